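"""Correlation-distance hierarchical clustering of traits and subjects.

The clustergram analysis sorts the subjects x traits z-score matrix along
both axes with agglomerative clustering under the correlation distance
``d = 1 - r`` (Pearson), weighted-average (WPGMA) linkage and no optimal
leaf reordering.  Cutting the trait tree at k=2 yields the positive /
negative trait clusters; cutting the subject tree at k=3 yields the
positive / moderate / negative subject groups.  Cluster composites are
plain means of member-trait z-scores, compared with paired t-tests and
within-group Pearson correlations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClusterError",
    "DistanceMatrix",
    "Dendrogram",
    "ClusterAssignment",
    "correlation_distance",
    "wpgma_linkage",
    "cut_tree",
    "composite_scores",
    "paired_ttest",
    "group_correlation",
]


class ClusterError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Symmetric distances with zero diagonal (<= 2 for correlation distance)."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ClusterError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(v)):
            raise ClusterError("non-finite distances")
        if np.abs(v - v.T).max(initial=0.0) > 1e-12:
            raise ClusterError("distance matrix is not symmetric")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


@dataclass
class Dendrogram:
    """Agglomeration result: n-1 merge records over clusters 0..2n-2.

    Leaves are clusters ``0..n-1`` (in label order); merge ``i`` creates
    cluster ``n + i``.  ``leaf_order`` is the display order obtained by
    traversing the final tree left-to-right in merge order — no
    optimal-leaf reordering is applied.
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]
    leaf_order: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.merges) != n - 1:
            raise ClusterError(f"expected {n - 1} merges for {n} leaves")
        if not self.leaf_order:
            self.leaf_order = self._traversal_order()

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def _children(self) -> dict[int, tuple[int, int]]:
        n = self.n_leaves
        return {n + i: (a, b) for i, (a, b, _) in enumerate(self.merges)}

    def _traversal_order(self) -> tuple[int, ...]:
        n = self.n_leaves
        children = self._children()

        def walk(node: int) -> list[int]:
            if node < n:
                return [node]
            a, b = children[node]
            return walk(a) + walk(b)

        return tuple(walk(2 * n - 2)) if n > 1 else (0,)

    @property
    def ordered_labels(self) -> tuple[str, ...]:
        return tuple(self.labels[i] for i in self.leaf_order)

    # -- export ----------------------------------------------------------

    def to_scipy(self) -> np.ndarray:
        """Linkage matrix in scipy's (left, right, height, count) layout."""
        n = self.n_leaves
        sizes = {i: 1 for i in range(n)}
        out = np.zeros((n - 1, 4))
        for i, (a, b, h) in enumerate(self.merges):
            sizes[n + i] = sizes[a] + sizes[b]
            out[i] = (a, b, h, sizes[n + i])
        return out

    def to_newick(self) -> str:
        """Newick string with ultrametric branch lengths (node height = merge height / 2)."""
        n = self.n_leaves
        children = self._children()
        height = {i: 0.0 for i in range(n)}
        for i, (_, _, h) in enumerate(self.merges):
            height[n + i] = h / 2.0

        def walk(node: int, parent_h: float) -> str:
            bl = parent_h - height[node]
            if node < n:
                return f"{self.labels[node]}:{bl:.10g}"
            a, b = children[node]
            return f"({walk(a, height[node])},{walk(b, height[node])}):{bl:.10g}"

        root = 2 * n - 2
        if n == 1:
            return f"{self.labels[0]};"
        a, b = children[root]
        return f"({walk(a, height[root])},{walk(b, height[root])});"

    def to_json(self, path: str | Path | None = None) -> str:
        n = self.n_leaves
        children = self._children()
        height = {i: 0.0 for i in range(n)}
        for i, (_, _, h) in enumerate(self.merges):
            height[n + i] = h

        def node(idx: int):
            if idx < n:
                return self.labels[idx]
            a, b = children[idx]
            return [node(a), node(b), height[idx]]

        s = json.dumps(node(2 * n - 2), sort_keys=True)
        if path is not None:
            Path(path).write_text(s)
        return s


@dataclass
class ClusterAssignment:
    """label -> cluster id (1..k); exactly k non-empty clusters."""

    mapping: dict[str, int]
    k: int

    def __post_init__(self) -> None:
        found = set(self.mapping.values())
        if found != set(range(1, self.k + 1)):
            raise ClusterError(f"expected clusters 1..{self.k}, found {sorted(found)}")

    def members(self, cluster: int) -> list[str]:
        return [lab for lab, c in self.mapping.items() if c == cluster]

    def labels_for(self, labels: Sequence[str]) -> np.ndarray:
        return np.array([self.mapping[lab] for lab in labels])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def correlation_distance(X, axis: str = "rows") -> DistanceMatrix:
    """Pairwise ``1 - Pearson r`` between profiles along the chosen axis.

    ``axis='rows'`` treats each row as a profile (columns are
    observations); ``axis='columns'`` the transpose.  Profiles must be
    non-constant and have at least 3 observations.
    """
    df = pd.DataFrame(X)
    if axis == "columns":
        df = df.T
    elif axis != "rows":
        raise ClusterError(f"axis must be 'rows' or 'columns', got {axis!r}")
    labels = tuple(str(i) for i in df.index)
    M = df.to_numpy(dtype=float)
    if M.shape[1] < 3:
        raise ClusterError("need at least 3 observations per profile")
    sd = M.std(axis=1)
    if (sd == 0).any():
        bad = [labels[i] for i in np.flatnonzero(sd == 0)[:5]]
        raise ClusterError(f"constant profile(s): {bad}")
    d = 1.0 - np.corrcoef(M)
    return DistanceMatrix(labels, d)


def wpgma_linkage(D: DistanceMatrix) -> Dendrogram:
    """Weighted-average (WPGMA) agglomeration.

    After merging clusters ``(a, b)`` the distance to any other cluster
    ``c`` is the unweighted mean ``(d(a,c) + d(b,c)) / 2`` of the two
    children's distances, regardless of cluster sizes.  Ties are broken
    by the lexicographically lowest cluster-index pair, so results are
    reproducible.
    """
    n = len(D.labels)
    if n < 2:
        raise ClusterError("need at least 2 leaves")
    if not np.all(np.isfinite(D.values)):
        raise ClusterError("NaN/inf distances")
    m = 2 * n - 1
    dist = np.full((m, m), np.inf)
    dist[:n, :n] = D.values
    np.fill_diagonal(dist, np.inf)
    active: list[int] = list(range(n))  # kept sorted ascending
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        idx = np.array(active)
        sub = dist[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        flat = sub[iu]
        k = int(np.argmin(flat))  # first occurrence => lowest (i, j) pair
        a, b = int(idx[iu[0][k]]), int(idx[iu[1][k]])
        h = float(flat[k])
        new = n + step
        others = [c for c in active if c != a and c != b]
        if others:
            dnew = 0.5 * (dist[a, others] + dist[b, others])
            dist[new, others] = dnew
            dist[others, new] = dnew
        merges.append((a, b, h))
        active.remove(a)
        active.remove(b)
        active.append(new)  # new > all previous ids, stays sorted
    return Dendrogram(tuple(D.labels), tuple(merges))


def cut_tree(dend: Dendrogram, k: int) -> ClusterAssignment:
    """The k clusters obtained by undoing the k-1 highest (last) merges."""
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ClusterError(f"k must be in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (a, b, _) in enumerate(dend.merges[: n - k]):
        new = n + i
        parent[find(a)] = new
        parent[find(b)] = new
    # number clusters 1..k in leaf-display order
    ids: dict[int, int] = {}
    mapping: dict[str, int] = {}
    for leaf in dend.leaf_order:
        root = find(leaf)
        if root not in ids:
            ids[root] = len(ids) + 1
        mapping[dend.labels[leaf]] = ids[root]
    return ClusterAssignment(mapping, k)


def composite_scores(trait_z: pd.DataFrame, assignment: ClusterAssignment) -> pd.DataFrame:
    """Per-subject mean z-score over each trait cluster (columns ``cluster_1..k``)."""
    missing = set(assignment.mapping) - set(trait_z.columns)
    if missing:
        raise ClusterError(f"assignment covers traits absent from scores: {sorted(missing)}")
    out = {}
    for c in range(1, assignment.k + 1):
        members = assignment.members(c)
        if not members:
            raise ClusterError(f"cluster {c} is empty")
        out[f"cluster_{c}"] = trait_z[members].mean(axis=1)
    return pd.DataFrame(out, index=trait_z.index)


def paired_ttest(x, y) -> tuple[float, int, float]:
    """Paired two-sided t-test on ``d = x - y``; returns ``(t, df, p)`` with df = n-1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ClusterError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 2:
        raise ClusterError("need at least 2 pairs")
    d = x - y
    if np.all(d == d[0]):
        if d[0] == 0:
            return 0.0, n - 1, 1.0
        raise ClusterError("constant non-zero differences; t undefined")
    t, p = stats.ttest_rel(x, y)
    return float(t), n - 1, float(p)


def group_correlation(
    pos: pd.Series,
    neg: pd.Series,
    groups: ClusterAssignment,
) -> pd.DataFrame:
    """Within-group Pearson correlation of the two composites.

    Returns one row per subject group with columns ``n``, ``r`` and the
    two-sided ``p`` from the exact t transform with n-2 degrees of
    freedom.  Each group needs >= 3 subjects and non-constant composites.
    """
    rows = []
    for c in range(1, groups.k + 1):
        members = groups.members(c)
        if len(members) < 3:
            raise ClusterError(f"group {c} has fewer than 3 subjects")
        x, y = pos.loc[members], neg.loc[members]
        if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
            raise ClusterError(f"constant composite within group {c}")
        r, p = stats.pearsonr(x, y)
        rows.append({"group": c, "n": len(members), "r": float(r), "p": float(p)})
    return pd.DataFrame(rows).set_index("group")
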
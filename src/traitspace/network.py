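"""Partial-correlation trait graphs via the PC-stable skeleton.

Edges of the trait graph are pairs of traits whose partial correlation
stays significant (Fisher-z test, two-sided p < alpha, default 0.01) for
*every* conditioning set the PC-stable algorithm examines.  PC-stable is
the order-independent variant of the PC skeleton search: at each level
the adjacency structure is frozen, so conditioning sets never depend on
the order in which edges were removed within the level.

Edge weight is the smallest-magnitude significant partial correlation
observed for the pair (the "net" pairwise association), its sign giving
the red/blue coloring; node centrality is the sum of absolute incident
edge weights (weighted degree importance).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NetworkError",
    "CITestRecord",
    "TraitGraph",
    "partial_corr",
    "fisher_z_test",
    "pc_stable_skeleton",
    "assign_edge_weights",
    "weighted_centrality",
]

log = logging.getLogger(__name__)


class NetworkError(ValueError):
    pass


@dataclass
class CITestRecord:
    """One conditional-independence test: rho_hat of (i, j) given S."""

    pair: tuple[str, str]
    cond_set: tuple[str, ...]
    rho_hat: float
    z: float
    p: float
    alpha: float
    degenerate: bool = False  # |rho_hat| reached 1

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


@dataclass
class Edge:
    pair: tuple[str, str]
    sign: int = 0
    weight: float = float("nan")
    p: float = float("nan")


@dataclass
class TraitGraph:
    """Undirected weighted trait graph with signed edges and centrality."""

    nodes: tuple[str, ...]
    edges: list[Edge] = field(default_factory=list)
    centrality: dict[str, float] = field(default_factory=dict)

    def edge_pairs(self) -> set[frozenset]:
        return {frozenset(e.pair) for e in self.edges}

    def has_edge(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.edge_pairs()

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(*e.pair, sign=e.sign, weight=e.weight, p=e.p)
        for node, c in self.centrality.items():
            g.nodes[node]["centrality"] = c
        return g

    def write_graphml(self, path: str | Path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), str(path))

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"node1": e.pair[0], "node2": e.pair[1], "sign": e.sign, "weight": e.weight, "p": e.p}
            for e in sorted(self.edges, key=lambda e: e.pair)
        ]
        return pd.DataFrame(rows, columns=["node1", "node2", "sign", "weight", "p"])

    def write_edge_tsv(self, path: str | Path) -> None:
        self.edge_table().to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------


def partial_corr(C: np.ndarray, i: int, j: int, S=()) -> float:
    """Partial correlation of variables i and j given index set S.

    Computed by inverting the ``{i, j} | S`` submatrix of the correlation
    matrix: ``-Omega_ij / sqrt(Omega_ii * Omega_jj)``.  With an empty S
    this is just ``C[i, j]``.
    """
    C = np.asarray(C, dtype=float)
    S = tuple(S)
    if i == j:
        raise NetworkError("i and j must differ")
    if i in S or j in S:
        raise NetworkError("conditioning set must not contain i or j")
    if not S:
        return float(C[i, j])
    idx = [i, j, *S]
    sub = C[np.ix_(idx, idx)]
    if np.linalg.cond(sub) > 1e12:
        raise NetworkError(f"singular submatrix for pair ({i}, {j}) given {S}")
    omega = np.linalg.inv(sub)
    return float(-omega[0, 1] / np.sqrt(omega[0, 0] * omega[1, 1]))


def fisher_z_test(
    rho_hat: float,
    n: int,
    s: int,
    alpha: float,
    pair: tuple[str, str] = ("i", "j"),
    cond_set: tuple[str, ...] = (),
) -> CITestRecord:
    """Fisher-z conditional-independence test.

    ``z = atanh(rho_hat) * sqrt(n - s - 3)``; the two-sided p-value is
    ``2 * (1 - Phi(|z|))``.  Requires ``n - s - 3 > 0``.  A degenerate
    ``|rho_hat| = 1`` yields p = 0 with the ``degenerate`` flag set.
    """
    from scipy import stats

    if n - s - 3 <= 0:
        raise NetworkError(f"sample too small for Fisher-z: n={n}, |S|={s}")
    if abs(rho_hat) >= 1.0:
        return CITestRecord(pair, cond_set, float(rho_hat), float("inf"), 0.0, alpha, degenerate=True)
    z = float(np.arctanh(rho_hat) * np.sqrt(n - s - 3))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return CITestRecord(pair, cond_set, float(rho_hat), z, p, alpha)


# ---------------------------------------------------------------------------
# PC-stable
# ---------------------------------------------------------------------------


def pc_stable_skeleton(
    data,
    alpha: float = 0.01,
    max_cond: int | None = None,
) -> tuple[TraitGraph, list[CITestRecord]]:
    """Learn the undirected skeleton with the PC-stable algorithm.

    ``data`` is a subjects x traits numeric table (DataFrame or array).
    Starting from the complete graph, for level l = 0, 1, 2, ... the
    adjacency is frozen; each still-adjacent pair (i, j) is tested
    against every size-l subset of the frozen neighborhoods adj(i)\\{j}
    and adj(j)\\{i}, and the edge is deleted on the first test accepting
    independence (p >= alpha).  The search stops when no node has l+1
    frozen neighbors (or l exceeds ``max_cond``).  Because conditioning
    sets come from the frozen snapshot, the surviving skeleton does not
    depend on variable order.

    Returns the graph (edges without weights; see
    :func:`assign_edge_weights`) and the full CI-test log.
    """
    df = pd.DataFrame(data)
    names = [str(c) for c in df.columns]
    X = df.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p + 3:
        raise NetworkError(f"need more subjects than traits + 3 (n={n}, p={p})")
    if (X.std(axis=0) == 0).any():
        raise NetworkError("constant column(s) in data")
    C = np.corrcoef(X, rowvar=False)

    adj: dict[int, set[int]] = {i: set(range(p)) - {i} for i in range(p)}
    records: list[CITestRecord] = []
    level = 0
    while True:
        frozen = {i: sorted(adj[i]) for i in range(p)}
        if max_cond is not None and level > max_cond:
            break
        if all(len(frozen[i]) < level + 1 for i in range(p)):
            break
        for i, j in combinations(range(p), 2):
            if j not in adj[i]:
                continue
            removed = False
            for a, b in ((i, j), (j, i)):
                cands = [v for v in frozen[a] if v != b]
                if len(cands) < level:
                    continue
                for S in combinations(cands, level):
                    rho = partial_corr(C, i, j, S)
                    rec = fisher_z_test(
                        rho, n, level, alpha,
                        pair=(names[i], names[j]),
                        cond_set=tuple(names[v] for v in S),
                    )
                    records.append(rec)
                    if not rec.significant:
                        adj[i].discard(j)
                        adj[j].discard(i)
                        removed = True
                        break
                if removed:
                    break
        level += 1

    graph = TraitGraph(tuple(names))
    for i, j in combinations(range(p), 2):
        if j in adj[i]:
            graph.edges.append(Edge(pair=(names[i], names[j])))
    return graph, records


def assign_edge_weights(graph: TraitGraph, records: list[CITestRecord]) -> TraitGraph:
    """Set each surviving edge's weight to its minimal-|rho| significant test.

    The edge width semantics: the lowest significant partial correlation
    observed between the node pair is the net pairwise association; its
    sign colors the edge (positive/negative).  A sign disagreement among
    a pair's records is resolved in favor of the minimal-|rho| record,
    with a warning.
    """
    by_pair: dict[frozenset, list[CITestRecord]] = {}
    for rec in records:
        by_pair.setdefault(frozenset(rec.pair), []).append(rec)
    for e in graph.edges:
        recs = by_pair.get(frozenset(e.pair))
        if not recs:
            raise NetworkError(f"edge {e.pair} has no CI-test records")
        best = min(recs, key=lambda r: abs(r.rho_hat))
        signs = {np.sign(r.rho_hat) for r in recs}
        if len(signs) > 1:
            warnings.warn(
                f"edge {e.pair}: partial-correlation sign varies across conditioning sets; "
                "using the minimal-|rho| record's sign",
                stacklevel=2,
            )
        e.weight = abs(best.rho_hat)
        e.sign = int(np.sign(best.rho_hat)) or 1
        e.p = best.p
    graph.centrality = weighted_centrality(graph)
    return graph


def weighted_centrality(graph: TraitGraph) -> dict[str, float]:
    """Weighted degree-importance centrality: sum of |edge weights| per node."""
    cent = {node: 0.0 for node in graph.nodes}
    for e in graph.edges:
        w = abs(e.weight)
        if np.isnan(w):
            raise NetworkError(f"edge {e.pair} has no weight; run assign_edge_weights first")
        cent[e.pair[0]] += w
        cent[e.pair[1]] += w
    return cent
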
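"""Embedding-based scale refinement: separability scoring, pruning, reassignment.

The idea: once every questionnaire item has a position in the 2-D trait
space, a well-localized scale is one whose items are linearly separable
from every neighboring trait's items.  Target items that drift into a
neighbor's territory and cannot be separated from it by a linear
maximum-margin classifier (training misclassification above a threshold)
are pruned; the internal consistency of the surviving scale is
re-checked with Cronbach's alpha.  Within a trait, items can also be
re-assigned to the subdomain whose item centroid they actually sit on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from .embedding import Embedding2D
from .reliability import cronbach_alpha
from .schema import QuestionnaireSchema

__all__ = [
    "RefineError",
    "RefinementReport",
    "linear_separability_error",
    "prune_items",
    "reassign_items",
]


class RefineError(ValueError):
    pass


@dataclass
class SeparabilityRecord:
    items: tuple[str, ...]
    neighbor: str
    error: float
    decision: str  # "keep" | "remove"


@dataclass
class RefinementReport:
    """Audit trail of one pruning run."""

    target: str
    theta: float
    tested: list[SeparabilityRecord] = field(default_factory=list)
    removed: tuple[str, ...] = ()
    kept: tuple[str, ...] = ()
    alpha_before: float | None = None
    alpha_after: float | None = None
    schema_variant: QuestionnaireSchema | None = field(default=None, repr=False)

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "target": self.target,
            "theta": self.theta,
            "tested": [asdict(t) for t in self.tested],
            "removed": list(self.removed),
            "kept": list(self.kept),
            "alpha_before": self.alpha_before,
            "alpha_after": self.alpha_after,
        }
        s = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(s)
        return s


def linear_separability_error(A: np.ndarray, B: np.ndarray) -> float:
    """Training misclassification fraction of a linear SVM separating A from B.

    A soft-margin linear maximum-margin classifier (regularization
    constant fixed at 1) is fit on the labeled union of the two 2-D
    point sets; the returned value is the number of incorrectly
    classified points divided by the total.  0 means linearly separable,
    0.5 is chance for balanced, coincident sets.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if len(A) == 0 or len(B) == 0:
        raise RefineError("both point sets must be non-empty")
    X = np.vstack([A, B])
    y = np.concatenate([np.zeros(len(A)), np.ones(len(B))])
    if len(A) == 1 and len(B) == 1:
        # a single point per class is always separable (unless coincident)
        return 0.0 if not np.allclose(A[0], B[0]) else 0.5
    clf = SVC(kernel="linear", C=1.0)
    clf.fit(X, y)
    return float((clf.predict(X) != y).mean())


def _trait_items(emb: Embedding2D, schema: QuestionnaireSchema, trait: str) -> list[str]:
    ids = [iid for iid in schema.instrument_for_trait(trait).item_ids if iid in set(emb.labels)]
    if not ids:
        raise RefineError(f"embedding covers no items of trait {trait!r}")
    return ids


def prune_items(
    emb: Embedding2D,
    schema: QuestionnaireSchema,
    target: str,
    neighbors: list[str],
    theta: float = 0.05,
    responses=None,
) -> RefinementReport:
    """Prune target-trait items that are not linearly separable from neighbors.

    Procedure: (1) every target item is tentatively matched to the
    nearest trait (target included) by item-centroid distance, the
    target's own centroid excluding the item itself; (2) for each
    neighbor trait, the subset of target items matched to it is scored
    with :func:`linear_separability_error` against that neighbor's
    items; (3) subsets whose error exceeds ``theta`` are flagged "not
    linearly separable" and removed; (4) if a keyed response matrix is
    supplied, Cronbach's alpha of the full and the pruned scale is
    recorded.  The returned report carries the full audit trail and the
    pruned schema variant.

    ``theta`` defaults to 0.05, between the separability errors of sets
    that were retained and sets that were removed in the motivating
    analysis; it is a configuration value.
    """
    if not 0.0 <= theta <= 1.0:
        raise RefineError("theta must be in [0, 1]")
    target_ids = _trait_items(emb, schema, target)
    target_pts = emb.points_of(target_ids)
    centroids = {t: emb.points_of(_trait_items(emb, schema, t)).mean(axis=0) for t in neighbors}

    matched: dict[str, list[str]] = {t: [] for t in neighbors}
    for iid, pt in zip(target_ids, target_pts):
        others = [p for j, p in zip(target_ids, target_pts) if j != iid]
        own = np.mean(others, axis=0) if others else pt
        dists = {target: np.linalg.norm(pt - own)}
        dists.update({t: np.linalg.norm(pt - c) for t, c in centroids.items()})
        best = min(dists, key=dists.get)
        if best != target:
            matched[best].append(iid)

    report = RefinementReport(target=target, theta=theta)
    removed: list[str] = []
    for t in neighbors:
        subset = matched[t]
        if not subset:
            continue
        err = linear_separability_error(
            emb.points_of(subset), emb.points_of(_trait_items(emb, schema, t))
        )
        decision = "remove" if err > theta else "keep"
        if decision == "remove":
            removed.extend(subset)
        report.tested.append(SeparabilityRecord(tuple(subset), t, err, decision))

    report.removed = tuple(removed)
    report.kept = tuple(i for i in target_ids if i not in set(removed))
    report.schema_variant = schema.without_items(removed) if removed else schema
    if responses is not None:
        import pandas as pd

        values = responses.values if hasattr(responses, "metadata") else pd.DataFrame(responses)
        report.alpha_before = cronbach_alpha(values[target_ids].to_numpy())
        if len(report.kept) >= 2:
            report.alpha_after = cronbach_alpha(values[list(report.kept)].to_numpy())
    return report


def reassign_items(
    emb: Embedding2D,
    schema: QuestionnaireSchema,
    trait: str,
) -> tuple[dict[str, str], QuestionnaireSchema]:
    """Reassign a trait's items to their nearest subdomain centroid.

    Each categorized item of the trait is assigned to the subdomain whose
    item centroid (excluding the item itself) is nearest in the
    embedding.  Returns the item -> subdomain map and a schema variant
    with the switches applied; switches leaving a subdomain empty are
    legal (its centroid is computed from the remaining items, and an
    empty remainder is an error).
    """
    inst = schema.instrument_for_trait(trait)
    subs = inst.subdomains
    if len(subs) < 2:
        raise RefineError(f"trait {trait!r} needs >= 2 subdomains to reassign")
    members = {s: [it.id for it in inst.subdomain_items(s) if it.id in set(emb.labels)] for s in subs}
    mapping: dict[str, str] = {}
    for it in inst.items:
        if it.id not in set(emb.labels):
            continue
        pt = emb.points_of([it.id])[0]
        dists = {}
        for s in subs:
            pool = [i for i in members[s] if i != it.id]
            if not pool:
                raise RefineError(f"subdomain {s!r} has no other items to form a centroid")
            dists[s] = float(np.linalg.norm(pt - emb.points_of(pool).mean(axis=0)))
        mapping[it.id] = min(dists, key=dists.get)
    variant = schema.with_subdomains(trait, mapping)
    return mapping, variant
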
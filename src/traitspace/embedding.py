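"""2-D embedding of questionnaire items: stress-majorization MDS, then t-SNE.

The item map is built from the correlation distance ``1 - r`` between all
item z-score profiles.  Metric ("nonclassical") multidimensional scaling
minimizes raw stress by majorization (SMACOF / Guttman transform) from a
classical-scaling start; its coordinates initialize t-SNE, run on the
same precomputed distances with perplexity 10, learning rate 100, up to
5000 iterations and an early-exaggeration factor of 80 applied for the
first 99 iterations.  Both steps are deterministic: with the same
distances and parameters the coordinates are bit-identical, and
embeddings are compared only up to similarity transforms (Procrustes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import DistanceMatrix

__all__ = [
    "EmbedError",
    "EmbedParams",
    "Embedding2D",
    "mds_embed",
    "tsne_embed",
    "embed_trait_matrix",
    "procrustes_align",
    "overlay_embeddings",
]


class EmbedError(ValueError):
    pass


@dataclass(frozen=True)
class EmbedParams:
    """t-SNE settings (defaults mirror the study's reported parameters)."""

    perplexity: float = 10.0
    exaggeration: float = 80.0
    learning_rate: float = 100.0
    max_iter: int = 5000
    seed: int = 0
    exaggeration_phase: int = 99
    min_grad_norm: float = 1e-7

    def __post_init__(self) -> None:
        for name in ("perplexity", "exaggeration", "learning_rate", "max_iter"):
            if getattr(self, name) <= 0:
                raise EmbedError(f"{name} must be positive")


@dataclass
class Embedding2D:
    """2-D coordinates per label, with trait/subdomain metadata."""

    labels: tuple[str, ...]
    coords: np.ndarray  # (n, 2)
    metadata: pd.DataFrame | None = None  # columns: trait, subdomain
    stress_history: np.ndarray | None = field(default=None, repr=False)
    kl_history: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.labels), 2):
            raise EmbedError("coords must be (n_labels, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise EmbedError("non-finite coordinates")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coords, index=list(self.labels), columns=["x", "y"])
        df.index.name = "label"
        if self.metadata is not None:
            df = self.metadata.join(df, how="right")
            df.index.name = "label"
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, float_format="%.10g")

    def points_of(self, labels) -> np.ndarray:
        pos = {lab: i for i, lab in enumerate(self.labels)}
        return self.coords[[pos[lab] for lab in labels]]


# ---------------------------------------------------------------------------
# MDS: classical start + stress majorization
# ---------------------------------------------------------------------------


def _classical_scaling(D: np.ndarray, dim: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:dim]
    w_top = np.clip(w[order], 0.0, None)
    return V[:, order] * np.sqrt(w_top)


def _raw_stress(X: np.ndarray, D: np.ndarray) -> float:
    d = np.sqrt(np.maximum(_sqdist(X), 0.0))
    iu = np.triu_indices_from(D, k=1)
    return float(((d[iu] - D[iu]) ** 2).sum())


def _sqdist(X: np.ndarray) -> np.ndarray:
    ss = (X**2).sum(axis=1)
    d2 = ss[:, None] + ss[None, :] - 2.0 * X @ X.T
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


def mds_embed(
    D: DistanceMatrix,
    dim: int = 2,
    max_iter: int = 300,
    tol: float = 1e-9,
) -> Embedding2D:
    """Metric MDS by stress majorization (SMACOF) from a classical-scaling start.

    Minimizes raw stress ``sum_{i<j} (d_ij(X) - D_ij)^2`` with the Guttman
    transform, which never increases stress, and stops when the relative
    stress improvement drops below ``tol``.  Fully deterministic.
    """
    Dm = np.asarray(D.values, dtype=float)
    n = Dm.shape[0]
    if n < dim + 1:
        raise EmbedError(f"need at least {dim + 1} points for a {dim}-D embedding")
    X = _classical_scaling(Dm, dim)
    history = [_raw_stress(X, Dm)]
    for _ in range(max_iter):
        d = np.sqrt(_sqdist(X))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 1e-12, Dm / d, 0.0)
        np.fill_diagonal(ratio, 0.0)
        B = -ratio
        np.fill_diagonal(B, ratio.sum(axis=1))
        X = (B @ X) / n
        s = _raw_stress(X, Dm)
        history.append(s)
        if history[-2] - s <= tol * max(history[-2], 1e-30):
            break
    if dim != 2:
        raise EmbedError("only 2-D embeddings are supported downstream")
    return Embedding2D(tuple(D.labels), X, stress_history=np.array(history))


# ---------------------------------------------------------------------------
# t-SNE on precomputed distances
# ---------------------------------------------------------------------------


def _joint_probabilities(D2: np.ndarray, perplexity: float, tol: float = 1e-7) -> np.ndarray:
    """Perplexity-calibrated conditional affinities, symmetrized."""
    n = D2.shape[0]
    target = np.log(perplexity)
    P = np.zeros((n, n))
    for i in range(n):
        d = np.delete(D2[i], i)
        lo, hi = 0.0, np.inf
        beta = 1.0
        for _ in range(100):
            w = np.exp(-d * beta)
            sw = w.sum()
            if sw <= 0:
                entropy = 0.0
            else:
                pj = w / sw
                nz = pj > 0
                entropy = float(-(pj[nz] * np.log(pj[nz])).sum())
            if abs(entropy - target) < tol:
                break
            if entropy > target:
                lo = beta
                beta = beta * 2.0 if not np.isfinite(hi) else (beta + hi) / 2.0
            else:
                hi = beta
                beta = (lo + beta) / 2.0
        row = np.exp(-D2[i] * beta)
        row[i] = 0.0
        s = row.sum()
        P[i] = row / s if s > 0 else 0.0
    P = (P + P.T) / (2.0 * n)
    return np.maximum(P, 1e-12)


def tsne_embed(D: DistanceMatrix, init: Embedding2D, params: EmbedParams) -> Embedding2D:
    """t-SNE on a precomputed distance matrix with a fixed initialization.

    Affinities use the squared input distances in the Gaussian kernel
    (calibrated per point to the target perplexity).  Gradient descent
    uses the standard momentum schedule (0.5, then 0.8 after iteration
    250) with adaptive gains; early exaggeration multiplies the
    affinities by ``params.exaggeration`` for the first
    ``params.exaggeration_phase`` iterations.  Iteration stops at
    ``max_iter`` or once the gradient norm falls below
    ``min_grad_norm`` after the exaggeration phase.  Deterministic:
    identical inputs give identical coordinates.
    """
    n = len(D.labels)
    if tuple(init.labels) != tuple(D.labels):
        raise EmbedError("init labels must match distance-matrix labels")
    if params.perplexity >= (n - 1) / 3.0:
        raise EmbedError(
            f"perplexity {params.perplexity} infeasible for {n} points (must be < (n-1)/3)"
        )
    P = _joint_probabilities(np.asarray(D.values) ** 2, params.perplexity)
    Y = init.coords.copy()
    dY = np.zeros_like(Y)
    gains = np.ones_like(Y)
    kl_history = []
    for it in range(params.max_iter):
        exag = params.exaggeration if it < params.exaggeration_phase else 1.0
        num = 1.0 / (1.0 + _sqdist(Y))
        np.fill_diagonal(num, 0.0)
        Q = np.maximum(num / num.sum(), 1e-12)
        PQ = (exag * P - Q) * num
        grad = 4.0 * (np.diag(PQ.sum(axis=1)) - PQ) @ Y
        momentum = 0.5 if it < 250 else 0.8
        flip = np.sign(grad) != np.sign(dY)
        gains = np.where(flip, gains + 0.2, gains * 0.8)
        gains = np.maximum(gains, 0.01)
        dY = momentum * dY - params.learning_rate * gains * grad
        Y = Y + dY
        Y = Y - Y.mean(axis=0)
        kl_history.append(float((P * np.log(P / Q)).sum()))
        if it >= params.exaggeration_phase and np.linalg.norm(grad) < params.min_grad_norm:
            break
    return Embedding2D(
        tuple(D.labels), Y, metadata=init.metadata, kl_history=np.array(kl_history)
    )


# ---------------------------------------------------------------------------
# trait-matrix embedding & comparison
# ---------------------------------------------------------------------------


def embed_trait_matrix(C: pd.DataFrame) -> Embedding2D:
    """MDS embedding of a trait-level correlation matrix (distance ``1 - C``).

    Accepts an externally supplied matrix (labels from the index); the
    matrix must be symmetric with a unit diagonal.  Use
    :func:`overlay_embeddings` to compare two embeddings with shared
    labels.
    """
    C = pd.DataFrame(C)
    M = C.to_numpy(dtype=float)
    if not C.index.equals(C.columns):
        raise EmbedError("correlation matrix must have matching row/column labels")
    if np.abs(M - M.T).max() > 1e-8:
        raise EmbedError("correlation matrix is not symmetric")
    if np.abs(np.diag(M) - 1.0).max() > 1e-8:
        raise EmbedError("correlation matrix must have a unit diagonal")
    D = DistanceMatrix(tuple(str(i) for i in C.index), 1.0 - (M + M.T) / 2.0)
    return mds_embed(D)


def procrustes_align(ref: np.ndarray, other: np.ndarray) -> tuple[np.ndarray, float]:
    """Align ``other`` to ``ref`` by translation, rotation/reflection and scale.

    Returns the aligned copy of ``other`` (in ``ref``'s frame) and the
    Procrustes disparity (sum of squared differences after aligning both
    to unit norm, as in :func:`scipy.spatial.procrustes`).
    """
    from scipy.spatial import procrustes as _proc

    m1, m2, disparity = _proc(ref, other)
    # map the standardized solution back to ref's original frame
    scale = np.linalg.norm(ref - ref.mean(axis=0))
    return m2 * scale + ref.mean(axis=0), float(disparity)


def overlay_embeddings(e1: Embedding2D, e2: Embedding2D) -> dict:
    """Procrustes comparison of two embeddings over their shared labels."""
    shared = [lab for lab in e1.labels if lab in set(e2.labels)]
    if len(shared) < 3:
        raise EmbedError("need at least 3 shared labels to compare embeddings")
    a = e1.points_of(shared)
    b = e2.points_of(shared)
    aligned, disparity = procrustes_align(a, b)
    rmsd = float(np.sqrt(((aligned - a) ** 2).sum(axis=1).mean()))
    return {
        "n_shared": len(shared),
        "disparity": disparity,
        "rmsd_after_alignment": rmsd,
        "labels": shared,
        "aligned_coords": aligned,
    }
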
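"""Internal-consistency reliability: Cronbach's alpha, split-half, prevalence.

Cronbach's alpha (also written rho_T) for k items is

    alpha = k/(k-1) * (1 - sum_i var(x_i) / var(sum_i x_i))

All variances are *sample* variances (denominator n-1); the coefficient is
invariant to that choice only when the same convention is used in numerator
and denominator, so it is fixed and documented here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReliabilityError",
    "ReliabilityReport",
    "cronbach_alpha",
    "split_half",
    "sps_high_fraction",
]


class ReliabilityError(ValueError):
    pass


@dataclass
class ReliabilityReport:
    """Reliability summary for one scale."""

    scale: str
    alpha: float
    split_half_raw: float
    split_half_corrected: float
    k: int
    n: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _as_array(items) -> np.ndarray:
    X = np.asarray(items, dtype=float)
    if X.ndim != 2:
        raise ReliabilityError("items must be a 2-D subjects x items array")
    return X


def cronbach_alpha(items) -> float:
    """Cronbach's alpha of a subjects x k item-score matrix.

    Requires k >= 2 items and a non-constant total score.  Equals 1 when
    all items are identical copies of one non-constant item, and is
    invariant under adding constants to items and under item reordering.
    """
    X = _as_array(items)
    n, k = X.shape
    if k < 2:
        raise ReliabilityError(f"alpha needs at least 2 items, got {k}")
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ReliabilityError("total score is constant; alpha undefined")
    return k / (k - 1) * (1.0 - item_var.sum() / total_var)


def split_half(items, scheme: str = "odd_even") -> tuple[float, float]:
    """Split-half reliability: Pearson r of half totals, Spearman-Brown corrected.

    The halves are the odd- and even-position items — a fixed positional
    convention chosen for reproducibility.  Returns ``(raw_r, corrected)``
    with the correction ``2 r / (1 + r)``.
    """
    if scheme != "odd_even":
        raise ReliabilityError(f"unknown split scheme {scheme!r}")
    X = _as_array(items)
    if X.shape[1] < 2:
        raise ReliabilityError("split-half needs at least 2 items")
    odd = X[:, 0::2].sum(axis=1)
    even = X[:, 1::2].sum(axis=1)
    if odd.std(ddof=1) == 0 or even.std(ddof=1) == 0:
        raise ReliabilityError("constant half-total; split-half undefined")
    r = float(stats.pearsonr(odd, even)[0])
    return r, 2 * r / (1 + r)


def sps_high_fraction(
    scores,
    sps_threshold: float,
    depression_cutoff: float = 53.0,
    *,
    sps_trait: str = "SPS",
    depression_trait: str = "depression",
) -> float:
    """Fraction of high-sensitivity scorers among non-depressed subjects.

    Subjects with a depression total above ``depression_cutoff`` (default
    53, the instrument's high-depression criterion) are excluded from the
    denominator; the returned fraction is the share of the remaining
    subjects whose sensitivity total exceeds ``sps_threshold``.  The
    threshold itself is a configuration value: the published high-score
    criterion is external to this package.
    """
    traits = scores.traits if hasattr(scores, "traits") else pd.DataFrame(scores)
    sps = traits[sps_trait]
    dep = traits[depression_trait]
    eligible = dep <= depression_cutoff
    if not eligible.any():
        raise ReliabilityError("no subjects below the depression cutoff")
    return float((sps[eligible] > sps_threshold).mean())
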
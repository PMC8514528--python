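"""Factorial effects of sensitivity and parental bonding, power calculations.

Sensitivity (high/low) and parental-bonding dimensions (care,
overprotection; mother and father forms averaged) are crossed in 2x2
unbalanced two-way ANOVAs with interaction on trait or composite scores,
using Type-II sums of squares, followed by Tukey HSD pairwise
comparisons.  The module also provides the Fisher-z sample-size formula
for detecting a correlation of a given magnitude.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectsError",
    "AnovaTable",
    "pbi_average",
    "dichotomize",
    "two_way_anova",
    "tukey_hsd",
    "correlation_power_n",
]

log = logging.getLogger(__name__)


class EffectsError(ValueError):
    pass


@dataclass
class AnovaTable:
    """Type-II two-way ANOVA table: factor A, factor B, A:B, residual."""

    table: pd.DataFrame  # index: A, B, A:B, Residual; columns: SS, df, F, p

    def row(self, name: str) -> pd.Series:
        return self.table.loc[name]

    @property
    def residual_df(self) -> int:
        return int(self.table.loc["Residual", "df"])


def pbi_average(mother: pd.DataFrame, father: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean of the mother and father parental-bonding forms.

    Both frames share columns (e.g. ``care``, ``overprotection``).
    Subjects missing either form are dropped with a log entry.
    """
    common = mother.index.intersection(father.index)
    dropped = len(mother.index.union(father.index)) - len(common)
    m = mother.loc[common]
    f = father.loc[common]
    complete = ~(m.isna().any(axis=1) | f.isna().any(axis=1))
    dropped += int((~complete).sum())
    if dropped:
        log.info("pbi_average: excluded %d subjects missing a parental form", dropped)
    return (m.loc[complete] + f.loc[complete]) / 2.0


def dichotomize(scores, rule="median") -> pd.Series:
    """Split scores into ``high`` / ``low`` levels.

    ``rule='median'`` labels values above the median high (ties go low);
    ``rule=('threshold', v)`` uses the fixed cutoff ``v`` instead.
    """
    s = pd.Series(scores, dtype=float)
    if len(s) < 2:
        raise EffectsError("need at least 2 subjects to dichotomize")
    if rule == "median":
        cut = s.median()
        if s.nunique() == 1:
            raise EffectsError("all scores equal; median split undefined")
    elif isinstance(rule, tuple) and len(rule) == 2 and rule[0] == "threshold":
        cut = float(rule[1])
    else:
        raise EffectsError(f"unknown dichotomization rule {rule!r}")
    return pd.Series(np.where(s > cut, "high", "low"), index=s.index, name="level")


def two_way_anova(y, A, B) -> AnovaTable:
    """Unbalanced 2x2 ANOVA with interaction, Type-II sums of squares.

    Type II tests each main effect after the other main effect (ignoring
    the interaction) and the interaction against the full model; with
    unbalanced cells this is the convention that does not depend on
    factor order.  Every cell must be non-empty.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": np.asarray(y, dtype=float), "A": list(A), "B": list(B)})
    if len(df) <= 4:
        raise EffectsError("need more than 4 observations")
    cells = df.groupby(["A", "B"], observed=True).size()
    n_a, n_b = df["A"].nunique(), df["B"].nunique()
    if len(cells) < n_a * n_b:
        raise EffectsError("empty factor cell; two-way ANOVA undefined")
    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    tab = tab.rename(
        index={"C(A)": "A", "C(B)": "B", "C(A):C(B)": "A:B"},
        columns={"sum_sq": "SS", "PR(>F)": "p"},
    )[["SS", "df", "F", "p"]]
    return AnovaTable(tab)


def tukey_hsd(y, groups) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons across the given groups.

    Uses the studentized-range distribution with the pooled residual
    mean square of the one-way cell model (equivalently, the full
    factorial model's residual when groups are the factor cells).
    Each group needs >= 2 observations.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    sizes = pd.Series(groups).value_counts()
    if len(sizes) < 2:
        raise EffectsError("need at least 2 groups")
    if (sizes < 2).any():
        raise EffectsError("every group needs at least 2 observations")
    res = pairwise_tukeyhsd(y, groups)
    out = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    out["p-adj"] = res.pvalues
    return out


def correlation_power_n(r: float, alpha: float = 0.05, power: float = 0.80) -> int:
    """Sample size to detect a correlation of magnitude r (two-sided Fisher-z).

    ``n = ceil( ((z_{1-alpha/2} + z_power) / atanh(r))^2 + 3 )``.
    With r=0.1, alpha=0.05 and power 0.80 this gives 783.
    """
    if not 0.0 < r < 1.0:
        raise EffectsError("r must be in (0, 1)")
    if not 0.0 < alpha < 1.0 or not 0.0 < power < 1.0:
        raise EffectsError("alpha and power must be in (0, 1)")
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(power)
    return int(math.ceil(((z_a + z_b) / math.atanh(r)) ** 2 + 3.0))
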
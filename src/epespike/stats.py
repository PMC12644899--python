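"""Treatment-comparison statistics and the pod-damage scale.

The statistical layer mirrors standard greenhouse practice: per-window
one-way ANOVA on log-transformed spike counts followed by Tukey's HSD
post-hoc test, paired t-tests for within-plant contrasts (stem vs pod
electrode, day vs night), descriptive means with 95% confidence intervals
for insect-survival counts, and the ordinal pod-damage classification from
the percentage of damaged seeds.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "significance_code",
    "anova_tukey",
    "paired_t",
    "ci95_mean",
    "DamageClass",
    "classify_damage",
]

# significance stars at the conventional cutpoints
_CUTPOINTS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_code(p_value: float) -> str:
    """Map a p-value to the figure-legend star convention."""
    if not (0.0 <= p_value <= 1.0):
        if math.isnan(p_value):
            return "n.s."
        raise ValueError("p-value must lie in [0, 1]")
    for cut, stars in _CUTPOINTS:
        if p_value < cut:
            return stars
    return "n.s."


@dataclass
class GroupSummary:
    mean: float
    se: float
    n: int


@dataclass
class ComparisonResult:
    contrast: str
    statistic_name: str  # "F" or "t"
    statistic: float
    p_value: float
    group_summaries: dict
    window: Optional[tuple] = None  # (start DAI, end DAI)
    pairwise: Optional[pd.DataFrame] = None  # Tukey-adjusted pairwise p-values
    degenerate: bool = False

    @property
    def significance_code(self) -> str:
        return significance_code(self.p_value)


def _summaries(groups: Mapping[str, Sequence[float]]) -> dict:
    out = {}
    for label, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        se = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size >= 2 else float("nan")
        out[label] = GroupSummary(mean=float(np.mean(v)), se=se, n=int(v.size))
    return out


def anova_tukey(groups: Mapping[str, Sequence[float]],
                window: Optional[tuple] = None,
                contrast: str = "treatment") -> ComparisonResult:
    """One-way fixed-effects ANOVA with Tukey HSD pairwise comparisons.

    ``groups`` maps treatment labels to per-channel log counts for one
    window.  When every group has zero within-group variance the F
    statistic is undefined; the result is flagged degenerate instead of
    reporting an arbitrary number.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(a.size < 2 for a in arrays.values()):
        raise ValueError("every group needs n >= 2 for inference")
    within_ss = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays.values())
    if within_ss == 0.0:
        return ComparisonResult(
            contrast=contrast, statistic_name="F", statistic=float("nan"),
            p_value=float("nan"), group_summaries=_summaries(arrays),
            window=window, degenerate=True,
        )
    f_stat, p = sps.f_oneway(*arrays.values())
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([np.full(a.size, k) for k, a in arrays.items()])
    tk = pairwise_tukeyhsd(values, labels)
    pairs = list(combinations(tk.groupsunique, 2))
    pairwise = pd.DataFrame({
        "group1": [a for a, _ in pairs],
        "group2": [b for _, b in pairs],
        "p_adj": np.asarray(tk.pvalues, dtype=float),
        "reject": np.asarray(tk.reject, dtype=bool),
    })
    return ComparisonResult(
        contrast=contrast, statistic_name="F", statistic=float(f_stat),
        p_value=float(p), group_summaries=_summaries(arrays),
        window=window, pairwise=pairwise,
    )


def paired_t(x: Sequence[float], y: Sequence[float],
             window: Optional[tuple] = None,
             contrast: str = "paired") -> ComparisonResult:
    """Classical two-sided paired t-test on matched per-unit values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    if x.size < 2:
        raise ValueError("need n >= 2 matched pairs")
    diffs = x - y
    summaries = _summaries({"x": x, "y": y})
    if np.std(diffs, ddof=1) == 0.0:
        if diffs[0] == 0.0:
            # identical inputs: no evidence of a difference
            return ComparisonResult(
                contrast=contrast, statistic_name="t", statistic=0.0,
                p_value=1.0, group_summaries=summaries, window=window,
                degenerate=True,
            )
        stat = math.copysign(math.inf, diffs[0])
        return ComparisonResult(
            contrast=contrast, statistic_name="t", statistic=stat,
            p_value=0.0, group_summaries=summaries, window=window,
            degenerate=True,
        )
    t_stat, p = sps.ttest_rel(x, y)
    return ComparisonResult(
        contrast=contrast, statistic_name="t", statistic=float(t_stat),
        p_value=float(p), group_summaries=summaries, window=window,
    )


def ci95_mean(values: Sequence[float]) -> tuple[float, float, float]:
    """Mean with the t-based 95% confidence interval (mean, lower, upper)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need n >= 2 for a confidence interval")
    m = float(np.mean(v))
    half = float(sps.t.ppf(0.975, v.size - 1) * np.std(v, ddof=1) / np.sqrt(v.size))
    return m, m - half, m + half


class DamageClass(enum.IntEnum):
    """Ordinal pod-damage classes from the percentage of damaged seeds."""

    NONE = 0       # below 1%
    MODERATE = 1   # 1-30%
    CRITICAL = 2   # 31-50%
    SEVERE = 3     # 51-70%
    COMPLETE = 4   # 71-100% (dead pods)


def classify_damage(percent_seeds_damaged: float) -> DamageClass:
    """Classify pod damage from the average percentage of damaged seeds.

    Fractional percentages are rounded to the nearest integer percent
    before classification; the scale partitions 0-100% without gaps.
    """
    p = float(percent_seeds_damaged)
    if not 0.0 <= p <= 100.0:
        raise ValueError("percent damaged seeds must lie in [0, 100]")
    pct = int(math.floor(p + 0.5))
    if pct < 1:
        return DamageClass.NONE
    if pct <= 30:
        return DamageClass.MODERATE
    if pct <= 50:
        return DamageClass.CRITICAL
    if pct <= 70:
        return DamageClass.SEVERE
    return DamageClass.COMPLETE
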
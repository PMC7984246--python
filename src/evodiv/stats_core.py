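"""Minimal group-comparison statistics shared by the pipeline stages.

Three primitives cover every hypothesis test the pipeline reports:

* :func:`lm_f_test` — the F test between nested Gaussian linear models
  (intercept-only versus group means).  For a single categorical predictor
  this is the classical one-way ANOVA F, which orders models identically to
  a likelihood-ratio test, so it is what "model comparison" means here.
* :func:`ranksum_w` — the two-sample Wilcoxon rank-sum test reported with
  the W convention (rank sum of ``x`` minus ``n_x(n_x+1)/2``, i.e. the
  Mann-Whitney U of ``x``).  For two groups this coincides with a
  two-sample Kruskal-Wallis test.
* :func:`holm_adjust` — step-down Holm-Bonferroni multiplicity adjustment.

Two-sided p-values throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FTestResult",
    "GroupedValues",
    "lm_f_test",
    "ranksum_w",
    "holm_adjust",
]


@dataclass(frozen=True)
class FTestResult:
    """One-way ANOVA / nested-model F test summary."""

    statistic: float
    df1: int
    df2: int
    p: float


@dataclass(frozen=True)
class GroupedValues:
    """Long-format sample: one value and one group label per observation."""

    values: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        groups = np.asarray(self.groups)
        if values.shape != groups.shape or values.ndim != 1:
            raise ValueError("values and groups must be equal-length 1-D arrays")
        if len(np.unique(groups)) < 2:
            raise ValueError("need at least two distinct groups")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "groups", groups)


def lm_f_test(values: Sequence[float], groups: Sequence) -> FTestResult:
    """F test of a group-means linear model against the intercept-only model.

    Parameters
    ----------
    values : array-like of float
        Response values, one per sample.
    groups : array-like
        Group label per sample; at least two distinct labels.

    Returns
    -------
    FTestResult
        F statistic with df1 = a - 1, df2 = n - a and the upper-tail
        F-distribution p-value.

    Raises
    ------
    ValueError
        If fewer than two groups, n <= number of groups, or both the
        between- and within-group sums of squares vanish (F undefined).
    """
    data = GroupedValues(np.asarray(values, dtype=float), np.asarray(groups))
    labels, idx = np.unique(data.groups, return_inverse=True)
    a, n = len(labels), len(data.values)
    if n <= a:
        raise ValueError(f"need n > number of groups (n={n}, groups={a})")

    grand = data.values.mean()
    group_means = np.array([data.values[idx == g].mean() for g in range(a)])
    counts = np.bincount(idx)
    ss_between = float(np.sum(counts * (group_means - grand) ** 2))
    ss_within = float(np.sum((data.values - group_means[idx]) ** 2))
    if ss_within == 0.0 and ss_between == 0.0:
        raise ValueError("all values identical: F statistic undefined")

    df1, df2 = a - 1, n - a
    if ss_within == 0.0:
        return FTestResult(np.inf, df1, df2, 0.0)
    f = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f, df1, df2))
    return FTestResult(float(f), df1, df2, p)


def ranksum_w(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test, W convention.

    W is the midrank sum of ``x`` minus ``n_x(n_x+1)/2`` (the Mann-Whitney
    U statistic of ``x``).  The p-value is exact for small untied samples
    and a tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def holm_adjust(p: Sequence[float]) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values, in the input order.

    Monotone (cumulative-max over the step-down sequence), capped at 1,
    and never below the raw p-values.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]
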
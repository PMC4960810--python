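"""Statistical procedures used in exposure comparisons.

Three small tools: Pearson correlation between two quantification methods
(e.g. fluorescence imaging vs LC/MS/MS), a paired two-tailed t-test on
log-transformed AUC values (the standard approach for exposure data, whose
ratios are more nearly log-normal), and a fold-ratio of group mean AUCs.

Natural logarithms are used throughout; the t statistic and p-value are
base-invariant and the fold change is reported on the natural scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "PairedTestResult",
    "pearson",
    "log_paired_ttest",
    "auc_fold_ratio",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson product-moment correlation with its two-sided p-value."""

    r: float
    p_value: float
    n: int

    def summary(self) -> str:
        return f"Pearson r = {self.r:.4f} (p = {self.p_value:.4g}, n = {self.n})"


@dataclass(frozen=True)
class PairedTestResult:
    """Paired two-tailed t-test on log-transformed values.

    ``mean_log_diff`` is mean(log b - log a); ``fold_change`` its exponential
    (the geometric-mean ratio b/a).  ``degenerate`` flags zero within-pair
    variance of the log-differences, where the t statistic is undefined.
    """

    t_stat: float
    df: int
    p_value: float
    mean_log_diff: float
    fold_change: float
    degenerate: bool = False

    def summary(self) -> str:
        if self.degenerate:
            return (
                f"paired t-test degenerate (zero within-pair variance); "
                f"fold change = {self.fold_change:.4g}"
            )
        return (
            f"paired t = {self.t_stat:.4f} (df = {self.df}, p = {self.p_value:.4g}); "
            f"fold change = {self.fold_change:.4g}"
        )


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation of two equally long series (n >= 3).

    The p-value is the two-sided probability from the t transform with n - 2
    degrees of freedom.  Constant input raises (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("series lengths differ")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=x.size)


def log_paired_ttest(a, b) -> PairedTestResult:
    """Two-tailed paired t-test on natural-log-transformed positive values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("series lengths differ")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("log transform requires strictly positive values")
    diffs = np.log(b) - np.log(a)
    mean_log_diff = float(diffs.mean())
    fold = math.exp(mean_log_diff)
    if np.allclose(diffs, diffs[0]):
        # zero within-pair variance: t undefined (or 0/0 for identical pairs)
        if mean_log_diff == 0.0:
            return PairedTestResult(
                t_stat=0.0,
                df=a.size - 1,
                p_value=1.0,
                mean_log_diff=0.0,
                fold_change=1.0,
                degenerate=True,
            )
        return PairedTestResult(
            t_stat=math.nan,
            df=a.size - 1,
            p_value=math.nan,
            mean_log_diff=mean_log_diff,
            fold_change=fold,
            degenerate=True,
        )
    res = sps.ttest_rel(np.log(b), np.log(a))
    return PairedTestResult(
        t_stat=float(res.statistic),
        df=a.size - 1,
        p_value=float(res.pvalue),
        mean_log_diff=mean_log_diff,
        fold_change=fold,
    )


def auc_fold_ratio(group_hi, group_lo) -> float:
    """Ratio of group mean AUCs (hi / lo); both groups strictly positive."""
    hi = np.asarray(group_hi, dtype=float)
    lo = np.asarray(group_lo, dtype=float)
    if hi.size == 0 or lo.size == 0:
        raise ValueError("empty group")
    if np.any(hi <= 0) or np.any(lo <= 0):
        raise ValueError("AUC values must be positive")
    denom = lo.mean()
    if denom == 0:
        raise ValueError("zero denominator")
    return float(hi.mean() / denom)
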
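"""The survey's statistics: Pearson correlation, chi-square test for trend,
t-tests, and the rounded-percentage convention used in reporting."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "pearson", "chi2_trend", "t_test", "percent"]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    test_name: str

    @property
    def r_squared(self) -> float:
        if self.test_name != "pearson":
            raise AttributeError("r_squared only defined for the Pearson test")
        return self.statistic**2


def pearson(x, y) -> TestResult:
    """Sample Pearson correlation with a two-tailed p from the t distribution
    (t = r * sqrt((n-2)/(1-r^2)) on n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in x or y")
    res = sps.pearsonr(x, y)
    return TestResult(float(res.statistic), float(n - 2), float(res.pvalue), "pearson")


def chi2_trend(counts, totals, scores) -> TestResult:
    """Cochran-Armitage chi-square test for trend in proportions (1 df).

    ``counts[i]`` successes out of ``totals[i]`` in category i, with strictly
    monotone numeric ``scores``. The statistic is
    ``(sum x_i s_i - p sum n_i s_i)^2 / (p(1-p)(sum n_i s_i^2 - (sum n_i s_i)^2 / N))``
    with ``p`` the pooled proportion; the p-value is the chi-square(1) upper
    tail. Proportional counts (no trend) give a statistic of exactly 0.
    """
    x = np.asarray(counts, dtype=float)
    n = np.asarray(totals, dtype=float)
    s = np.asarray(scores, dtype=float)
    if not (x.shape == n.shape == s.shape) or x.ndim != 1 or len(x) < 2:
        raise ValueError("counts, totals and scores must be equal-length vectors (>= 2)")
    d = np.diff(s)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("scores must be strictly monotone")
    if np.any(x < 0) or np.any(n < x):
        raise ValueError("need 0 <= counts <= totals")
    if x.sum() == 0:
        raise ValueError("all counts are zero")
    N = n.sum()
    p = x.sum() / N
    num = (x * s).sum() - p * (n * s).sum()
    den = p * (1 - p) * ((n * s * s).sum() - (n * s).sum() ** 2 / N)
    if den == 0:
        raise ValueError("degenerate trend test (no variance in scores)")
    stat = num**2 / den
    return TestResult(float(stat), 1.0, float(sps.chi2.sf(stat, 1)), "chi2_trend")


def t_test(sample, mu: float | None = None, sample_b=None) -> TestResult:
    """One-sample t-test against ``mu``, or Welch's two-sample t-test.

    Exactly one of ``mu`` and ``sample_b`` must be given; p-values are
    two-tailed.
    """
    a = np.asarray(sample, dtype=float)
    if len(a) < 2:
        raise ValueError("need at least 2 observations per sample")
    if (mu is None) == (sample_b is None):
        raise ValueError("supply exactly one of mu (one-sample) or sample_b (two-sample)")
    if mu is not None:
        if np.var(a, ddof=1) == 0:
            raise ValueError("degenerate (zero-variance) sample")
        res = sps.ttest_1samp(a, popmean=mu)
        return TestResult(float(res.statistic), float(res.df), float(res.pvalue), "t_one_sample")
    b = np.asarray(sample_b, dtype=float)
    if len(b) < 2:
        raise ValueError("need at least 2 observations per sample")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("degenerate (zero-variance) samples")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue), "t_welch")


def percent(numerator: int, denominator: int) -> int:
    """round(100 * numerator / denominator) with half-away-from-zero rounding.

    This convention reproduces the printed percentages of the source tables
    (e.g. 48/290 -> 17, 100/124 -> 81).
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("need 0 <= numerator <= denominator")
    value = 100 * numerator / denominator
    return int(np.floor(value + 0.5))
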
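"""Statistical layer: t-tests, ANOVA, BH correction, exact binomial direction
tests, and simple linear regression with R^2.

Conventions follow the study's reporting: "Student's" means equal-variance by
default (Welch by flag); the binomial direction test is one-sided toward the
observed majority under a fair-coin null; BH is the step-up FDR procedure.
Degenerate inputs with no variance anywhere use the p = 1 convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "RegressionResult",
    "ClusterSummary",
    "unpaired_t",
    "bh_adjust",
    "one_way_anova",
    "binomial_direction_test",
    "linear_regression_r2",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    adjusted_p: float | None = None


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass(frozen=True)
class ClusterSummary:
    """Direction-of-change summary for one functional cluster."""

    cluster: str
    n_members: int
    n_increased: int
    n_decreased: int
    n_ties: int
    majority_direction: str
    p_value: float


def unpaired_t(x, y, equal_variance: bool = True) -> TestResult:
    """Two-sample t-test (Student's by default, Welch by flag), two-sided."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return TestResult(0.0, 1.0, (x.size, y.size))
        return TestResult(np.sign(x.mean() - y.mean()) * np.inf, 0.0, (x.size, y.size))
    t, p = sps.ttest_ind(x, y, equal_var=equal_variance)
    return TestResult(float(t), float(p), (x.size, y.size))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def one_way_anova(*groups) -> TestResult:
    """One-way ANOVA F test across two or more groups."""
    arrays = [np.asarray(g, float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate(arrays)
    if pooled.var() == 0.0:
        return TestResult(0.0, 1.0, tuple(a.size for a in arrays))
    f, p = sps.f_oneway(*arrays)
    return TestResult(float(f), float(p), tuple(a.size for a in arrays))


def binomial_direction_test(
    n_majority: int, n_total: int, two_sided: bool = False
) -> float:
    """Exact binomial test of a directional majority under a fair-coin null.

    One-sided (default): P(X >= n_majority | n_total, 1/2), the probability
    of at least as extreme a majority toward the observed direction.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_majority <= n_total:
        raise ValueError("n_majority must lie in [0, n_total]")
    if two_sided:
        return float(sps.binomtest(n_majority, n_total, 0.5, alternative="two-sided").pvalue)
    return float(sps.binom.sf(n_majority - 1, n_total, 0.5))


def linear_regression_r2(x, y) -> RegressionResult:
    """Ordinary least squares y ~ x with R^2 and a two-sided slope test."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("regression needs n >= 3 points")
    if np.ptp(x) == 0.0:
        raise ValueError("x is constant; slope undefined")
    if np.ptp(y) == 0.0:
        # flat response: zero slope explains everything and nothing
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, int(x.size))
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )
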
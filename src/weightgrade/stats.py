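"""Descriptive summaries and grading-model comparison statistics.

Dispersion is summarised by the coefficient of variation CV = SD/mean x 100
(sample SD, n-1 denominator). CV equality between two groups is tested with
Forkman's (2008) approximate F test for normally distributed data; central
tendency with one-way ANOVA plus Fisher's LSD post hoc t-tests on the
pooled mean-square error; effect sizes with Cohen's d on the pooled SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import DomainError


@dataclass(frozen=True)
class GroupSummary:
    """Five-number descriptive block for one group of one variable."""

    n: int
    mean: float
    sd: float
    median: float
    range: tuple[float, float]
    cv: float  # percent


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two- or k-group comparison."""

    statistic: float
    df: tuple
    p_value: float
    effect_size: float | None = None
    percent_reduction: float | None = None
    method: str = ""
    extra: dict = field(default_factory=dict)


def summarize(values) -> GroupSummary:
    """Mean, sample SD, median, range and CV of a vector."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DomainError(f"need n >= 2 for a summary, got {x.size}")
    mean = float(x.mean())
    if mean == 0.0:
        raise DomainError("CV undefined for zero mean")
    sd = float(x.std(ddof=1))
    return GroupSummary(
        n=int(x.size),
        mean=mean,
        sd=sd,
        median=float(np.median(x)),
        range=(float(x.min()), float(x.max())),
        cv=sd / mean * 100.0,
    )


def cv_reduction(cv_ref: float, cv_alt: float) -> float:
    """Percent reduction of a CV relative to a reference CV."""
    if cv_ref <= 0:
        raise DomainError(f"reference CV must be > 0, got {cv_ref}")
    return (cv_ref - cv_alt) / cv_ref * 100.0


def _forkman_term(x: np.ndarray) -> tuple[float, int]:
    n = x.size
    c = x.std(ddof=1) / x.mean()
    return c * c / (1.0 + c * c * (n - 1) / n), n


def compare_cv(sample_a, sample_b) -> TestResult:
    """Forkman's approximate F test for equality of two coefficients of variation.

    F is the ratio of the groups' shrunken squared CV estimates, referred to
    F(n_a - 1, n_b - 1); the p-value is two-sided.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    ta, na = _forkman_term(a)
    tb, nb = _forkman_term(b)
    if tb == 0.0:
        raise DomainError("second sample has zero CV; F undefined")
    f = ta / tb
    dfa, dfb = na - 1, nb - 1
    p = 2.0 * min(sps.f.cdf(f, dfa, dfb), sps.f.sf(f, dfa, dfb))
    return TestResult(
        statistic=float(f),
        df=(dfa, dfb),
        p_value=float(min(p, 1.0)),
        method="forkman_approximate_F",
    )


def anova_lsd(groups) -> TestResult:
    """One-way ANOVA with Fisher's LSD post hoc pairwise comparisons.

    LSD p-values are unadjusted pairwise t-tests on the pooled within-group
    MSE with N - k degrees of freedom, stored in ``extra['lsd']`` keyed by
    group-index pair.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise DomainError("ANOVA needs at least two groups")
    if any(g.size < 2 for g in gs):
        raise DomainError("each group needs n >= 2")
    ns = np.array([g.size for g in gs])
    means = np.array([g.mean() for g in gs])
    N, k = int(ns.sum()), len(gs)
    grand = float(np.concatenate(gs).mean())
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(gs, means)))
    df_b, df_w = k - 1, N - k
    msb, msw = ssb / df_b, ssw / df_w
    if msw == 0.0:
        f = np.inf if msb > 0 else 0.0
        p = 0.0 if msb > 0 else 1.0
    else:
        f = msb / msw
        p = float(sps.f.sf(f, df_b, df_w))
    lsd = {}
    for i in range(k):
        for j in range(i + 1, k):
            if msw == 0.0:
                t = np.inf if means[i] != means[j] else 0.0
                pij = 0.0 if means[i] != means[j] else 1.0
            else:
                se = np.sqrt(msw * (1.0 / ns[i] + 1.0 / ns[j]))
                t = (means[i] - means[j]) / se
                pij = float(2.0 * sps.t.sf(abs(t), df_w))
            lsd[(i, j)] = {"t": float(t), "p": pij}
    return TestResult(
        statistic=float(f),
        df=(df_b, df_w),
        p_value=float(p),
        method="one_way_anova",
        extra={"lsd": lsd, "msw": msw},
    )


def cohens_d(sample_a, sample_b) -> float:
    """Cohen's d = (mean_a - mean_b) / pooled SD, pooled over n_a + n_b - 2 df.

    The second argument is the reference group, so a positive d means the
    first group's mean is higher.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("Cohen's d needs n >= 2 in both samples")
    sp = pooled_sd(a.std(ddof=1), a.size, b.std(ddof=1), b.size)
    if sp == 0.0:
        raise DomainError("zero pooled SD; d undefined")
    return float((a.mean() - b.mean()) / sp)


def pooled_sd(sd_a: float, n_a: int, sd_b: float, n_b: int) -> float:
    """Two-sample pooled SD from group SDs and sizes (n_a + n_b - 2 df)."""
    return float(
        np.sqrt(((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2))
    )


def cohens_d_from_moments(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> float:
    """Cohen's d computed from printed summary moments."""
    sp = pooled_sd(sd_a, n_a, sd_b, n_b)
    if sp == 0.0:
        raise DomainError("zero pooled SD; d undefined")
    return float((mean_a - mean_b) / sp)


def pearson(x, y) -> TestResult:
    """Sample Pearson correlation with a two-sided t-based p-value."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size or xv.size < 3:
        raise DomainError("Pearson correlation needs n >= 3 equal-length vectors")
    if xv.std() == 0.0 or yv.std() == 0.0:
        raise DomainError("correlation undefined for a constant vector")
    res = sps.pearsonr(xv, yv)
    return TestResult(
        statistic=float(res.statistic),
        df=(xv.size - 2,),
        p_value=float(res.pvalue),
        method="pearson",
    )
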
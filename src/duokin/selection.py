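"""Goodness-of-fit and between-model statistics.

AIC in the least-squares form, nested F-tests with the tabulated 5% critical
value, the coefficient of variation of distribution volumes pooled across
regions and subjects, and cross-model agreement (least-squares regression
plus Spearman rank correlation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import ValidationError

__all__ = [
    "aic",
    "FTestResult",
    "f_test_nested",
    "f_critical_value",
    "cov_across",
    "AgreementReport",
    "compare_estimates",
    "percent_better_fit",
]


def aic(rss: float, n: int, p: int) -> float:
    """Least-squares Akaike information criterion, ``n ln(RSS/n) + 2p``.

    ``n`` is the number of frames and ``p`` the number of free parameters.
    A zero RSS (exact interpolation) is degenerate and returns -inf.
    """
    if n <= p:
        raise ValidationError("AIC requires more observations than parameters")
    if rss < 0:
        raise ValidationError("RSS must be non-negative")
    if rss == 0.0:
        warnings.warn("RSS is zero; AIC degenerate (-inf)")
        return -np.inf
    return float(n * np.log(rss / n) + 2 * p)


@dataclass(frozen=True)
class FTestResult:
    """Nested-model F statistic with its reference distribution."""

    f: float
    df1: int  # p_full - p_reduced
    df2: int  # n - p_full
    critical_value: float  # upper 5% quantile of F(df1, df2)
    p_value: float
    reduced_is_adequate: bool  # F below the 5% critical value


def f_critical_value(df1: int, df2: int, alpha: float = 0.05) -> float:
    """Upper-tail critical value of the F distribution."""
    return float(stats.f.ppf(1.0 - alpha, df1, df2))


def f_test_nested(
    rss_full: float,
    p_full: int,
    rss_reduced: float,
    p_reduced: int,
    n: int,
    alpha: float = 0.05,
) -> FTestResult:
    """Extra-sum-of-squares F-test of a reduced model against the full one.

    F = [(RSS_r - RSS_f) / (p_f - p_r)] / [RSS_f / (n - p_f)] with
    df = (p_f - p_r, n - p_f).  If the optimizer left the reduced model with
    a smaller RSS than the full one, F is clamped at 0 with a warning.
    """
    if p_reduced >= p_full:
        raise ValidationError("reduced model must have fewer parameters")
    if n <= p_full:
        raise ValidationError("need more observations than full-model parameters")
    if rss_full <= 0:
        raise ValidationError("full-model RSS must be positive")
    df1, df2 = p_full - p_reduced, n - p_full
    if rss_reduced < rss_full:
        warnings.warn("reduced-model RSS below full-model RSS; F clamped at 0")
        f = 0.0
    else:
        f = ((rss_reduced - rss_full) / df1) / (rss_full / df2)
    crit = f_critical_value(df1, df2, alpha)
    p_value = float(stats.f.sf(f, df1, df2))
    return FTestResult(
        f=float(f),
        df1=df1,
        df2=df2,
        critical_value=crit,
        p_value=p_value,
        reduced_is_adequate=f < crit,
    )


def cov_across(values) -> float:
    """Coefficient of variation in percent: sample SD / mean * 100.

    Pooled over all regions and subjects; requires at least two finite
    values and a non-zero mean.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValidationError("COV needs at least two finite values")
    mean = float(np.mean(v))
    if mean == 0.0:
        raise ValidationError("COV undefined for zero mean")
    return float(np.std(v, ddof=1) / mean * 100.0)


@dataclass(frozen=True)
class AgreementReport:
    """Agreement between two paired distribution-volume vectors."""

    slope: float
    intercept: float
    r_squared: float
    spearman_rho: float
    spearman_p: float
    n: int
    rank_degenerate: bool  # a constant vector makes the rank correlation undefined


def compare_estimates(vt_a, vt_b) -> AgreementReport:
    """Least-squares regression and Spearman correlation of paired volumes.

    ``vt_b`` is regressed on ``vt_a``.  Pairs with a non-finite member are
    dropped; at least three pairs are required.
    """
    a = np.asarray(vt_a, dtype=float)
    b = np.asarray(vt_b, dtype=float)
    if a.size != b.size:
        raise ValidationError("paired vectors must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValidationError("need at least three finite pairs")
    degenerate = bool(np.all(a == a[0]) or np.all(b == b[0]))
    if degenerate:
        warnings.warn("constant vector; rank correlation undefined")
        rho, rho_p = np.nan, np.nan
        slope, intercept, r2 = np.nan, np.nan, np.nan
    else:
        lin = stats.linregress(a, b)
        slope, intercept, r2 = float(lin.slope), float(lin.intercept), float(lin.rvalue**2)
        sp = stats.spearmanr(a, b)
        rho, rho_p = float(sp.statistic), float(sp.pvalue)
    return AgreementReport(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        spearman_rho=rho,
        spearman_p=rho_p,
        n=int(a.size),
        rank_degenerate=degenerate,
    )


def percent_better_fit(aic_reduced, aic_full) -> float:
    """Percentage of regions where the reduced model has strictly lower AIC.

    Ties count as "not better"; the result is rounded half-up to one
    decimal, matching the reporting convention of the comparison tables.
    """
    red = np.asarray(aic_reduced, dtype=float)
    full = np.asarray(aic_full, dtype=float)
    if red.size != full.size or red.size == 0:
        raise ValidationError("AIC vectors must be non-empty and paired")
    frac = np.mean(red < full)
    return float(np.floor(1000.0 * frac + 0.5) / 10.0)
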
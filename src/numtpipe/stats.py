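"""Accumulation-rate estimation and cohort statistics.

The longitudinal model is ordinary least squares, Y = β0 + β1·X + ε,
with Y the (optionally group-median-normalized) Numt count and X days in
culture; β1 is the numtogenesis rate (reported per day and per 10 days).
Slopes between two arms are compared by the ANOVA F-test on the
day×group interaction in a pooled model.  Cross-sectional effect sizes
use Hedge's g with the small-sample correction J = 1 − 3/(4n − 9), and
age-at-death associations are per-cognitive-stratum OLS fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "RateFit", "EffectSize", "fit_rate", "normalize_by_group_median",
    "compare_slopes", "fold_change", "hedges_g", "assign_age_group",
    "age_association",
]


@dataclass(frozen=True)
class RateFit:
    intercept: float
    slope: float
    slope_se: float
    ci_low: float
    ci_high: float
    r_squared: float
    pvalue: float
    n: int

    @property
    def rate_per_10_days(self) -> float:
        return 10.0 * self.slope


@dataclass(frozen=True)
class EffectSize:
    g: float
    mean_a: float
    mean_b: float
    pooled_sd: float
    n_a: int
    n_b: int
    correction: float


def fit_rate(x, y, alpha: float = 0.05) -> RateFit:
    """OLS fit of counts on time with a t-based confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("at least 3 points are required")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    lo, hi = res.conf_int(alpha=alpha)[1]
    return RateFit(
        intercept=float(res.params[0]), slope=float(res.params[1]),
        slope_se=float(res.bse[1]), ci_low=float(lo), ci_high=float(hi),
        r_squared=float(res.rsquared), pvalue=float(res.pvalues[1]),
        n=int(x.size),
    )


def normalize_by_group_median(counts, groups) -> np.ndarray:
    """Divide each count by the median of its group.

    A group with median 0 falls back to a divisor of 1 (with a warning) so
    all-zero early series survive normalization unchanged.
    """
    counts = np.asarray(counts, dtype=float)
    groups = np.asarray(groups)
    if counts.size != groups.size:
        raise ValueError("counts and groups must have equal length")
    out = np.empty_like(counts)
    for g in pd.unique(groups):
        sel = groups == g
        med = float(np.median(counts[sel]))
        if med == 0:
            warnings.warn(f"group {g!r} has median 0; dividing by 1", stacklevel=2)
            med = 1.0
        out[sel] = counts[sel] / med
    return out


def compare_slopes(
    x_a, y_a, x_b, y_b, labels: tuple[str, str] = ("A", "B")
) -> tuple[float, float]:
    """ANOVA F-test for equality of two regression slopes.

    Fits the pooled model Y ~ X + group + X:group and tests the
    interaction term; equivalent to the nested-model ANOVA of the
    additive model against the full model.  Returns (F, p).
    """
    if labels[0] == labels[1]:
        raise ValueError("groups must carry distinct labels")
    x = np.concatenate([np.asarray(x_a, float), np.asarray(x_b, float)])
    y = np.concatenate([np.asarray(y_a, float), np.asarray(y_b, float)])
    g = np.concatenate([np.zeros(len(np.atleast_1d(x_a))), np.ones(len(np.atleast_1d(x_b)))])
    design = np.column_stack([np.ones_like(x), x, g, x * g])
    full = sm.OLS(y, design).fit()
    reduced = sm.OLS(y, design[:, :3]).fit()
    df_resid = full.df_resid
    if df_resid <= 0:
        raise ValueError("not enough points to test the interaction")
    f = (reduced.ssr - full.ssr) / (full.ssr / df_resid)
    p = float(sps.f.sf(f, 1, df_resid))
    return float(f), p


def fold_change(a: float, b: float) -> float:
    """Ratio a/b rounded half-even to one decimal (printed style)."""
    if b <= 0:
        raise ValueError("denominator must be positive")
    return round(a / b, 1)


def hedges_g(group_a, group_b) -> EffectSize:
    """Hedge's g: bias-corrected standardized mean difference.

    g = J · (mean_A − mean_B) / s_pooled with J = 1 − 3/(4(n_A+n_B) − 9).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2))
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    j = 1.0 - 3.0 / (4.0 * (a.size + b.size) - 9.0)
    g = j * (a.mean() - b.mean()) / pooled
    return EffectSize(
        g=float(g), mean_a=float(a.mean()), mean_b=float(b.mean()),
        pooled_sd=float(pooled), n_a=int(a.size), n_b=int(b.size),
        correction=float(j),
    )


def assign_age_group(age: float) -> str:
    """Age-at-death stratum: <85, 85–92, or ≥93 years."""
    if age <= 0:
        raise ValueError("age must be positive")
    if age < 85:
        return "<85"
    if age < 93:
        return "85-92"
    return ">=93"


def age_association(
    counts, ages, strata=None, min_n: int = 3
) -> pd.DataFrame:
    """OLS of Numt count on age at death, per cognitive stratum.

    Returns one row per stratum with slope per year and per decade, r²,
    p-value and n.  Strata with fewer than ``min_n`` samples are skipped
    with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    ages = np.asarray(ages, dtype=float)
    strata = np.asarray(strata) if strata is not None else np.full(counts.size, "all")
    rows = []
    for s in pd.unique(strata):
        sel = strata == s
        if sel.sum() < min_n:
            warnings.warn(f"stratum {s!r} has n < {min_n}; skipped", stacklevel=2)
            continue
        if np.ptp(counts[sel]) == 0:
            rows.append(dict(stratum=s, slope_per_year=0.0, slope_per_decade=0.0,
                             r_squared=0.0, pvalue=1.0, n=int(sel.sum())))
            continue
        fit = fit_rate(ages[sel], counts[sel])
        rows.append(
            dict(stratum=s, slope_per_year=fit.slope,
                 slope_per_decade=10.0 * fit.slope, r_squared=fit.r_squared,
                 pvalue=fit.pvalue, n=fit.n)
        )
    return pd.DataFrame(
        rows, columns=["stratum", "slope_per_year", "slope_per_decade",
                       "r_squared", "pvalue", "n"],
    )
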
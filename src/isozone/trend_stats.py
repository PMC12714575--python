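"""Inferential helpers: Pearson correlation with CI, OLS trend, one-way ANOVA.

Thin, validated wrappers over scipy; results come back as small dataclasses
so downstream reports carry n, effect size and uncertainty together.  For a
simple (one-predictor) regression R² equals the squared Pearson r, which the
result object exposes explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["TrendResult", "AnovaResult", "pearson_with_ci", "fit_linear_trend", "one_way_anova"]


@dataclass(frozen=True)
class TrendResult:
    n: int
    slope: float
    intercept: float
    r2: float
    pearson_r: float
    r_ci: tuple[float, float]
    p_value: float


@dataclass(frozen=True)
class AnovaResult:
    k_groups: int
    f_stat: float
    df_between: int
    df_within: int
    p_value: float


def _clean_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 finite paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation/trend undefined")
    return x, y


def pearson_with_ci(x, y, ci_level: float = 0.95) -> TrendResult:
    """Pearson r with two-sided t-test p-value and Fisher-z confidence interval.

    Slope/intercept of the companion least-squares line are included so the
    result doubles as a trend summary.
    """
    x, y = _clean_xy(x, y)
    r, p = stats.pearsonr(x, y)
    # Fisher z interval
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(x.size - 3)
    zcrit = stats.norm.ppf(0.5 + ci_level / 2.0)
    lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    lr = stats.linregress(x, y)
    return TrendResult(
        n=int(x.size),
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        r2=float(r * r),
        pearson_r=float(r),
        r_ci=(float(lo), float(hi)),
        p_value=float(p),
    )


def fit_linear_trend(x, y) -> TrendResult:
    """Ordinary least squares of y on x: slope, intercept, R², slope p-value."""
    x, y = _clean_xy(x, y)
    lr = stats.linregress(x, y)
    r = float(lr.rvalue)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(x.size - 3)
    zcrit = stats.norm.ppf(0.975)
    return TrendResult(
        n=int(x.size),
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        r2=r * r,
        pearson_r=r,
        r_ci=(float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se))),
        p_value=float(lr.pvalue),
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA across ≥ 2 groups (each n ≥ 2)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    if all(np.ptp(a) == 0 for a in arrays) and len({float(a[0]) for a in arrays}) == 1:
        # identical constant groups: F = 0 / p = 1 rather than scipy's NaN
        n_tot = sum(a.size for a in arrays)
        return AnovaResult(len(arrays), 0.0, len(arrays) - 1, n_tot - len(arrays), 1.0)
    f, p = stats.f_oneway(*arrays)
    n_tot = sum(a.size for a in arrays)
    return AnovaResult(
        k_groups=len(arrays),
        f_stat=float(f),
        df_between=len(arrays) - 1,
        df_within=n_tot - len(arrays),
        p_value=float(p),
    )
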
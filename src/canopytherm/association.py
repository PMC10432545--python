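"""Correlation and regression analysis of patch metrics vs cooling rate.

Pearson product-moment correlations with two-tailed significance, simple
ordinary-least-squares fits with R^2 and the Durbin-Watson residual
autocorrelation statistic, and backward stepwise elimination of predictors
by p-value. Fits are delegated to scipy/statsmodels; the Durbin-Watson
statistic is computed definitionally,

    DW = sum_t (e_t - e_{t-1})^2 / sum_t e_t^2,

on residuals in the input row order — reordering rows changes DW, so the
orientation of the table matters and is preserved everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "OLSFit",
    "StepwiseResult",
    "pearson",
    "ols_simple",
    "durbin_watson",
    "backward_stepwise",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class OLSFit:
    slope: float
    intercept: float
    r_squared: float
    residuals: np.ndarray     # in input row order
    durbin_watson: float
    slope_p: float


@dataclass(frozen=True)
class StepwiseResult:
    retained: tuple
    removed: tuple            # ((name, p_at_removal), ...) in removal order
    final_fits: Mapping       # name -> OLSFit (simple fit per retained predictor)


def _as_1d(name: str, v) -> np.ndarray:
    a = np.asarray(v, dtype=float).ravel()
    if np.isnan(a).any():
        raise ValueError(f"{name} contains NaN")
    return a


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation with two-tailed p from the t transform
    t = r sqrt((n-2)/(1-r^2))."""
    x, y = _as_1d("x", x), _as_1d("y", y)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in x or y")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue),
                             n=x.size)


def durbin_watson(residuals) -> float:
    """First-order residual autocorrelation statistic; ~2 means none.

    Computed on the residuals in the order given.
    """
    e = _as_1d("residuals", residuals)
    if e.size < 2:
        raise ValueError("need at least 2 residuals")
    denom = float(np.sum(e * e))
    if denom == 0:
        raise ValueError("all-zero residuals: DW undefined")
    return float(np.sum(np.diff(e) ** 2) / denom)


def ols_simple(y, x) -> OLSFit:
    """Simple least-squares regression of y on x.

    Residuals keep the input row order. For constant y the fit degenerates to
    slope 0 / intercept y; R^2 is defined as 0 there (SStot = 0 convention)
    and DW is NaN — both logged.
    """
    y, x = _as_1d("y", y), _as_1d("x", x)
    if y.size != x.size:
        raise ValueError(f"length mismatch: {y.size} vs {x.size}")
    if y.size < 3:
        raise ValueError("need n >= 3")
    if np.var(x) == 0:
        raise ValueError("degenerate predictor: zero variance")
    if np.var(y) == 0:
        logger.warning("constant response: slope 0, R^2 := 0, DW undefined")
        return OLSFit(slope=0.0, intercept=float(y[0]), r_squared=0.0,
                      residuals=np.zeros_like(y), durbin_watson=np.nan,
                      slope_p=1.0)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    resid = np.asarray(fit.resid)
    return OLSFit(slope=float(fit.params[1]), intercept=float(fit.params[0]),
                  r_squared=float(fit.rsquared), residuals=resid,
                  durbin_watson=durbin_watson(resid),
                  slope_p=float(fit.pvalues[1]))


def backward_stepwise(y, predictors: Mapping, alpha: float = 0.05
                      ) -> StepwiseResult:
    """Backward elimination on the multiple OLS fit.

    Repeatedly drop the predictor with the largest p-value above ``alpha``
    and refit, until every remaining predictor is significant (or none are
    left). Deterministic given the rule; the per-predictor simple fits of the
    retained set are reported as the final models.
    """
    if not predictors:
        raise ValueError("need at least one predictor")
    y = _as_1d("y", y)
    cols = {name: _as_1d(name, v) for name, v in predictors.items()}
    for name, v in cols.items():
        if v.size != y.size:
            raise ValueError(f"predictor {name!r} length mismatch")
    names = list(cols)
    removed = []
    while names:
        X = sm.add_constant(np.column_stack([cols[n] for n in names]))
        fit = sm.OLS(y, X).fit()
        pvals = dict(zip(names, fit.pvalues[1:]))
        worst = max(pvals, key=pvals.get)
        if pvals[worst] <= alpha:
            break
        logger.info("stepwise: removing %s (p = %.4f > %.2f)",
                    worst, pvals[worst], alpha)
        removed.append((worst, float(pvals[worst])))
        names.remove(worst)
    final = {n: ols_simple(y, cols[n]) for n in names}
    return StepwiseResult(retained=tuple(names), removed=tuple(removed),
                          final_fits=final)
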
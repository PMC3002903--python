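"""Moment-relationship models over the per-gene moment table.

Two trends characterize the signal stratum: a linear trend of log10 CV on
mean log expression (CV decreases with the mean), and a quadratic trend of
kurtosis on skewness, K = c0 + c1*S + c2*S**2, which lies above the
theoretical attainability boundary K = S**2 + 1.  Both are ordinary least
squares; the reported standard errors are plain OLS SEs, and residual
diagnostics quantify (rather than correct) the heteroscedasticity that makes
those intervals approximate.  The noise stratum is summarized with loess
curves instead of polynomial fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .gof import STAT_AD, bootstrap_gof
from .fitting import DistFamily

__all__ = [
    "TrendFit",
    "fit_log_cv_vs_mean",
    "fit_kurt_vs_skew",
    "loess_smooth",
    "residual_diagnostics",
    "spearman_mean_sd",
]

MODEL_LINEAR_LOGCV_MEAN = "linear_logcv_mean"
MODEL_QUADRATIC_KURT_SKEW = "quadratic_kurt_skew"


@dataclass
class TrendFit:
    model: str
    coefficients: np.ndarray  # intercept first
    standard_errors: np.ndarray
    r_squared: float
    f_pvalue: float
    n: int
    residuals: np.ndarray
    fitted: np.ndarray
    exog: np.ndarray  # regressor columns (without intercept)
    n_excluded: int = 0
    bound_violations: int | None = None

    def summary_frame(self) -> pd.DataFrame:
        names = (
            ["intercept", "slope"]
            if self.model == MODEL_LINEAR_LOGCV_MEAN
            else ["constant", "linear", "quadratic"]
        )
        return pd.DataFrame(
            {"coefficient": self.coefficients, "se": self.standard_errors}, index=names
        )


def _ols(y: np.ndarray, X: np.ndarray, model: str) -> TrendFit:
    res = sm.OLS(y, sm.add_constant(X)).fit()
    return TrendFit(
        model=model,
        coefficients=np.asarray(res.params, dtype=float),
        standard_errors=np.asarray(res.bse, dtype=float),
        r_squared=float(res.rsquared),
        f_pvalue=float(res.f_pvalue),
        n=int(res.nobs),
        residuals=np.asarray(res.resid, dtype=float),
        fitted=np.asarray(res.fittedvalues, dtype=float),
        exog=X,
    )


def fit_log_cv_vs_mean(moment_df: pd.DataFrame, signal_mask=None) -> TrendFit:
    """OLS of log10(CV) on the mean, over the signal stratum only.

    Genes with non-positive or undefined CV are excluded (the count is
    recorded on the fit).  Needs at least 3 usable genes.
    """
    sub = moment_df if signal_mask is None else moment_df[np.asarray(signal_mask)]
    usable = sub[(sub["cv"] > 0) & np.isfinite(sub["cv"])]
    n_excluded = len(sub) - len(usable)
    if len(usable) < 3:
        raise ValueError(f"only {len(usable)} genes with positive CV; need >= 3")
    fit = _ols(
        np.log10(usable["cv"].to_numpy()),
        usable["mean"].to_numpy()[:, None],
        MODEL_LINEAR_LOGCV_MEAN,
    )
    fit.n_excluded = n_excluded
    return fit


def fit_kurt_vs_skew(moment_df: pd.DataFrame, signal_mask=None) -> TrendFit:
    """OLS of kurtosis on (1, S, S^2) over the signal stratum.

    Also counts violations of the attainability bound K >= S**2 + 1, which
    is zero for any moments produced by the plug-in estimators.
    """
    sub = moment_df if signal_mask is None else moment_df[np.asarray(signal_mask)]
    usable = sub[np.isfinite(sub["skewness"]) & np.isfinite(sub["kurtosis"])]
    if len(usable) < 4:
        raise ValueError(f"only {len(usable)} usable genes; need >= 4")
    s = usable["skewness"].to_numpy()
    k = usable["kurtosis"].to_numpy()
    fit = _ols(k, np.column_stack([s, s**2]), MODEL_QUADRATIC_KURT_SKEW)
    fit.bound_violations = int(np.sum(k < s**2 + 1.0 - 1e-9))
    return fit


def loess_smooth(x, y, span: float = 0.75, grid_size: int = 100):
    """Local linear (degree-1) regression with tricube weights on a grid.

    Evaluates the smooth at `grid_size` evenly spaced points over the range
    of x; `span` is the fraction of points in each local window.  Used for
    the noise-stratum moment trends.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10:
        raise ValueError("loess needs at least 10 points")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    grid = np.linspace(x.min(), x.max(), grid_size)
    smoothed = sm.nonparametric.lowess(
        y, x, frac=span, it=0, xvals=grid, is_sorted=False
    )
    return grid, np.asarray(smoothed, dtype=float)


def residual_diagnostics(
    trend_fit: TrendFit,
    covariates: dict[str, np.ndarray],
    gof_B: int = 200,
    seed=0,
) -> pd.DataFrame:
    """Heteroscedasticity and normality diagnostics of a trend fit.

    For each named covariate, the Pearson correlation of |residuals| with
    the covariate (and its p-value); plus a parametric-bootstrap AD p-value
    for normality of the residuals, repeated on every row for convenience.
    """
    resid = trend_fit.residuals
    normality = bootstrap_gof(resid, DistFamily.NORMAL, STAT_AD, B=gof_B, seed=seed)
    rows = []
    for name, cov in covariates.items():
        cov = np.asarray(cov, dtype=float)
        rho, rho_p = stats.pearsonr(np.abs(resid), cov)
        rows.append(
            {
                "covariate": name,
                "rho_abs_resid": float(rho),
                "rho_p_value": float(rho_p),
                "normality_p": normality.p_value,
            }
        )
    return pd.DataFrame(rows)


def spearman_mean_sd(moment_df: pd.DataFrame) -> float:
    """Spearman rank correlation (mid-rank ties) of per-gene mean vs SD."""
    if len(moment_df) < 3:
        raise ValueError("need >= 3 genes")
    mean = moment_df["mean"].to_numpy()
    sd = moment_df["sd"].to_numpy()
    if np.ptp(mean) == 0.0 or np.ptp(sd) == 0.0:
        return float("nan")
    rho, _ = stats.spearmanr(mean, sd)
    return float(rho)
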
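"""Baseline survival machinery.

Kaplan-Meier survival and censoring (reverse-KM) curves, Cox proportional
hazards fitting with optional delayed entry, the centered prognostic index
PI = (X - Xbar)' beta_hat, and the scaled-Schoenfeld screen for a
time-varying covariate effect.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from . import cox
from .stepfun import StepFunction

__all__ = [
    "CoxFit",
    "CensoringCurve",
    "km_estimate",
    "censoring_km",
    "fit_cox",
    "prognostic_index",
    "tv_effect_test",
    "hr_table",
]


def _validate_times(times, status):
    times = np.asarray(times, dtype=float)
    status = np.asarray(status)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times <= 0):
        raise ValueError("times must be strictly positive")
    if not np.isin(status, (0, 1)).all():
        raise ValueError("status must be 0/1")
    return times, status.astype(int)


def km_estimate(times, status) -> StepFunction:
    """Product-limit survivor estimate (ties drop simultaneously)."""
    times, status = _validate_times(times, status)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=status)
    sf = kmf.survival_function_
    knots = sf.index.to_numpy(dtype=float)
    vals = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = knots > 0
    return StepFunction(knots=knots[keep], values=vals[keep], initial=1.0)


class CensoringCurve(NamedTuple):
    curve: StepFunction
    median_followup: float


def censoring_km(times, status) -> CensoringCurve:
    """Reverse Kaplan-Meier: the censoring survivor function G.

    Treats censorings as the event of interest; the median of the curve is
    the standard "median follow-up" summary.
    """
    times, status = _validate_times(times, status)
    curve = km_estimate(times, 1 - status)
    return CensoringCurve(curve, curve.quantile_crossing(0.5))


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model."""

    beta: pd.Series
    covariance: pd.DataFrame
    baseline_cumhaz: StepFunction
    loglik: float
    n: int
    n_events: int
    x_mean: pd.Series
    _engine: cox.PartialLikelihoodFit

    @property
    def columns(self) -> list[str]:
        return list(self.beta.index)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.covariance.to_numpy())), index=self.beta.index)

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        return X[self.columns].to_numpy() @ self.beta.to_numpy()

    def predict_survival(self, x: dict | pd.Series, t) -> np.ndarray:
        """S(t | x) = exp(-H0(t) * exp(x' beta)) (uncentered baseline)."""
        lp = sum(self.beta[c] * float(pd.Series(x)[c]) for c in self.columns)
        return np.exp(-np.asarray(self.baseline_cumhaz(t)) * np.exp(lp))


def fit_cox(
    cohort: pd.DataFrame,
    columns: Sequence[str],
    entry_times=None,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> CoxFit:
    """Fit a Cox PH model by Newton-Raphson (Breslow ties).

    ``entry_times`` enables delayed-entry (left-truncated) fits.  The
    covariance is the inverse observed information.
    """
    columns = list(columns)
    missing = [c for c in columns if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks columns: {missing}")
    times, status = _validate_times(cohort["time"], cohort["status"])
    entry = np.zeros(len(cohort)) if entry_times is None else np.asarray(entry_times, float)
    X = cohort[columns].to_numpy(dtype=float)
    fit = cox.fit_partial_likelihood(
        entry, times, status, X, names=columns, tol=tol, max_iter=max_iter
    )
    te, dh = fit.baseline(0)
    baseline = StepFunction(knots=te, values=np.cumsum(dh), initial=0.0)
    return CoxFit(
        beta=pd.Series(fit.beta, index=columns),
        covariance=pd.DataFrame(fit.cov, index=columns, columns=columns),
        baseline_cumhaz=baseline,
        loglik=fit.loglik,
        n=fit.n,
        n_events=fit.n_events,
        x_mean=pd.Series(X.mean(axis=0), index=columns),
        _engine=fit,
    )


def prognostic_index(cohort: pd.DataFrame, fit: CoxFit, columns=None) -> np.ndarray:
    """Centered linear predictor PI_i = (X_i - Xbar)' beta_hat.

    Xbar is the sample mean of the design columns of ``cohort`` itself, so
    mean(PI) is zero to floating precision.  ``columns`` restricts the index
    to a subset of the fitted covariates.
    """
    cols = list(columns) if columns is not None else fit.columns
    unknown = [c for c in cols if c not in fit.columns]
    if unknown:
        raise ValueError(f"columns not in the fit: {unknown}")
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks columns: {missing}")
    X = cohort[cols].to_numpy(dtype=float)
    beta = fit.beta[cols].to_numpy()
    return (X - X.mean(axis=0)) @ beta


def tv_effect_test(cohort: pd.DataFrame, fit: CoxFit, column: str):
    """Proportional-hazards screen for one covariate.

    Grambsch-Therneau scaled-Schoenfeld test with the identity time
    transform: regresses the (scaled) Schoenfeld residuals of ``column`` on
    the event times and returns the chi-square statistic (1 df) and p-value.
    """
    if column not in fit.columns:
        raise ValueError(f"{column!r} is not a fitted covariate")
    if fit.n_events < 2:
        raise ValueError("need at least 2 events for the time-varying test")
    times, resid = fit._engine.schoenfeld()
    d = len(times)
    c = times - times.mean()
    s_c = resid.T @ c                      # p-vector
    cov = fit.covariance.to_numpy()
    j = fit.columns.index(column)
    num = (cov @ s_c)[j]
    stat = d * num**2 / (cov[j, j] * float(c @ c))
    return float(stat), float(stats.chi2.sf(stat, df=1))


def hr_table(fit: CoxFit) -> pd.DataFrame:
    """Coefficients, hazard ratios, SEs, Wald z and p-values."""
    se = fit.se
    z = fit.beta / se
    return pd.DataFrame(
        {
            "coef": fit.beta,
            "hr": np.exp(fit.beta),
            "se": se,
            "z": z,
            "p": 2 * stats.norm.sf(np.abs(z)),
        }
    )
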
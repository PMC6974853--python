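"""Landmark super-dataset construction and landmark supermodels.

The landmark strategy for dynamic prediction: pick a window width ``w`` and
a grid of landmark times ``s_1 <= ... <= s_L``; at each landmark keep the
subjects still at risk (time > s), truncate their follow-up at the horizon
``s + w`` (administrative censoring), and stack all landmark-specific data
sets into one "super dataset" with a stratum label per landmark.

Two supermodels are fitted on the stack, both with smoothly landmark-varying
coefficients ``beta_LM(s) = sum_j theta_j f_j(s)``:

* the *stratified* supermodel ``h(t | x, s) = h0(t | s) exp(x beta_LM(s))``
  (one Breslow baseline per landmark, risk sets within stratum), and
* the *proportional-baselines* supermodel
  ``h(t | x, s) = h0(t) exp(x beta_LM(s) + gamma(s))`` with
  ``gamma(s) = sum_j gamma_j g_j(s)``, ``g_j(s_1) = 0`` for identifiability,
  fitted as one partial likelihood over the stacked rows with delayed-entry
  ``(entry, exit]`` at-risk logic and a single baseline anchored at ``s_1``.

Because a subject contributes rows to many strata, the default covariance is
the cluster-robust sandwich with clustering on subject id.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import cox
from .stepfun import StepFunction

__all__ = [
    "Basis",
    "LandmarkDesign",
    "polynomial_f_basis",
    "polynomial_g_basis",
    "indicator_basis",
    "default_design",
    "SuperDataset",
    "build_landmark_dataset",
    "SupermodelFit",
    "fit_stratified_supermodel",
    "fit_proportional_supermodel",
    "breslow_baseline",
    "beta_lm",
    "beta_lm_curve",
    "gamma_at",
    "dynamic_death_probability",
    "fit_crude_landmarks",
    "supermodel_table",
]


@dataclass(frozen=True)
class Basis:
    """A named basis function of the landmark time s."""

    name: str
    fn: Callable[[float], float]

    def __call__(self, s):
        return self.fn(s)


_POLY_NAMES = {0: "constant", 1: "linear", 2: "quadratic", 3: "cubic"}


def polynomial_f_basis(s_max: float, degree: int = 2) -> tuple[Basis, ...]:
    """f_j(s) = (s / s_max)^j for j = 0..degree (constant, linear, ...)."""
    if s_max <= 0:
        raise ValueError("s_max must be > 0")
    return tuple(
        Basis(_POLY_NAMES.get(j, f"s^{j}"), lambda s, j=j: (s / s_max) ** j)
        for j in range(degree + 1)
    )


def polynomial_g_basis(s_min: float, s_max: float, degree: int = 2) -> tuple[Basis, ...]:
    """g_j(s) = ((s - s_min) / (s_max - s_min))^j for j = 1..degree.

    Vanishes at the first landmark, keeping gamma identifiable.
    """
    if s_max <= s_min:
        return ()
    span = s_max - s_min
    return tuple(
        Basis(_POLY_NAMES.get(j, f"s^{j}"), lambda s, j=j: ((s - s_min) / span) ** j)
        for j in range(1, degree + 1)
    )


def indicator_basis(grid: Sequence[float]) -> tuple[Basis, ...]:
    """One indicator per landmark (the saturated basis)."""
    return tuple(
        Basis(f"at{s:g}", lambda x, s=s: float(np.isclose(x, s))) for s in grid
    )


@dataclass(frozen=True)
class LandmarkDesign:
    """Window width, landmark grid, and the f/g basis functions."""

    window: float
    grid: np.ndarray
    f_basis: tuple[Basis, ...] = ()
    g_basis: tuple[Basis, ...] = ()

    def __post_init__(self):
        grid = np.atleast_1d(np.asarray(self.grid, dtype=float))
        if self.window <= 0:
            raise ValueError("window width must be > 0")
        if grid.size == 0 or np.any(np.diff(grid) < 0):
            raise ValueError("grid must be nonempty and nondecreasing")
        object.__setattr__(self, "grid", grid)
        if not self.f_basis:
            degree = 2 if grid.size > 1 else 0
            object.__setattr__(
                self, "f_basis", polynomial_f_basis(max(grid[-1], 1.0), degree)
            )
        if not self.g_basis and grid.size > 1:
            object.__setattr__(
                self, "g_basis", polynomial_g_basis(grid[0], grid[-1])
            )
        for g in self.g_basis:
            if abs(g(grid[0])) > 1e-12:
                raise ValueError(f"g basis {g.name!r} must vanish at s_1={grid[0]}")

    @property
    def s_min(self) -> float:
        return float(self.grid[0])

    @property
    def s_max(self) -> float:
        return float(self.grid[-1])

    def f_matrix(self, s) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        return np.column_stack([[f(v) for v in s] for f in self.f_basis])

    def g_matrix(self, s) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if not self.g_basis:
            return np.zeros((s.size, 0))
        return np.column_stack([[g(v) for v in s] for g in self.g_basis])


def default_design(window: float = 5.0, start: float = 0.0, stop: float = 3.0,
                   step: float = 0.1) -> LandmarkDesign:
    """The standard analysis design: w = 5 years, landmarks 0..3 by 0.1,
    f = {1, s/3, (s/3)^2}, g = {s/3, (s/3)^2}."""
    n_steps = max(int(round((stop - start) / step)), 0)
    grid = start + step * np.arange(n_steps + 1)
    if grid.size == 1:
        return LandmarkDesign(window=window, grid=grid,
                              f_basis=polynomial_f_basis(1.0, 0), g_basis=())
    return LandmarkDesign(
        window=window,
        grid=grid,
        f_basis=polynomial_f_basis(stop),
        g_basis=polynomial_g_basis(start, stop),
    )


@dataclass
class SuperDataset:
    """Stacked per-landmark records plus the design that produced them.

    ``data`` columns: id, stratum, entry, exit, status, the original
    covariates, the interaction columns ``{cov}:{f_name}`` and the landmark
    columns ``lm:{g_name}``.
    """

    data: pd.DataFrame
    design: LandmarkDesign
    covariates: list[str]

    @property
    def f_columns(self) -> list[str]:
        return [f"{c}:{f.name}" for c in self.covariates for f in self.design.f_basis]

    @property
    def g_columns(self) -> list[str]:
        return [f"lm:{g.name}" for g in self.design.g_basis]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.10g")


def build_landmark_dataset(
    cohort: pd.DataFrame,
    design: LandmarkDesign,
    covariates: Sequence[str] = (),
) -> SuperDataset:
    """Truncate, administratively censor and stack the cohort per landmark.

    At each landmark s: subjects with time > s enter with ``entry = s`` and
    ``exit = min(time, s + w)``; the event indicator survives only if the
    event occurred in ``(s, s + w]`` (events exactly at the horizon count;
    administrative censoring applies strictly after).  A landmark with no
    subject at risk raises, naming the offending s.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    covariates = list(covariates)
    missing = [c for c in covariates if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks columns: {missing}")
    w = design.window
    time = cohort["time"].to_numpy(dtype=float)
    status = cohort["status"].to_numpy()
    empty = [float(s) for s in design.grid if not np.any(time > s)]
    if empty:
        raise ValueError(f"no subjects at risk at landmark(s): {empty}")
    blocks = []
    for s in design.grid:
        at_risk = time > s
        sub = cohort.loc[at_risk, ["id", *covariates]].copy()
        t = time[at_risk]
        horizon = s + w
        sub.insert(1, "stratum", float(s))
        sub.insert(2, "entry", float(s))
        sub.insert(3, "exit", np.minimum(t, horizon))
        sub.insert(4, "status", np.where(t <= horizon, status[at_risk], 0))
        fvals = [f(float(s)) for f in design.f_basis]
        for c in covariates:
            for f, fv in zip(design.f_basis, fvals):
                sub[f"{c}:{f.name}"] = sub[c].to_numpy(dtype=float) * fv
        for g in design.g_basis:
            sub[f"lm:{g.name}"] = g(float(s))
        blocks.append(sub)
    data = pd.concat(blocks, ignore_index=True)
    return SuperDataset(data=data, design=design, covariates=covariates)


@dataclass
class SupermodelFit:
    """A fitted landmark supermodel (stratified or proportional-baselines)."""

    kind: str  # "stratified" | "proportional"
    theta: pd.Series                 # (covariate x f basis) coefficients
    gamma: pd.Series                 # g-basis coefficients (empty if stratified)
    covariance: pd.DataFrame         # model-based, all coefficients
    covariance_robust: pd.DataFrame  # sandwich, clustered on subject id
    baselines: dict                  # stratified: {s: StepFunction}; proportional: {"s1": StepFunction}
    design: LandmarkDesign
    covariates: list[str]
    loglik: float
    n_rows: int
    n_events: int
    iterations: int

    @property
    def coef(self) -> pd.Series:
        return pd.concat([self.theta, self.gamma])

    def theta_block(self, covariate: str) -> pd.Series:
        cols = [f"{covariate}:{f.name}" for f in self.design.f_basis]
        return self.theta[cols]

    def beta_lm_value(self, covariate: str, s: float) -> float:
        fvec = self.design.f_matrix(s)[0]
        return float(self.theta_block(covariate).to_numpy() @ fvec)

    def gamma_value(self, s: float) -> float:
        if self.kind != "proportional":
            raise ValueError("gamma is only defined for the proportional fit")
        if not len(self.gamma):
            return 0.0
        return float(self.gamma.to_numpy() @ self.design.g_matrix(s)[0])

    def risk_score(self, X: pd.DataFrame, s: float) -> np.ndarray:
        """x' beta_LM(s) (+ gamma(s) for the proportional fit)."""
        lp = np.zeros(len(X))
        for c in self.covariates:
            lp += X[c].to_numpy(dtype=float) * self.beta_lm_value(c, s)
        if self.kind == "proportional":
            lp += self.gamma_value(s)
        return lp


def _fit_stacked(sd: SuperDataset, columns, stratified: bool) -> cox.PartialLikelihoodFit:
    df = sd.data
    X = df[columns].to_numpy(dtype=float) if columns else np.empty((len(df), 0))
    return cox.fit_partial_likelihood(
        df["entry"].to_numpy(dtype=float),
        df["exit"].to_numpy(dtype=float),
        df["status"].to_numpy(),
        X,
        strata=df["stratum"].to_numpy() if stratified else None,
        cluster=df["id"].to_numpy(),
        names=columns,
    )


def _package_fit(sd: SuperDataset, eng: cox.PartialLikelihoodFit, kind: str,
                 columns, n_gamma: int) -> SupermodelFit:
    cov = pd.DataFrame(eng.cov, index=columns, columns=columns)
    cov_rob = pd.DataFrame(
        eng.cov_robust if eng.cov_robust is not None else eng.cov,
        index=columns, columns=columns,
    )
    theta_cols = columns[: len(columns) - n_gamma]
    gamma_cols = columns[len(columns) - n_gamma:]
    coef = pd.Series(eng.beta, index=columns)
    baselines = {}
    if kind == "stratified":
        for i, s in enumerate(eng.strata_labels):
            te, dh = eng.baseline(i)
            baselines[float(s)] = StepFunction(te, np.cumsum(dh), initial=0.0)
    else:
        te, dh = eng.baseline(0)
        baselines["s1"] = StepFunction(te, np.cumsum(dh), initial=0.0)
    return SupermodelFit(
        kind=kind,
        theta=coef[theta_cols],
        gamma=coef[gamma_cols],
        covariance=cov,
        covariance_robust=cov_rob,
        baselines=baselines,
        design=sd.design,
        covariates=sd.covariates,
        loglik=eng.loglik,
        n_rows=eng.n,
        n_events=eng.n_events,
        iterations=eng.iterations,
    )


def fit_stratified_supermodel(sd: SuperDataset) -> SupermodelFit:
    """Stratified landmark supermodel: one baseline per landmark.

    Maximises the stratified partial likelihood over the stacked rows (risk
    sets within stratum); errors name any stratum without events.  The
    robust covariance clusters on subject id.
    """
    columns = sd.f_columns
    try:
        eng = _fit_stacked(sd, columns, stratified=True)
    except cox.EmptyStratumError as exc:
        raise ValueError(f"landmark stratum without events: {exc.strata}") from exc
    return _package_fit(sd, eng, "stratified", columns, n_gamma=0)


def fit_proportional_supermodel(source, design: LandmarkDesign | None = None,
                                covariates: Sequence[str] = ()) -> SupermodelFit:
    """Proportional-baselines supermodel: single baseline plus gamma(s).

    Accepts either a cohort DataFrame plus a design (the super dataset is
    built internally) or a prebuilt :class:`SuperDataset`.  Fitted as one
    unstratified partial likelihood over the stacked rows with delayed-entry
    at-risk logic; the Breslow baseline refers to the first landmark, where
    gamma vanishes by construction.
    """
    if isinstance(source, SuperDataset):
        sd = source
    else:
        if design is None:
            raise ValueError("a LandmarkDesign is required with a cohort input")
        sd = build_landmark_dataset(source, design, covariates)
    for g in sd.design.g_basis:
        if abs(g(sd.design.s_min)) > 1e-12:
            raise ValueError(f"g basis {g.name!r} does not vanish at s_1")
    columns = sd.f_columns + sd.g_columns
    eng = _fit_stacked(sd, columns, stratified=False)
    return _package_fit(sd, eng, "proportional", columns, n_gamma=len(sd.g_columns))


def breslow_baseline(sd: SuperDataset, fit: SupermodelFit, s: float) -> StepFunction:
    """Breslow cumulative hazard for landmark stratum s.

    Increment at each event time t_i in the stratum:
    (#events at t_i) / sum_{j at risk in stratum} exp(x_j beta_LM_hat(s)).
    """
    matches = np.isclose(sd.design.grid, s)
    if not matches.any():
        raise ValueError(f"unknown landmark stratum: {s}")
    s = float(sd.design.grid[matches.argmax()])
    sub = sd.data[np.isclose(sd.data["stratum"], s)]
    lp = fit.risk_score(sub, s)
    if fit.kind == "proportional":
        lp -= fit.gamma_value(s)  # stratum baseline absorbs gamma here
    exit_ = sub["exit"].to_numpy(dtype=float)
    status = sub["status"].to_numpy().astype(bool)
    te = np.unique(exit_[status])
    r = np.exp(lp)
    inc = np.array([
        status[np.isclose(exit_, t)].sum() / r[exit_ >= t].sum() for t in te
    ])
    return StepFunction(te, np.cumsum(inc), initial=0.0)


def _lincomb_ci(coef: np.ndarray, cov: np.ndarray, vec: np.ndarray, level=0.95):
    est = float(vec @ coef)
    var = float(vec @ cov @ vec)
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2)
    return est, se, est - z * se, est + z * se


def beta_lm(fit: SupermodelFit, s: float, covariate: str | None = None,
            robust: bool = True) -> pd.DataFrame:
    """Landmark-varying effect beta_LM(s) with pointwise 95% CI.

    Returns one row per covariate: estimate, se, ci_low, ci_high and the
    dynamic hazard ratio exp(beta_LM(s)).  Values of s beyond the fitted
    grid are computed but tagged with a warning (extrapolation).
    """
    if s > fit.design.s_max + 1e-12 or s < fit.design.s_min - 1e-12:
        warnings.warn(
            f"s={s} lies outside the fitted landmark grid "
            f"[{fit.design.s_min}, {fit.design.s_max}]; extrapolating",
            stacklevel=2,
        )
    cov_all = (fit.covariance_robust if robust else fit.covariance)
    fvec = fit.design.f_matrix(s)[0]
    rows = {}
    for c in ([covariate] if covariate else fit.covariates):
        cols = [f"{c}:{f.name}" for f in fit.design.f_basis]
        block = cov_all.loc[cols, cols].to_numpy()
        est, se, lo, hi = _lincomb_ci(fit.theta[cols].to_numpy(), block, fvec)
        rows[c] = {"estimate": est, "se": se, "ci_low": lo, "ci_high": hi,
                   "hr": np.exp(est)}
    return pd.DataFrame.from_dict(rows, orient="index")


def beta_lm_curve(fit: SupermodelFit, s_values=None, covariate=None,
                  robust: bool = True) -> pd.DataFrame:
    """beta_lm evaluated over a grid (long format, one row per (s, cov))."""
    if s_values is None:
        s_values = fit.design.grid
    frames = []
    for s in np.atleast_1d(s_values):
        df = beta_lm(fit, float(s), covariate=covariate, robust=robust)
        df.insert(0, "s", float(s))
        frames.append(df.reset_index(names="covariate"))
    return pd.concat(frames, ignore_index=True)


def gamma_at(fit: SupermodelFit, s: float, robust: bool = True) -> dict:
    """gamma(s) with CI; exp(gamma(s_1)) = 1 exactly by construction."""
    if fit.kind != "proportional":
        raise ValueError("gamma_at requires a proportional-baselines fit")
    gvec = fit.design.g_matrix(s)[0]
    if not len(fit.gamma):
        return {"estimate": 0.0, "se": 0.0, "ci_low": 0.0, "ci_high": 0.0, "hr": 1.0}
    cols = list(fit.gamma.index)
    cov_all = fit.covariance_robust if robust else fit.covariance
    block = cov_all.loc[cols, cols].to_numpy()
    est, se, lo, hi = _lincomb_ci(fit.gamma.to_numpy(), block, gvec)
    return {"estimate": est, "se": se, "ci_low": lo, "ci_high": hi, "hr": np.exp(est)}


def dynamic_death_probability(fit: SupermodelFit, x, s: float) -> float:
    """Probability of dying in the window (s, s + w] given alive at s.

    F_w(s | x) = 1 - exp(-[H0(s+w) - H0(s)] exp(x beta_LM(s) + gamma(s))),
    with coefficients frozen at their landmark-s values across the window
    (the landmark convention).  Stratified fits use the stratum-s baseline;
    the proportional fit uses its single anchored baseline.
    """
    if s < fit.design.s_min - 1e-12 or s > fit.design.s_max + 1e-12:
        raise ValueError(f"s={s} outside the landmark grid")
    xs = pd.DataFrame([dict(x)]) if not isinstance(x, pd.DataFrame) else x
    return float(window_death_probability(fit, xs, s)[0])


def window_death_probability(fit: SupermodelFit, X: pd.DataFrame, s: float) -> np.ndarray:
    """Vectorised window death probabilities for many subjects at once."""
    if s < fit.design.s_min - 1e-12 or s > fit.design.s_max + 1e-12:
        raise ValueError(f"s={s} outside the landmark grid")
    horizon = s + fit.design.window
    if fit.kind == "stratified":
        matches = np.isclose(fit.design.grid, s)
        if not matches.any():
            raise ValueError(
                f"stratified predictions need s on the fitted grid; got {s}"
            )
        base = fit.baselines[float(fit.design.grid[matches.argmax()])]
        lp = fit.risk_score(X, s)  # no gamma in stratified fits
    else:
        base = fit.baselines["s1"]
        lp = fit.risk_score(X, s)  # includes gamma(s)
    dh0 = base(horizon) - base(s)
    return 1.0 - np.exp(-dh0 * np.exp(lp))


def fit_crude_landmarks(cohort: pd.DataFrame, design: LandmarkDesign,
                        covariates: Sequence[str]) -> pd.DataFrame:
    """Separate ("crude") Cox fits per landmark data set.

    Each landmark's data is the truncated, administratively censored subset;
    returns one row per (s, covariate) with coefficient and model SE.
    """
    from .survival import fit_cox

    covariates = list(covariates)
    rows = []
    for s in design.grid:
        sub = cohort[cohort["time"] > s].copy()
        horizon = s + design.window
        sub["status"] = np.where(sub["time"] <= horizon, sub["status"], 0)
        sub["time"] = np.minimum(sub["time"], horizon)
        fit = fit_cox(sub, covariates, entry_times=np.full(len(sub), float(s)))
        for c in covariates:
            rows.append({"s": float(s), "covariate": c,
                         "coef": float(fit.beta[c]), "se": float(fit.se[c])})
    return pd.DataFrame(rows)


def supermodel_table(fit: SupermodelFit, robust: bool = True) -> pd.DataFrame:
    """Coefficient table in the standard layout:
    part, covariate, time function, coefficient, SE."""
    cov = fit.covariance_robust if robust else fit.covariance
    se = np.sqrt(np.diag(cov.to_numpy()))
    se = pd.Series(se, index=cov.index)
    part = "stratified" if fit.kind == "stratified" else "proportional hazards"
    rows = []
    for c in fit.covariates:
        for f in fit.design.f_basis:
            col = f"{c}:{f.name}"
            rows.append({"part": part, "covariate": c, "time_function": f.name,
                         "coef": float(fit.theta[col]), "se": float(se[col])})
    for g in fit.design.g_basis:
        col = f"lm:{g.name}"
        if col in fit.gamma.index:
            rows.append({"part": part, "covariate": "gamma(s)",
                         "time_function": g.name,
                         "coef": float(fit.gamma[col]), "se": float(se[col])})
    return pd.DataFrame(rows)
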
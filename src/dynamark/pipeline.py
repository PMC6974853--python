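"""End-to-end analysis driver.

Simulate (or read) a cohort, fit the all-covariate Cox model, compute the
prognostic index, screen it for a time-varying effect, run the landmark
analysis (super dataset, stratified and proportional-baselines supermodels)
and write every table and curve as CSV plus a figure analogue.  Every
figure has a CSV twin; no number appears only in a plot.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .evaluate import dynamic_auc, dynamic_cindex, prediction_error_curve
from .landmark import (
    LandmarkDesign,
    beta_lm_curve,
    build_landmark_dataset,
    default_design,
    fit_crude_landmarks,
    fit_proportional_supermodel,
    fit_stratified_supermodel,
    gamma_at,
    supermodel_table,
    window_death_probability,
)
from .simulate import generate_cohort, read_cohort_csv, table1_design
from .survival import censoring_km, fit_cox, hr_table, km_estimate, prognostic_index, tv_effect_test

log = logging.getLogger("dynamark")

__all__ = ["AnalysisConfig", "run_analysis", "validate_cohort_csv"]


class CohortSchemaError(ValueError):
    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid cohort file:\n  " + "\n  ".join(self.problems))


@dataclass
class AnalysisConfig:
    """Configuration for one full analysis run.

    Exactly one of ``input_csv`` / ``preset`` must be given.
    """

    input_csv: str | None = None
    preset: str | None = None
    n: int = 550
    seed: int = 0
    window: float = 5.0
    grid_start: float = 0.0
    grid_stop: float = 3.0
    grid_step: float = 0.1
    pi_columns: list | None = None    # None = all covariates
    outdir: str = "dynamark_out"
    evaluate: bool = True
    figures: bool = True
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.input_csv is None) == (self.preset is None):
            raise ValueError("give exactly one of input_csv / preset")
        if self.grid_step <= 0:
            raise ValueError("grid step must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def design(self) -> LandmarkDesign:
        return default_design(self.window, self.grid_start, self.grid_stop,
                              self.grid_step)

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_cohort_csv(path, covariates=None) -> pd.DataFrame:
    """Schema-check a cohort CSV and return it as a DataFrame.

    Requires columns id, time, status plus at least one covariate; times
    strictly positive, status binary, no missing cells.  Violations are
    reported with 1-based data row numbers.
    """
    df = read_cohort_csv(path)
    problems = []
    for col in ("id", "time", "status"):
        if col not in df.columns:
            problems.append(f"missing required column {col!r}")
    if problems:
        raise CohortSchemaError(problems)
    covs = [c for c in df.columns if c not in ("id", "time", "status")]
    if covariates:
        missing = [c for c in covariates if c not in covs]
        if missing:
            problems.append(f"missing covariate columns: {missing}")
    if not covs:
        problems.append("no covariate columns present")
    na_rows = df.index[df.isna().any(axis=1)]
    problems += [f"row {i + 1}: missing value(s)" for i in na_rows[:20]]
    bad_t = df.index[pd.to_numeric(df["time"], errors="coerce").fillna(-1) <= 0]
    problems += [f"row {i + 1}: time must be > 0" for i in bad_t[:20]]
    bad_s = df.index[~df["status"].isin((0, 1))]
    problems += [f"row {i + 1}: status must be 0 or 1" for i in bad_s[:20]]
    if problems:
        raise CohortSchemaError(problems)
    return df


def _covariate_summary(cohort: pd.DataFrame, covs) -> pd.DataFrame:
    rows = []
    n = len(cohort)
    for c in covs:
        x = cohort[c].to_numpy(dtype=float)
        if set(np.unique(x)) <= {0.0, 1.0}:
            k = int(x.sum())
            rows.append({"variable": c, "summary": f"{k} ({100 * k / n:.2f}%)"})
        else:
            rows.append({"variable": c,
                         "summary": f"{x.mean():.2f} ({x.std(ddof=1):.2f})"})
    return pd.DataFrame(rows)


def _save_fig(fig, path, enabled):
    if enabled:
        fig.savefig(path, dpi=120)
    plt.close(fig)


def run_analysis(config: AnalysisConfig) -> dict:
    """Run the full pipeline; returns a manifest dict (also written as JSON).

    Deterministic for a fixed config (including seed): the same run twice
    produces byte-identical CSV outputs.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    # --- cohort -----------------------------------------------------------
    if config.preset is not None:
        if config.preset != "table1":
            raise ValueError(f"unknown preset {config.preset!r}")
        design_sim = table1_design(n=config.n, seed=config.seed)
        cohort = generate_cohort(design_sim)
    else:
        cohort = validate_cohort_csv(config.input_csv)
    covs = [c for c in cohort.columns if c not in ("id", "time", "status")]
    n_events = int(cohort["status"].sum())
    log.info("cohort: n=%d, events=%d (%.1f%%)", len(cohort), n_events,
             100 * n_events / len(cohort))
    cohort.to_csv(out / "cohort.csv", index=False, float_format="%.10g")

    # --- KM survival and censoring curves (fig 1 analogue) ----------------
    S = km_estimate(cohort["time"], cohort["status"])
    Gc = censoring_km(cohort["time"], cohort["status"])
    km_df = pd.DataFrame({"time": S.knots, "survival": S.values,
                          "censoring": Gc.curve(S.knots)})
    km_df.to_csv(out / "km_curves.csv", index=False)
    log.info("median follow-up (reverse KM): %.3f", Gc.median_followup)
    fig, ax = plt.subplots()
    ax.step(np.r_[0, S.knots], np.r_[1, S.values], where="post", label="survival")
    ax.step(np.r_[0, Gc.curve.knots], np.r_[1, Gc.curve.values], where="post",
            label="censoring")
    ax.set_xlabel("years"); ax.set_ylabel("probability"); ax.legend()
    _save_fig(fig, out / "fig1_km.png", config.figures)

    # --- all-covariate Cox fit and PI -------------------------------------
    cox_fit = fit_cox(cohort, covs)
    _covariate_summary(cohort, covs).to_csv(out / "covariate_summary.csv", index=False)
    hr_table(cox_fit).to_csv(out / "cox_hr_table.csv", float_format="%.6g")
    pi_cols = config.pi_columns or covs
    pi = prognostic_index(cohort, cox_fit, columns=pi_cols)
    cohort = cohort.assign(pi=pi)
    pi_sd = float(np.std(pi, ddof=1))

    pi_fit = fit_cox(cohort, ["pi"])
    tv_stat, tv_p = tv_effect_test(cohort, pi_fit, "pi")
    pd.DataFrame([{"pi_mean": float(np.mean(pi)), "pi_sd": pi_sd,
                   "tv_chi2": tv_stat, "tv_p": tv_p}]).to_csv(
        out / "pi_summary.csv", index=False, float_format="%.6g")
    log.info("PI sd=%.3f, tv-effect p=%.4f", pi_sd, tv_p)

    # --- survival by PI level (fig 2a analogue) ---------------------------
    tgrid = np.linspace(0.0, float(cohort["time"].max()), 121)
    levels = {"-2sd": -2 * pi_sd, "-1sd": -pi_sd, "mean": 0.0,
              "+1sd": pi_sd, "+2sd": 2 * pi_sd}
    surv = pd.DataFrame({"time": tgrid})
    for name, v in levels.items():
        surv[name] = pi_fit.predict_survival({"pi": v}, tgrid)
    surv.to_csv(out / "survival_by_pi.csv", index=False, float_format="%.6g")
    fig, ax = plt.subplots()
    for name in levels:
        ax.plot(tgrid, surv[name], label=f"PI {name}")
    ax.set_xlabel("years"); ax.set_ylabel("S(t | PI)"); ax.legend()
    _save_fig(fig, out / "fig2a_survival_by_pi.png", config.figures)

    # --- landmark supermodels ---------------------------------------------
    design = config.design()
    sd = build_landmark_dataset(cohort, design, covariates=["pi"])
    sd.to_csv(out / "super_dataset.csv")
    strat = fit_stratified_supermodel(sd)
    prop = fit_proportional_supermodel(sd)
    log.info("stratified supermodel: %d rows, %d events, %d iterations",
             strat.n_rows, strat.n_events, strat.iterations)
    tables = pd.concat([supermodel_table(strat), supermodel_table(prop)],
                       ignore_index=True)
    tables.to_csv(out / "supermodel_table.csv", index=False, float_format="%.6g")

    # --- dynamic death probabilities (fig 2b analogue) --------------------
    dd = pd.DataFrame({"s": design.grid})
    for name, v in levels.items():
        dd[name] = [
            float(window_death_probability(prop, pd.DataFrame({"pi": [v]}), float(s))[0])
            for s in design.grid
        ]
    dd.to_csv(out / "dynamic_death_prob.csv", index=False, float_format="%.6g")
    fig, ax = plt.subplots()
    for name in levels:
        ax.plot(dd["s"], dd[name], label=f"PI {name}")
    ax.set_xlabel("landmark s (years)")
    ax.set_ylabel(f"P(death in (s, s+{design.window:g}] | alive at s)")
    ax.legend()
    _save_fig(fig, out / "fig2b_dynamic_death_prob.png", config.figures)

    # --- landmark effect curves (fig 3 analogue) --------------------------
    eff = beta_lm_curve(strat, covariate="pi").rename(columns={"estimate": "beta_lm"})
    gam = pd.DataFrame([{"s": float(s), **gamma_at(prop, float(s))}
                        for s in design.grid])
    crude = fit_crude_landmarks(cohort, design, ["pi"])
    eff.to_csv(out / "landmark_effects.csv", index=False, float_format="%.6g")
    gam.to_csv(out / "landmark_gamma.csv", index=False, float_format="%.6g")
    crude.to_csv(out / "landmark_crude.csv", index=False, float_format="%.6g")
    fig, ax = plt.subplots()
    ax.plot(eff["s"], eff["beta_lm"], "--", label="supermodel")
    ax.fill_between(eff["s"], eff["ci_low"], eff["ci_high"], alpha=0.2)
    ax.plot(crude["s"], crude["coef"], "-", label="crude")
    ax.set_xlabel("landmark s (years)"); ax.set_ylabel("beta_LM(s) for PI")
    ax.legend()
    _save_fig(fig, out / "fig3_landmark_effects.png", config.figures)

    # --- evaluation (fig 4 analogue) --------------------------------------
    manifest_metrics = {}
    if config.evaluate:
        cind = dynamic_cindex(cohort, design, prop)
        brier = prediction_error_curve(cohort, design, prop)
        auc = dynamic_auc(cohort, design, prop)
        ev = pd.DataFrame({"s": design.grid, "cindex": cind.cindex,
                           "brier_model": brier.brier_model,
                           "brier_null": brier.brier_null, "auc": auc.auc})
        ev.to_csv(out / "evaluation.csv", index=False, float_format="%.6g")
        manifest_metrics = {**cind.summary, **brier.summary, **auc.summary}
        fig, ax = plt.subplots()
        ax.plot(ev["s"], ev["cindex"], label="dynamic C")
        ax.plot(ev["s"], ev["auc"], label="AUC(s+w)")
        ax.set_ylim(0, 1); ax.set_xlabel("landmark s (years)"); ax.legend()
        _save_fig(fig, out / "fig4a_cindex_auc.png", config.figures)
        fig, ax = plt.subplots()
        ax.plot(ev["s"], ev["brier_model"], label="model")
        ax.plot(ev["s"], ev["brier_null"], label="KM null")
        ax.set_xlabel("landmark s (years)"); ax.set_ylabel("Brier(s+w)")
        ax.legend()
        _save_fig(fig, out / "fig4b_prediction_error.png", config.figures)

    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "versions": {"dynamark": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "n": int(len(cohort)),
        "n_events": n_events,
        "median_followup": Gc.median_followup,
        "pi_sd": pi_sd,
        "tv_p": tv_p,
        "metrics": manifest_metrics,
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
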
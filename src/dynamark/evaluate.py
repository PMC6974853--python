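"""Dynamic performance metrics for landmark prediction models.

Per landmark s, among subjects still at risk at s and with the prediction
window (s, s + w]:

* a window-restricted Harrell-type concordance (dynamic C-index),
* the IPCW Brier score at the horizon s + w, for the model and for the
  conditional Kaplan-Meier null, and
* the cumulative/dynamic time-dependent AUC at the horizon, IPCW-weighted.

Censoring weights use the conditional reverse-KM G(t)/G(s) estimated on the
full cohort.  Ties in risk scores count 0.5 in C and AUC.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landmark import LandmarkDesign, SupermodelFit, window_death_probability
from .survival import censoring_km, km_estimate

__all__ = [
    "DynamicCurves",
    "dynamic_cindex",
    "prediction_error_curve",
    "dynamic_auc",
    "evaluate_all",
]


@dataclass
class DynamicCurves:
    """Per-landmark metric curves plus summaries."""

    grid: np.ndarray
    cindex: np.ndarray | None = None
    brier_model: np.ndarray | None = None
    brier_null: np.ndarray | None = None
    auc: np.ndarray | None = None
    summary: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"s": self.grid})
        for name in ("cindex", "brier_model", "brier_null", "auc"):
            v = getattr(self, name)
            if v is not None:
                out[name] = v
        return out


def _resolve_scores(fit, score_fn):
    if score_fn is not None:
        return score_fn
    if fit is None:
        raise ValueError("need either a fitted supermodel or a score_fn")
    return lambda X, s: fit.risk_score(X, s)


def _window_masks(time, status, s, horizon):
    at_risk = time > s
    case = at_risk & (status == 1) & (time <= horizon)
    control = at_risk & (time > horizon)
    return at_risk, case, control


def dynamic_cindex(cohort: pd.DataFrame, design: LandmarkDesign,
                   fit: SupermodelFit | None = None, score_fn=None,
                   landmark_weights: str = "equal") -> DynamicCurves:
    """Window-restricted Harrell concordance per landmark.

    At each s, usable pairs are (i, j) with i an event in (s, s + w] and
    time_i < time_j among subjects at risk at s; a pair is concordant when
    the earlier event carries the higher risk score (ties count 0.5).  The
    per-landmark C pools concordances over all usable pairs across the event
    times in the window; the summary averages landmarks with equal weights
    ("equal") or by their usable-pair counts ("pairs"); the all-pairs pooled
    ratio is also reported.
    """
    score_fn = _resolve_scores(fit, score_fn)
    time = cohort["time"].to_numpy(dtype=float)
    status = cohort["status"].to_numpy()
    cvals = np.full(design.grid.size, np.nan)
    conc_tot = 0.0
    pairs_tot = 0.0
    npairs = np.zeros(design.grid.size)
    for k, s in enumerate(design.grid):
        horizon = s + design.window
        at_risk = time > s
        if not at_risk.any():
            continue
        r = np.asarray(score_fn(cohort.loc[at_risk], float(s)), dtype=float)
        t = time[at_risk]
        d = status[at_risk]
        ev = (d == 1) & (t <= horizon)
        conc = 0.0
        pairs = 0.0
        for i in np.nonzero(ev)[0]:
            later = t > t[i]
            m = int(later.sum())
            if m == 0:
                continue
            pairs += m
            conc += (r[i] > r[later]).sum() + 0.5 * (r[i] == r[later]).sum()
        if pairs > 0:
            cvals[k] = conc / pairs
            conc_tot += conc
            pairs_tot += pairs
            npairs[k] = pairs
    ok = ~np.isnan(cvals)
    summary = {
        "cindex_mean": float(np.mean(cvals[ok])) if ok.any() else np.nan,
        "cindex_pooled": float(conc_tot / pairs_tot) if pairs_tot else np.nan,
        "landmarks_undefined": int((~ok).sum()),
    }
    if landmark_weights == "pairs" and npairs[ok].sum() > 0:
        summary["cindex_mean"] = float(
            np.average(cvals[ok], weights=npairs[ok])
        )
    return DynamicCurves(grid=design.grid.copy(), cindex=cvals, summary=summary)


def _ipcw_weights(time, status, s, horizon, G):
    """Conditional IPCW weights among subjects at risk at s.

    Events in the window weight 1 / [G(T-) / G(s)]; subjects observed past
    the horizon weight 1 / [G(horizon) / G(s)]; censored-in-window rows get
    weight 0.  Raises if the conditional censoring survivor hits 0 at the
    horizon while subjects remain beyond it.
    """
    gs = G(s)
    g_hor = G(horizon)
    w = np.zeros(time.size)
    ev = (status == 1) & (time <= horizon)
    beyond = time > horizon
    if g_hor <= 0:
        raise ValueError(
            f"censoring survivor is 0 at horizon {horizon}; IPCW weights inestimable"
        )
    g_ev = G.eval_left(time[ev])
    if np.any(g_ev <= 0):
        raise ValueError("censoring survivor is 0 at an event time; weights inestimable")
    w[ev] = gs / g_ev
    if beyond.any():
        w[beyond] = gs / g_hor
    return w


def prediction_error_curve(cohort: pd.DataFrame, design: LandmarkDesign,
                           fit: SupermodelFit | None = None,
                           predict_fn=None) -> DynamicCurves:
    """IPCW Brier score at the horizon, per landmark, model vs KM null.

    The model prediction is the dynamic window death probability; the null
    substitutes the conditional Kaplan-Meier window death probability
    1 - S(s + w)/S(s) (one number per landmark, same for everyone).
    """
    if predict_fn is None:
        if fit is None:
            raise ValueError("need either a fitted supermodel or a predict_fn")
        predict_fn = lambda X, s: window_death_probability(fit, X, s)
    time = cohort["time"].to_numpy(dtype=float)
    status = cohort["status"].to_numpy()
    G = censoring_km(time, status).curve
    S = km_estimate(time, status)
    bm = np.full(design.grid.size, np.nan)
    bn = np.full(design.grid.size, np.nan)
    for k, s in enumerate(design.grid):
        horizon = s + design.window
        at_risk = time > s
        if not at_risk.any():
            continue
        t = time[at_risk]
        d = status[at_risk]
        w = _ipcw_weights(t, d, float(s), float(horizon), G)
        D = ((d == 1) & (t <= horizon)).astype(float)
        p_model = np.asarray(predict_fn(cohort.loc[at_risk], float(s)), dtype=float)
        ss = S(float(s))
        p_null = 1.0 - (S(float(horizon)) / ss if ss > 0 else 0.0)
        n_s = int(at_risk.sum())
        bm[k] = float(np.sum(w * (D - p_model) ** 2) / n_s)
        bn[k] = float(np.sum(w * (D - p_null) ** 2) / n_s)
    return DynamicCurves(
        grid=design.grid.copy(), brier_model=bm, brier_null=bn,
        summary={"brier_model_mean": float(np.nanmean(bm)),
                 "brier_null_mean": float(np.nanmean(bn))},
    )


def dynamic_auc(cohort: pd.DataFrame, design: LandmarkDesign,
                fit: SupermodelFit | None = None, score_fn=None) -> DynamicCurves:
    """Cumulative/dynamic time-dependent AUC at the horizon, per landmark.

    Cases are events in (s, s + w], controls survive past s + w; the AUC is
    the IPCW-weighted probability that a case outscores a control (score
    ties count 0.5).  Landmarks without cases or controls are flagged
    undefined (NaN).
    """
    score_fn = _resolve_scores(fit, score_fn)
    time = cohort["time"].to_numpy(dtype=float)
    status = cohort["status"].to_numpy()
    G = censoring_km(time, status).curve
    avals = np.full(design.grid.size, np.nan)
    for k, s in enumerate(design.grid):
        horizon = s + design.window
        at_risk, case, control = _window_masks(time, status, s, horizon)
        if not case.any() or not control.any():
            continue
        r = np.full(time.size, np.nan)
        r[at_risk] = np.asarray(score_fn(cohort.loc[at_risk], float(s)), dtype=float)
        w = np.zeros(time.size)
        w[at_risk] = _ipcw_weights(
            time[at_risk], status[at_risk], float(s), float(horizon), G
        )
        wc = w[case]
        wk = w[control]
        rc = r[case][:, None]
        rk = r[control][None, :]
        ww = wc[:, None] * wk[None, :]
        wins = ww * ((rc > rk) + 0.5 * (rc == rk))
        denom = float(ww.sum())
        if denom > 0:
            avals[k] = float(wins.sum() / denom)
    ok = ~np.isnan(avals)
    return DynamicCurves(
        grid=design.grid.copy(), auc=avals,
        summary={"auc_mean": float(np.mean(avals[ok])) if ok.any() else np.nan,
                 "landmarks_undefined": int((~ok).sum())},
    )


def evaluate_all(cohort, design, fit) -> DynamicCurves:
    """All three metric curves on one shared landmark grid."""
    c = dynamic_cindex(cohort, design, fit)
    b = prediction_error_curve(cohort, design, fit)
    a = dynamic_auc(cohort, design, fit)
    return DynamicCurves(
        grid=design.grid.copy(), cindex=c.cindex, brier_model=b.brier_model,
        brier_null=b.brier_null, auc=a.auc,
        summary={**c.summary, **b.summary, **a.summary},
    )
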
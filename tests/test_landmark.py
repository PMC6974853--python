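"""Super-dataset construction and the two landmark supermodels."""
import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from dynamark.landmark import (
    Basis,
    LandmarkDesign,
    beta_lm,
    beta_lm_curve,
    breslow_baseline,
    build_landmark_dataset,
    default_design,
    dynamic_death_probability,
    fit_crude_landmarks,
    fit_proportional_supermodel,
    fit_stratified_supermodel,
    gamma_at,
    indicator_basis,
    polynomial_f_basis,
    polynomial_g_basis,
    supermodel_table,
    window_death_probability,
)
from dynamark.simulate import Censoring, generate_cohort
from dynamark.survival import fit_cox

from conftest import single_covariate_design


def three_subject_cohort():
    return pd.DataFrame(
        {"id": ["A", "B", "C"], "time": [1.5, 2.5, 4.0], "status": [1, 0, 1]}
    )


class TestBuildLandmarkDataset:
    def test_three_subject_enumeration(self):
        """Grid {0,1,2}, w=2: 8 rows with hand-enumerated entry/exit/status,
        including administrative censoring at s+2 and the event exactly at
        the horizon counting as an event."""
        sd = build_landmark_dataset(
            three_subject_cohort(),
            LandmarkDesign(window=2.0, grid=[0.0, 1.0, 2.0],
                           f_basis=polynomial_f_basis(2.0, 0)),
        )
        got = sd.data[["id", "stratum", "entry", "exit", "status"]]
        expected = pd.DataFrame(
            {
                "id": ["A", "B", "C", "A", "B", "C", "B", "C"],
                "stratum": [0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 2.0, 2.0],
                "entry": [0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 2.0, 2.0],
                "exit": [1.5, 2.0, 2.0, 1.5, 2.5, 3.0, 2.5, 4.0],
                "status": [1, 0, 0, 1, 0, 0, 0, 1],
            }
        )
        pd.testing.assert_frame_equal(got.reset_index(drop=True), expected)

    def test_infinite_window_single_landmark_is_the_cohort(self, simple_cohort):
        des = LandmarkDesign(window=1e12, grid=[0.0],
                             f_basis=polynomial_f_basis(1.0, 0))
        sd = build_landmark_dataset(simple_cohort, des, ["x"])
        assert len(sd.data) == len(simple_cohort)
        assert np.allclose(sd.data["exit"], simple_cohort["time"])
        assert np.array_equal(sd.data["status"], simple_cohort["status"])

    def test_subject_at_exact_landmark_time_excluded(self):
        coh = pd.DataFrame({"id": [0, 1], "time": [1.0, 3.0], "status": [1, 1]})
        sd = build_landmark_dataset(
            coh, LandmarkDesign(window=5.0, grid=[1.0],
                                f_basis=polynomial_f_basis(1.0, 0))
        )
        assert list(sd.data["id"]) == [1]

    def test_errors(self, simple_cohort):
        with pytest.raises(ValueError):
            LandmarkDesign(window=-1.0, grid=[0.0])
        with pytest.raises(ValueError, match="at risk"):
            build_landmark_dataset(
                three_subject_cohort(),
                LandmarkDesign(window=2.0, grid=[0.0, 10.0],
                               f_basis=polynomial_f_basis(10.0, 0)),
            )
        with pytest.raises(ValueError):
            build_landmark_dataset(simple_cohort.iloc[:0], default_design())

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.floats(0.05, 9.5), st.booleans()),
                    min_size=2, max_size=40))
    def test_row_count_and_window_invariants(self, rows):
        coh = pd.DataFrame(
            {"id": range(len(rows)), "time": [t for t, _ in rows],
             "status": [int(d) for _, d in rows]}
        )
        des = LandmarkDesign(window=2.5, grid=[0.0, 1.0, 2.0],
                             f_basis=polynomial_f_basis(2.0, 1))
        try:
            sd = build_landmark_dataset(coh, des)
        except ValueError:
            return  # an empty stratum is a legitimate rejection
        d = sd.data
        assert len(d) == sum((coh["time"] > s).sum() for s in des.grid)
        assert (d["exit"] > d["entry"]).all()
        assert (d["entry"] == d["stratum"]).all()
        assert (d["exit"] <= d["stratum"] + des.window + 1e-12).all()
        orig = coh.set_index("id")
        ev = d[d["status"] == 1]
        assert (orig.loc[ev["id"], "status"].to_numpy() == 1).all()
        assert np.allclose(ev["exit"], orig.loc[ev["id"], "time"])


def _written_stratified_negll(sd, f_of_s):
    """Literal stacked stratified partial likelihood (naive double loop)."""
    d = sd.data

    def negll(theta):
        ll = 0.0
        for s in np.unique(d["stratum"]):
            sub = d[d["stratum"] == s]
            b = float(np.dot(theta, f_of_s(s)))
            for _, row in sub[sub["status"] == 1].iterrows():
                risk = sub[(sub["entry"] < row["exit"]) & (sub["exit"] >= row["exit"])]
                ll += b * row["x"] - np.log(np.sum(np.exp(b * risk["x"])))
        return -ll

    return negll


def _grid_then_polish(negll, ndim, lo=-4.0, hi=4.0, steps=17):
    grids = [np.linspace(lo, hi, steps)] * ndim
    best = None
    for point in np.stack(np.meshgrid(*grids), -1).reshape(-1, ndim):
        v = negll(point)
        if best is None or v < best[0]:
            best = (v, point)
    res = minimize(negll, best[1], method="Nelder-Mead",
                   options={"xatol": 1e-9, "fatol": 1e-13, "maxiter": 4000})
    return res.x


class TestSupermodelFitters:
    def test_single_landmark_constant_basis_reduces_to_plain_cox(self, simple_cohort):
        des = LandmarkDesign(window=3.0, grid=[0.5],
                             f_basis=polynomial_f_basis(1.0, 0))
        sd = build_landmark_dataset(simple_cohort, des, ["x"])
        strat = fit_stratified_supermodel(sd)
        sub = simple_cohort[simple_cohort["time"] > 0.5].copy()
        sub["status"] = np.where(sub["time"] <= 3.5, sub["status"], 0)
        sub["time"] = np.minimum(sub["time"], 3.5)
        plain = fit_cox(sub, ["x"], entry_times=np.full(len(sub), 0.5))
        assert abs(strat.theta.iloc[0] - plain.beta["x"]) < 1e-8
        prop = fit_proportional_supermodel(sd)
        assert abs(prop.theta.iloc[0] - strat.theta.iloc[0]) < 1e-8
        assert len(prop.gamma) == 0

    def test_saturated_basis_reproduces_crude_fits(self, simple_cohort):
        grid = [0.0, 1.0, 2.0]
        des = LandmarkDesign(window=3.0, grid=grid, f_basis=indicator_basis(grid))
        sd = build_landmark_dataset(simple_cohort, des, ["x"])
        strat = fit_stratified_supermodel(sd)
        crude = fit_crude_landmarks(simple_cohort, des, ["x"])
        assert np.max(np.abs(strat.theta.to_numpy() - crude["coef"].to_numpy())) < 1e-6

    def test_stratified_matches_bruteforce_likelihood(self, toy_cohort):
        des = LandmarkDesign(window=2.0, grid=[0.0, 1.0],
                             f_basis=polynomial_f_basis(1.0, 1), g_basis=())
        sd = build_landmark_dataset(toy_cohort, des, ["x"])
        assert len(sd.data) <= 12
        fit = fit_stratified_supermodel(sd)
        oracle = _grid_then_polish(
            _written_stratified_negll(sd, lambda s: [1.0, s]), ndim=2
        )
        assert np.max(np.abs(fit.theta.to_numpy() - oracle)) < 1e-4

    def test_proportional_matches_bruteforce_likelihood(self, toy_cohort):
        des = LandmarkDesign(window=2.0, grid=[0.0, 1.0],
                             f_basis=polynomial_f_basis(1.0, 0),
                             g_basis=(Basis("linear", lambda s: s),))
        sd = build_landmark_dataset(toy_cohort, des, ["x"])
        fit = fit_proportional_supermodel(sd)
        d = sd.data

        def negll(th):
            b, g = th
            lp = b * d["x"].to_numpy() + g * d["lm:linear"].to_numpy()
            ll = 0.0
            for i in np.nonzero(d["status"].to_numpy() == 1)[0]:
                te = d["exit"].to_numpy()[i]
                risk = (d["entry"].to_numpy() < te) & (d["exit"].to_numpy() >= te)
                ll += lp[i] - np.log(np.sum(np.exp(lp[risk])))
            return -ll

        oracle = _grid_then_polish(negll, ndim=2)
        got = np.r_[fit.theta.to_numpy(), fit.gamma.to_numpy()]
        assert np.max(np.abs(got - oracle)) < 1e-4

    def test_constant_effect_recovery_with_quadratic_basis(self):
        d = single_covariate_design(n=2000, beta=0.8, rate=0.08, admin=12.0, seed=101)
        coh = generate_cohort(d)
        des = LandmarkDesign(window=5.0, grid=np.arange(0, 3.01, 0.5),
                             f_basis=polynomial_f_basis(3.0, 2))
        fit = fit_stratified_supermodel(build_landmark_dataset(coh, des, ["x"]))
        se = np.sqrt(np.diag(fit.covariance_robust.to_numpy()))
        truth = np.array([0.8, 0.0, 0.0])
        assert np.all(np.abs(fit.theta.to_numpy() - truth) < 3 * se)

    def test_gamma_null_when_baseline_truly_proportional(self):
        d = single_covariate_design(n=2000, beta=0.5, rate=0.1, admin=12.0, seed=202)
        coh = generate_cohort(d)
        des = LandmarkDesign(window=5.0, grid=np.arange(0, 3.01, 0.5),
                             f_basis=polynomial_f_basis(3.0, 2),
                             g_basis=polynomial_g_basis(0.0, 3.0, 2))
        fit = fit_proportional_supermodel(coh, des, ["x"])
        # exponential waiting times are memoryless, so the conditional
        # baseline does not drift with s and the true gamma is identically 0
        for col in fit.gamma.index:
            se = np.sqrt(fit.covariance_robust.loc[col, col])
            assert abs(fit.gamma[col]) < 3 * se

    def test_table_layout_and_empty_stratum_error(self, simple_cohort):
        des = LandmarkDesign(window=5.0, grid=np.arange(0, 3.01, 1.0),
                             f_basis=polynomial_f_basis(3.0, 2),
                             g_basis=polynomial_g_basis(0.0, 3.0, 2))
        sd = build_landmark_dataset(simple_cohort, des, ["x"])
        prop = fit_proportional_supermodel(sd)
        tbl = supermodel_table(prop)
        assert list(tbl.columns) == ["part", "covariate", "time_function", "coef", "se"]
        assert list(tbl["time_function"]) == [
            "constant", "linear", "quadratic", "linear", "quadratic"]
        assert (tbl["covariate"] == "gamma(s)").sum() == 2
        # all exits censored in a stratum -> named error
        coh = pd.DataFrame({"id": [0, 1, 2], "time": [0.5, 2.0, 3.0],
                            "status": [1, 0, 0]})
        des2 = LandmarkDesign(window=4.0, grid=[0.0, 1.0],
                              f_basis=polynomial_f_basis(1.0, 0))
        sd2 = build_landmark_dataset(coh, des2)
        with pytest.raises(ValueError, match="without events"):
            fit_stratified_supermodel(sd2)


class TestBreslowBaseline:
    def test_null_model_first_increment_is_one_over_n(self, simple_cohort):
        des = LandmarkDesign(window=1e9, grid=[0.0],
                             f_basis=polynomial_f_basis(1.0, 0))
        sd = build_landmark_dataset(simple_cohort, des, [])
        fit = fit_stratified_supermodel(sd)
        base = breslow_baseline(sd, fit, 0.0)
        assert base.values[0] == pytest.approx(1 / len(simple_cohort))

    def test_single_event_increment_arithmetic(self):
        """Risk-set linear predictors {0.5, -0.2, 0}: the increment is
        1 / (e^0.5 + e^-0.2 + 1) ~= 0.2742."""
        coh = pd.DataFrame({"id": [0, 1, 2], "time": [1.0, 2.0, 3.0],
                            "status": [1, 1, 0], "x": [0.5, -0.2, 0.0]})
        des = LandmarkDesign(window=10.0, grid=[0.0],
                             f_basis=polynomial_f_basis(1.0, 0))
        sd = build_landmark_dataset(coh, des, ["x"])
        fit = fit_stratified_supermodel(sd)
        fit.theta.iloc[0] = 1.0  # evaluate the printed formula at beta = 1
        base = breslow_baseline(sd, fit, 0.0)
        expected = 1.0 / (np.exp(0.5) + np.exp(-0.2) + 1.0)
        assert base.values[0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.2884, abs=5e-4)

    def test_breslow_identity_reproduces_event_counts(self, simple_cohort):
        des = LandmarkDesign(window=5.0, grid=[0.0, 1.0],
                             f_basis=polynomial_f_basis(1.0, 1))
        sd = build_landmark_dataset(simple_cohort, des, ["x"])
        fit = fit_stratified_supermodel(sd)
        for s in des.grid:
            base = breslow_baseline(sd, fit, float(s))
            sub = sd.data[np.isclose(sd.data["stratum"], s)]
            lp = fit.risk_score(sub, float(s))
            inc = np.diff(np.r_[0.0, base.values])
            total = sum(
                inc[k] * np.exp(lp[(sub["exit"].to_numpy() >= t)]).sum()
                for k, t in enumerate(base.knots)
            )
            assert total == pytest.approx(sub["status"].sum(), abs=1e-9)

    def test_unknown_stratum_errors(self, simple_cohort):
        des = LandmarkDesign(window=5.0, grid=[0.0],
                             f_basis=polynomial_f_basis(1.0, 0))
        sd = build_landmark_dataset(simple_cohort, des, ["x"])
        fit = fit_stratified_supermodel(sd)
        with pytest.raises(ValueError, match="unknown"):
            breslow_baseline(sd, fit, 2.5)


def _fit_with_coefs(kind="stratified"):
    """A real fitted shell whose coefficients are then overwritten, to check
    the basis arithmetic of beta_lm / gamma_at in isolation."""
    coh = generate_cohort(single_covariate_design(n=300, seed=31))
    coh = coh.rename(columns={"x": "pi"})
    des = LandmarkDesign(window=5.0, grid=np.arange(0, 3.01, 1.0),
                         f_basis=polynomial_f_basis(3.0, 2),
                         g_basis=polynomial_g_basis(0.0, 3.0, 2))
    sd = build_landmark_dataset(coh, des, ["pi"])
    if kind == "stratified":
        return fit_stratified_supermodel(sd)
    return fit_proportional_supermodel(sd)


class TestLandmarkEffects:
    def test_beta_lm_polynomial_arithmetic(self):
        fit = _fit_with_coefs("stratified")
        fit.theta[:] = [1.031, 0.086, -0.097]
        assert fit.beta_lm_value("pi", 0.0) == pytest.approx(1.031)
        assert fit.beta_lm_value("pi", 3.0) == pytest.approx(1.020)
        row = beta_lm(fit, 1.5)
        assert row.loc["pi", "estimate"] == pytest.approx(
            1.031 + 0.086 * 0.5 - 0.097 * 0.25)
        assert row.loc["pi", "hr"] == pytest.approx(np.exp(row.loc["pi", "estimate"]))
        assert row.loc["pi", "ci_low"] < row.loc["pi", "estimate"] < row.loc["pi", "ci_high"]

    def test_constant_only_theta_gives_flat_curve(self):
        fit = _fit_with_coefs("stratified")
        fit.theta[:] = [0.7, 0.0, 0.0]
        curve = beta_lm_curve(fit, np.linspace(0, 3, 7), covariate="pi")
        assert np.allclose(curve["estimate"], 0.7)

    def test_extrapolation_warns(self):
        fit = _fit_with_coefs("stratified")
        with pytest.warns(UserWarning, match="extrapolat"):
            beta_lm(fit, 4.0)

    def test_gamma_arithmetic_and_anchoring(self):
        fit = _fit_with_coefs("proportional")
        fit.gamma[:] = [-0.175, 0.195]
        g0 = gamma_at(fit, 0.0)
        assert g0["estimate"] == 0.0 and g0["hr"] == 1.0
        assert gamma_at(fit, 3.0)["estimate"] == pytest.approx(0.020)
        strat = _fit_with_coefs("stratified")
        with pytest.raises(ValueError):
            gamma_at(strat, 1.0)

    def test_gamma_ci_widens_away_from_anchor(self):
        fit = _fit_with_coefs("proportional")
        widths = [gamma_at(fit, s)["ci_high"] - gamma_at(fit, s)["ci_low"]
                  for s in (0.0, 1.0, 2.0)]
        assert widths[0] == 0.0 and widths[1] > 0.0


class TestDynamicDeathProbability:
    def test_zero_baseline_increment_gives_zero(self):
        from dynamark.stepfun import StepFunction

        fit = _fit_with_coefs("proportional")
        # baseline with all its mass before the window (s, s+w]
        fit.baselines["s1"] = StepFunction([0.5], [0.3], initial=0.0)
        assert dynamic_death_probability(fit, {"pi": 2.0}, 1.0) == 0.0

    def test_monotone_in_risk_score(self):
        fit = _fit_with_coefs("proportional")
        for s in fit.design.grid:
            lo = dynamic_death_probability(fit, {"pi": -1.0}, float(s))
            hi = dynamic_death_probability(fit, {"pi": 1.0}, float(s))
            assert hi > lo

    def test_exponential_closed_form_no_covariates(self):
        lam, w = 0.1, 5.0
        d = single_covariate_design(n=10000, beta=0.0, rate=lam, admin=1e12, seed=7)
        coh = generate_cohort(d)
        grid = np.arange(0, 3.01, 0.5)
        des = LandmarkDesign(window=w, grid=grid, f_basis=polynomial_f_basis(3.0, 0))
        fit = fit_stratified_supermodel(build_landmark_dataset(coh, des, []))
        probs = np.array([dynamic_death_probability(fit, {}, float(s)) for s in grid])
        assert np.max(np.abs(probs - (1 - np.exp(-lam * w)))) < 0.02

    def test_out_of_grid_errors(self):
        fit = _fit_with_coefs("proportional")
        with pytest.raises(ValueError):
            dynamic_death_probability(fit, {"pi": 0.0}, 5.0)
        strat = _fit_with_coefs("stratified")
        with pytest.raises(ValueError, match="grid"):
            window_death_probability(strat, pd.DataFrame({"pi": [0.0]}), 0.25)
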
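# Methods

## Landmarking

The package targets dynamic prediction: the probability of dying in a
sliding window `(s, s + w]` given survival to the landmark time `s`. The
construction follows the standard landmark super-dataset recipe:

1. choose a window width `w` (default 5 years);
2. choose landmark points `s_1 ≤ … ≤ s_L` (default an equidistant grid from
   0 to 3 years with step 0.1);
3. for each landmark, select the subjects at risk at `s` and apply
   truncation at `s` and administrative censoring at `s + w`;
4. stack the landmark data sets into a super dataset with a stratum label
   per landmark.

Conventions, where the construction is genuinely ambiguous:

- **"At risk at s"** means `time > s`; a subject whose observed time equals
  the landmark is excluded (the left-truncation convention).
- **Window endpoint**: an event exactly at `s + w` counts as an event inside
  the window; administrative censoring applies strictly after.
- **Prediction convention**: coefficients and `γ` are evaluated at the
  landmark `s` and held fixed over the whole window.

## The supermodels

Both supermodels express the landmark-varying effect through a basis,
`β_LM(s) = Σ_j θ_j f_j(s)`, default `f = {1, u, u²}` with `u = s / s_L`
(the code stores `s_L` and normalizes internally so other grids work
unchanged). The stratified supermodel keeps one nonparametric baseline per
landmark and maximizes the stratified Breslow partial likelihood; the
proportional-baselines supermodel replaces the per-stratum baselines with a
single baseline plus a landmark effect `γ(s) = Σ_j γ_j g_j(s)` and is fitted
as one partial likelihood over the stacked rows with delayed-entry
`(entry, exit]` at-risk logic. The `g_j` (default `{u, u²}`, computed
relative to `s_1`) vanish at the first landmark, so the fitted baseline is
anchored at `s_1` and `exp(γ(s_1)) = 1` exactly.

The Cox engine is a Newton–Raphson maximizer with step-halving,
convergence when the relative log-likelihood change drops below 1e-9
(at most 100 iterations), Breslow handling of ties, and risk-set sums
computed by suffix cumulative sums over exit- and entry-sorted rows.
Breslow ties are the natural companion of the Breslow baseline estimator
`dĤ0(t) = d_t / Σ_{at risk} exp(x'β̂)`; Efron ties are not offered.
Degenerate inputs fail loudly: no events, a landmark stratum without
subjects (at build time) or without events (at stratified-fit time, named
by `s`), and rank-deficient design matrices (offending columns named via
pivoted QR) all raise.

**Covariances.** The model-based covariance is the inverse observed
information. Because a subject contributes a row to every stratum it
survives into, the rows are not independent; the default reported standard
errors are therefore the cluster-robust sandwich with clustering on subject
id (Lin–Wei score residuals aggregated per subject). Model-based SEs remain
available for the single-stratum case, where the two coincide in spirit.

**A degeneracy worth knowing.** In the proportional-baselines fit, if every
covariate effect is constant in `s` (basis `f = {1}` only), the stacked
risk set at any event time factorizes into (subjects at risk) × (strata
covering that time), and the `γ` score vanishes identically at `γ = 0`:
`γ` is then unidentified and the fitter returns exactly zero with a
degenerate sandwich variance. `γ` is identified precisely through the
covariate × `f_j(s)` interaction columns, so meaningful `γ` inference
requires a non-constant `f` basis — as in the default quadratic design.

**Dynamic prediction.** `F_w(s|x) = 1 − exp(−[Ĥ0(s+w) − Ĥ0(s)]
exp(xβ̂_LM(s) + γ̂(s)))`, with the stratum-`s` Breslow baseline for
stratified fits (hence `s` must lie on the fitted grid) and the single
anchored baseline for proportional fits (any `s` in `[s_1, s_L]`).
Evaluating `β_LM` beyond `s_L` is allowed but tagged with an extrapolation
warning.

## Evaluation metrics

All three metrics condition on being at risk at `s` and use the window
`(s, s+w]`; censoring weights use the conditional reverse Kaplan–Meier
`G(t)/G(s)` estimated once on the full cohort (the standard IPCW choice).
Risk-score ties count 0.5.

- **Dynamic C**: Harrell-type concordance over usable pairs — an event in
  the window paired with any at-risk subject observed longer. The
  per-landmark value pools concordances over all usable pairs across the
  event times in the window; the summary averages landmarks with equal
  weights (a pair-count-weighted average and the fully pooled ratio are
  also reported, since "the" average over event times admits both
  readings). Landmarks without usable pairs are flagged undefined and
  excluded from the average.
- **Prediction error**: IPCW Brier score at the horizon; events in the
  window get weight `G(s)/G(T−)`, subjects observed past the horizon get
  `G(s)/G(s+w)`, subjects censored inside the window get 0. The null model
  is the conditional KM window death probability. A censoring survivor of 0
  at the horizon makes the weights inestimable and raises.
- **Dynamic AUC**: cumulative/dynamic time-dependent AUC — cases are events
  in the window, controls survive past the horizon, IPCW-weighted.

C and AUC are rank-based and invariant to strictly monotone transformations
of the risk score; the Brier score is not.

## The time-varying-effect screen

The screen for a non-proportional covariate effect is the
Grambsch–Therneau scaled-Schoenfeld test with the identity time transform
(per-covariate statistic `d · [(I⁻¹S_c)_j]² / ((I⁻¹)_jj · Σc²)`, 1 df),
computed from the engine's own Schoenfeld residuals and cross-checked
against an independent implementation in the tests. At small samples
(n ≲ 150, ~100 events) the `V̄ = I/d` approximation makes the test mildly
conservative; its size is well inside [0.02, 0.09] at n = 500.

## Synthetic cohort generator

The generator emulates the structure of a hospital-based breast-cancer
registry cohort so every downstream stage is testable without patient data.

- **Covariates** are drawn i.i.d. from registry-style marginals: age
  ~ Normal(47.86, 11.79) (standardized in the design matrix); stage I–IV
  (20.0/41.5/34.2/4.4%), grade 1–3 (12.0/52.4/35.6%), metastasis (15.1%
  yes), ER+ (71.3%), PR+ (68.4%), HER2+ (23.6%), pathological type
  (in-situ/lobular/ductal 5.3/4.5/90.2%), surgery (65.1%
  breast-conserving). Categorical covariates are dummy-coded against the
  first level.
- **Event times** come from `h(t|x) = h0(t) exp(x'β(t))` by
  inverse-transform sampling; `β(t)` is constant, a step at `τ`, or a
  linear decay to zero at `τ` (closed-form inversion for constant and step
  profiles and for the exponential-baseline decay).
- **The `table1` preset** uses hazard-ratio-informed generating
  coefficients (e.g. log 9.04 for stage IV, log 12.51 for metastasis, log
  1.05 per year of age). These are illustrative defaults, not estimates: a
  registry's multivariable HRs describe its own case mix, not a generative
  truth. The baseline is Weibull with shape 1.5 (increasing hazard) and
  scale 30, calibrated once so the marginal 10-year survival is roughly
  50% with survival around 0.75 at 4 years; censoring mixes early dropout
  (85% of subjects Uniform(0, 4.5) years) with an administrative horizon of
  15 years, which puts the reverse-KM median follow-up near 2.7 years,
  below 3.
- **Determinism**: all randomness flows from one seed through one
  generator stream in a fixed order (covariates, then event times, then
  censoring), so censoring never reuses event-time random numbers and a
  fixed design reproduces bit-identical cohorts.

What the generator deliberately does not emulate: missing data, competing
risks, recurrent events, covariate measurement error, cohort-entry drift
(period effects), or dependence between covariates (real stage and
metastasis are strongly associated; here they are independent). Passing
tests therefore demonstrate the correctness and calibration of the
methodology under its own assumptions, not the clinical validity of any
particular registry's estimates.

## Problem sizes used in the checks

The simulation-backed checks are sized to run comfortably on one CPU:
parameter recovery uses 20 replicates of n = 2000 on a 7-point landmark
grid (0 to 3, step 0.5) with `w = 5`; the closed-form exponential
prediction limit uses n = 10000; metric null calibrations use 200
replicates of n = 300 (C and AUC) and n = 500 (test size); the analysis
default keeps the 31-point 0.1-step grid. Under the recovery design the
landmark truth is exact: conditioning on `T > s` and administratively
censoring at `s + w` preserve a proportional-hazards model with the same
coefficient, so `θ = (β, 0, 0)` in the polynomial basis.

## Known limitations

- Breslow ties only; with very heavy tying Efron-style corrections would be
  preferable.
- Polynomial bases only (plus per-landmark indicators); no splines.
- Monotone-likelihood configurations (e.g. a stratum whose events all share
  the extreme covariate value) end in a convergence error rather than a
  penalized fit.
- The IPCW weights assume censoring independent of covariates; a
  covariate-dependent censoring model is not offered.
- One subject-level covariate vector per subject: no time-dependent
  covariates beyond the landmark mechanism itself.
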
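# dynamark

Landmark dynamic prediction of survival for registry-style cohorts.

Classical survival models answer a static question — "what is this patient's
prognosis at diagnosis?" — and can mislead when covariate effects drift over
follow-up. Clinicians more often need the *dynamic* version: given that a
patient is still alive `s` years after diagnosis, what is the probability of
dying within the next `w` years? `dynamark` implements the landmarking
answer to that question for right-censored survival data, together with a
synthetic breast-cancer-registry generator so the whole pipeline is testable
and reproducible without access to patient-level registry data. It is aimed
at biostatisticians and epidemiologists working with cohort or registry
survival tables (one row per patient: follow-up time in years, death
indicator, baseline covariates).

## The model

Fix a window width `w` and landmark times `s_1 ≤ … ≤ s_L`. At each landmark
`s`, keep the subjects still at risk (`T > s`), truncate their follow-up at
the horizon `s + w` (administrative censoring), and stack the landmark data
sets into one *super dataset* with a stratum per landmark. On the stack,
two Cox-type supermodels with smoothly landmark-varying coefficients
`β_LM(s) = Σ_j θ_j f_j(s)` are fitted:

- **stratified**: `h(t | x, s) = h0(t|s) exp(x β_LM(s))`, one Breslow
  baseline per landmark, risk sets within stratum;
- **proportional baselines**: `h(t | x, s) = h0(t) exp(x β_LM(s) + γ(s))`
  with `γ(s) = Σ_j γ_j g_j(s)`, `g_j(s_1) = 0`, fitted as a single partial
  likelihood over the stacked rows with delayed-entry `(entry, exit]`
  at-risk logic and one baseline anchored at the first landmark.

The default design uses `w = 5` years, landmarks `0, 0.1, …, 3`,
`f = {1, s/3, (s/3)²}` and `g = {s/3, (s/3)²}`, and takes as covariate the
centered prognostic index `PI = (X − X̄)'β̂` from an all-covariate Cox fit.
Dynamic predictions freeze the coefficients at their landmark-`s` values
over the window:

```
F_w(s | x) = 1 − exp(−[Ĥ0(s+w) − Ĥ0(s)] · exp(x β̂_LM(s) + γ̂(s)))
```

Model performance is tracked per landmark with a window-restricted Harrell
C-index, an IPCW Brier score at the horizon (against the conditional
Kaplan–Meier null), and a cumulative/dynamic time-dependent AUC.

Because each subject contributes rows to many strata, reported standard
errors are cluster-robust (sandwich) with clustering on subject id.

## Worked example

```python
import numpy as np
from dynamark import (table1_design, generate_cohort, fit_cox, prognostic_index,
                      tv_effect_test, censoring_km, default_design,
                      build_landmark_dataset, fit_proportional_supermodel,
                      beta_lm, dynamic_death_probability)
from dynamark.evaluate import evaluate_all

cohort = generate_cohort(table1_design(n=550, seed=1))
covs = [c for c in cohort.columns if c not in ("id", "time", "status")]
cox = fit_cox(cohort, covs)
cohort = cohort.assign(pi=prognostic_index(cohort, cox))

design = default_design()            # w = 5, landmarks 0.0 .. 3.0 by 0.1
sd = build_landmark_dataset(cohort, design, ["pi"])
prop = fit_proportional_supermodel(sd)
row = beta_lm(prop, 1.5)
curves = evaluate_all(cohort, design, prop)
```

Output (printed by the snippet above plus a few summaries):

```
events: 141/550
median follow-up: 2.84 years
PI mean: 6.46e-17, sd: 1.40
                part covariate time_function   coef    se
proportional hazards        pi      constant  1.015 0.067
proportional hazards        pi        linear  0.169 0.226
proportional hazards        pi     quadratic -0.473 0.261
proportional hazards  gamma(s)        linear -0.013 0.245
proportional hazards  gamma(s)     quadratic  0.204 0.208
beta_LM(1.5) = 0.982 (95% CI 0.816 to 1.147), dynamic HR = 2.67
P(die in (1.5, 6.5] | alive at 1.5, PI=-1.4) = 0.082
P(die in (1.5, 6.5] | alive at 1.5, PI=+0.0) = 0.287
P(die in (1.5, 6.5] | alive at 1.5, PI=+1.4) = 0.737
dynamic C (landmark average): 0.793
mean Brier, model vs KM null: 0.162 vs 0.223
```

Reading the numbers: the censoring pattern of the synthetic registry gives a
median follow-up below 3 years; the prognostic index is centered by
construction (mean ~1e-16) with SD 1.40. The supermodel's constant term
(~1.0) says a one-SD-higher PI roughly e^1 ≈ 2.7-folds the hazard of dying
within the next five years, and `beta_lm` turns the θ's into the
landmark-varying effect with a pointwise CI. The dynamic death
probabilities order correctly in PI, the dynamic C-index stays near 0.8,
and the model's prediction-error curve sits below the Kaplan–Meier null at
every landmark — the model carries real predictive information.

## Command line

```sh
dynamark simulate --preset table1 --n 550 --seed 1 --out cohort.csv
dynamark all --preset table1 --n 550 --seed 1 --out results/
dynamark all --input-csv cohort.csv --window 5 --grid-step 0.1 --out results/
```

`dynamark all` writes every table and curve as CSV (covariate summary, Cox
HR table, PI summary, supermodel coefficient tables, dynamic
death-probability curves, landmark-effect curves with CIs, evaluation
curves) plus figure analogues and a `manifest.json` recording the seed,
config hash and versions. Every figure has a CSV twin.

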
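# litpk — population pharmacokinetics of lithium

Lithium remains a first-line treatment for bipolar disorder, but its narrow
therapeutic index (maintenance trough target 0.4–0.8 mmol/L, acute
0.6–1.2 mmol/L) makes dosing a perennial clinical problem, especially when
renal function or body size deviate from average.  `litpk` is a
self-contained Python implementation of the standard pharmacometric
workflow used to answer that question from routine therapeutic-drug-
monitoring (trough-only) data:

* a one-compartment oral structural model with first-order absorption
  (Ka fixed at 0.293 h⁻¹) and elimination, parameterised as CL/F and V/F;
* nonlinear mixed-effects estimation by **FOCE with interaction**,
  including empirical Bayes etas, shrinkage, CWRES, standard errors and
  condition number — implemented from scratch and validated against ODE
  and adaptive Gauss–Hermite quadrature oracles;
* three-step **stepwise covariate modelling** (correlation screening,
  forward inclusion at ΔOFV > 3.84, backward elimination at ΔOFV < 6.63);
* model qualification by subject-level **bootstrap** and **visual
  predictive check** (numeric tables);
* **Monte Carlo dose-regimen simulation** of steady-state troughs over
  weight × creatinine-clearance × dose grids with target-attainment-based
  dose recommendation;
* a **synthetic-data generator** that emulates the reference study
  population (268 patients, ≈ 476 troughs, two-thirds female, median
  62 kg / 600 mg/day, Cockcroft–Gault creatinine clearance), so the whole
  analysis runs with no external data.

The central model is the fitted clearance covariate relationship

```
CL/F (L/h) = 0.909 · (TDD/600)^0.354 · (WT/62)^0.33 · (CRCL/116)^0.186
V/F  (L)   = 10.9          Ka (h⁻¹) = 0.293 (fixed)
```

with lognormal between-subject variability (16.4% on CL, 40.2% on V) and
additive residual error (SD 0.0218 mmol/L).  The dose exponent 0.354 < 1
captures lithium's nonlinear renal excretion: clearance rises with the
daily dose, so troughs grow sublinearly in dose.

See `docs/methods.md` for the full model, estimation details, generator
design and known limitations.

## Worked example

```python
from litpk import (PopulationSpec, generate_population, generate_dataset,
                   final_lithium_model, fit, EstimationSettings,
                   simulate_troughs, MAINTENANCE_WINDOW, recommend_dose)
from litpk.model_core import PopulationModel, CovariateEffect, ResidualModel

# 1. a synthetic study: 268 subjects, trough-only q12h design
pop = generate_population(PopulationSpec(), seed=1)
ds = generate_dataset(pop, final_lithium_model(), seed=2)

# 2. refit the final-model structure from generic initial values
skeleton = PopulationModel(
    theta_cl=1.0, theta_v=8.0, ka=0.293,
    covariate_effects=(
        CovariateEffect("cl", "tdd", "power", 0.1, 600.0),
        CovariateEffect("cl", "wt", "power", 0.1, 62.0),
        CovariateEffect("cl", "crcl", "power", 0.1, 116.0),
    ),
    omega2_cl=0.05, omega2_v=0.1,
    residual=ResidualModel("additive", sigma2_add=0.03**2),
)
res = fit(ds, skeleton, EstimationSettings())
print(res.param_table())
```

prints (this exact run):

```
     parameter  estimate  rse_percent
      theta_cl  0.871524    16.297531
       theta_v  8.799216    65.081645
   beta_cl_tdd  0.373331    12.002457
    beta_cl_wt  0.231880    32.674202
  beta_cl_crcl  0.227126    22.474660
bsv_cl_percent 14.275691    20.876477
 bsv_v_percent 36.166894    33.852725
     sigma_add  0.021386     4.877526
```

The typical clearance (0.87 L/h) lands within 5% of the generating
0.909 L/h and all three covariate exponents sit inside the model's
reported 95% intervals; V/F is, as expected for a trough-only design,
only loosely determined (46% eta-shrinkage on V in this run).

```python
# 3. dose selection for a 100 kg patient, normal vs impaired renal function
dists = simulate_troughs(
    final_lithium_model(),
    {"weights": [100.0], "crcls": [30.0, 120.0], "daily_doses": [500.0, 750.0]},
    n=1000, seed=3)
print(recommend_dose(dists, MAINTENANCE_WINDOW))
```

```
 weight  crcl  daily_dose    n   median     p2.5    p97.5  attainment  recommended
  100.0  30.0       500.0 1000 0.574396 0.343048 0.872408       0.860         True
  100.0  30.0       750.0 1000 0.721179 0.418385 1.093329       0.668        False
  100.0 120.0       500.0 1000 0.417888 0.221936 0.651630       0.569        False
  100.0 120.0       750.0 1000 0.510034 0.279485 0.820459       0.774         True
```

With normal renal function (CRCL 120 ml/min) 750 mg/day keeps the median
day-7 trough at 0.51 mmol/L with 77% of patients inside the maintenance
window; with renal impairment (CRCL 30 ml/min) clearance falls by 23% and
500 mg/day becomes the better choice — 750 mg/day would push a third of
patients above 0.8 mmol/L.

A CLI mirrors the pipeline stages
(`litpk gen-data | fit | scm | bootstrap | vpc | simulate-dose | run`,
each taking `--config config.yaml --seed N --out-dir DIR`) and writes CSV
tables plus a run log.

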
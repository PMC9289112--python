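# Methods

## Scope

`litpk` re-implements, as a tested library, a sparse-data population
pharmacokinetic (PPK) analysis of lithium carbonate in adults and
adolescents with bipolar disorder on maintenance therapy, together with the
model-based dose-selection study built on it.  Because the underlying
patient-level data are not public, the package ships a synthetic-data
generator that emulates the study population; every estimation and
qualification procedure runs end to end on generated data.

## Structural and statistical model

Only pre-dose (trough) samples exist in this setting, so the structural
model is a one-compartment disposition model with first-order absorption
and elimination, parameterised as apparent clearance CL/F (L/h) and
apparent volume V/F (L).  The absorption rate constant is fixed,
Ka = 0.293 h⁻¹, because trough-only data carry essentially no absorption
information.  Concentrations are superpositions of the closed-form
single-dose solution

    C(t) = (D·ka) / (V·(ka − ke)) · (e^(−ke·t) − e^(−ka·t)),  ke = CL/V,

summed over administered doses; for equal doses at a fixed interval the sum
collapses to a geometric closed form, and the removable ka = ke singularity
switches to the D·ka·t·e^(−ka·t)/V limit when |ka − ke|/ka < 1e−8.  Doses
are milligrams of lithium carbonate, converted to millimoles of lithium
ion with 0.0270662 mmol/mg (two Li⁺ per Li₂CO₃, MW 73.893 g/mol);
concentrations are mmol/L throughout.

Between-subject variability (BSV) is lognormal, `P_i = P_tv·exp(η_i)` with
`η ~ N(0, ω²)` on CL and V (diagonal Ω).  BSV is reported as
%BSV = 100·√ω².  The residual model may be additive, proportional or
combined; the final lithium model is additive with SD 0.0218 mmol/L.

Covariates act multiplicatively on typical values through power, linear or
categorical terms anchored at frozen reference values.  The final clearance
model is

    CL/F = 0.909 · (TDD/600)^0.354 · (WT/62)^0.33 · (CRCL/116)^0.186  L/h
    V/F  = 10.9 L,   Ka = 0.293 h⁻¹ (fixed),

with ω²_CL = 0.027 (16.4 %BSV) and ω²_V = 0.162 (40.2 %BSV).  The
references 600 mg/day, 62 kg and 116 ml/min are fixed constants of the
model, not recomputed dataset medians.  The dose-on-clearance exponent
(0.354 < 1) encodes the nonlinear (saturable reabsorption) renal handling
of lithium: troughs grow sublinearly with the daily dose.

Creatinine clearance is always derived by Cockcroft–Gault,

    CRCL = (140 − age)·WT / (0.818·SCR) · k,   k = 1 (male), 0.85 (female),

with SCR in µmol/L.

## Estimation (FOCE-I)

Fixed effects, BSV variances and residual variances are estimated by
first-order conditional estimation with interaction.  For each subject the
empirical Bayes η* minimises the penalised conditional deviance
`Σ_j[(y_j − f_j(η))²/σ²_j(η) + log σ²_j(η)] + ηᵀΩ⁻¹η`, solved by a damped
Gauss–Newton iteration vectorised across subjects (prediction sensitivities
by central differences with step 1e−4 on η; absolute deviance tolerance
1e−10, at most 60 iterations with step halving).  The objective is

    OFV = Σ_i [ log|V_i| + r_iᵀV_i⁻¹r_i + n_i·log 2π ],

with G_i = ∂f/∂η at η*_i, V_i = G_iΩG_iᵀ + Σ_i(η*_i) and
r_i = y_i − f_i(η*_i) + G_i·η*_i.  The residual variance Σ is evaluated at
η* (the interaction); with an additive residual this coincides with plain
FOCE, but the code path is identical so proportional/combined models are
handled correctly.

The outer problem optimises log-transformed positive parameters (θ_CL,
θ_V, ω², σ²; covariate coefficients untransformed) with L-BFGS-B and a
central finite-difference gradient (relative step 3e−5; ftol 1e−8).  A
variance set to exactly 0 in the starting skeleton is treated as
structurally absent (its η is fixed at 0), which also gives the degenerate
weighted-least-squares mode used in tests.  Fits are deterministic given
data and settings.

Standard errors come from the inverse of one half of a central
finite-difference Hessian of the OFV (relative step 5e−3), delta-method
transformed to the reporting scale; the condition number is the eigenvalue
ratio of the implied correlation matrix.  η-shrinkage is
100·(1 − sd(η*)/√ω²), ε-shrinkage 100·(1 − sd(IWRES)).

Below-LLOQ samples (< 0.19 mmol/L) are excluded from the objective when
they are under 10% of all observations and are an error otherwise;
continuous covariates missing in under 10% of rows are median-imputed on
read, more is an error.

Validation anchors: the closed-form concentration matches numerical ODE
integration to 1e−6 relative on randomised instances, and the FOCE OFV
matches a 32-node adaptive Gauss–Hermite −2 log-likelihood within 0.1 on a
five-subject toy at ω = 0.05, with the gap shrinking monotonically as
ω → 0.

## Covariate selection

A three-step stepwise covariate modelling (SCM) procedure: (1) screening
by the Pearson (point-biserial for 0/1) correlation between the empirical
Bayes η_CL and each candidate covariate, keeping |r| ≥ 0.1; (2) greedy
forward inclusion, accepting the largest OFV drop when it exceeds 3.84
(χ²₁, p < 0.05); (3) backward elimination, removing a covariate when its
deletion raises the OFV by less than 6.63 (p > 0.01).  Candidates are
tested on CL only (V is shrinkage-dominated in a trough-only design); sex
is coded 0 = female (the majority class), 1 = male.  Ties break on
declaration order, so the search is deterministic.

## Synthetic population and study design

The generator reproduces the source study's demographic table: 268
subjects, 66.8% female, 76.1% sustained-release formulation, and one or
two steady-state pre-dose troughs per subject (P(two) = 0.776, ≈ 476
samples in expectation), every observation preceded by at least 14 q12h
administrations.

Only medians, ranges and means ± SD are published, so distribution
families are the package's own choice:

* weight ~ truncated normal(63.7, 11.1) kg on [35, 110];
* serum creatinine ~ truncated normal(63.7, 12.6) µmol/L on [40, 115];
* age is right-skewed (median 31 < mean 35): 13 + lognormal(median 19 y,
  σ_log 0.70), truncated at 77 y — a truncated normal cannot produce this
  median/mean pair;
* total daily dose ~ lognormal(median 600 mg, σ_log 0.75) rounded to a
  150 mg half-tablet grid and clamped to [150, 1500] mg, reproducing the
  median (600) and mean (≈ 710 vs 720) of the study; its SD (≈ 430 mg) is
  wider than the printed 236 mg — no two-parameter lognormal can match
  median, mean and SD simultaneously — which makes the dose signal in
  synthetic data somewhat stronger than in the real study;
* CRCL is always derived from the sampled age/weight/SCR/sex via
  Cockcroft–Gault (population mean ≈ 120 vs 118 ml/min), never sampled.

Observations are simulated from the final model (η and additive ε drawn
per subject/sample) and flagged BLQ below 0.19 mmol/L; with these
defaults the BLQ fraction stays near 1%, well under the 10% rule.  Age and
dosage form are carried but have no generating effect, matching the final
model.  The generator does not emulate within-subject dose titration,
irregular sampling times, assay batch effects, or covariate measurement
error — so passing tests demonstrate the machinery's correctness under the
stated design, not robustness to those real-data features.

## Dose-regimen simulation

For each (weight, CRCL, daily dose) stratum, 1000 virtual patients draw η
from the final model, receive the daily dose as two equal q12h
administrations for 7 days, and contribute the day-7 pre-dose trough
(closed-form superposition; steady state is reached well before day 7).
No residual error is added by default: the decision target is the true
trough, not a noisy measurement (a flag adds ε for TDM-emulation studies).
The q12h split is a package choice — the daily dose must be divided for
typical troughs to sit inside the maintenance window; once-daily
administration of the same daily doses gives materially lower troughs.
Attainment is the fraction of troughs inside the therapeutic window
(maintenance 0.4–0.8, acute 0.6–1.2 mmol/L); the recommended dose is the
attainment argmax, ties to the lower dose.  Each stratum uses an
independent seeded stream, so results are reproducible and grid-order
invariant.

## Numerical choices and known limitations

* Trough-only single-TAD data weakly identify V/F; a flip-flop local
  optimum (ke > ka, small V) exists and can capture small-sample fits
  (n ≲ 40).  Full-size fits and warm-started refits (SCM steps, bootstrap
  replicates started at the final estimates) stay in the physiological
  basin; occasional bootstrap replicates that wander produce the long
  lower tail visible in the CL percentile table.
* The sensitivity of the CL estimate to the fixed Ka is larger here
  (≈ ±20% across Ka 0.146–0.586) than in the source analysis (≈ ±7%),
  because every synthetic sample sits at exactly 12 h after dose, where
  the absorption tail is maximally confounded with clearance; clinically
  scattered sampling times damp this.
* Bootstrap resamples whole subjects with replacement to the original
  subject count; replicate convergence is the outer optimiser's own
  criterion (a positive-definite Hessian is not required).
* The VPC is uncorrected (no prediction correction) and defaults to a
  single bin because all observations share a common time after dose;
  optional quantile binning on time after first dose is available.
* Default problem sizes in the shipped tests are scaled for a single CPU:
  20 SCM replicates, 100 bootstrap replicates, 300–400 VPC simulations.
  The API defaults remain 1000 where the procedure's own definition uses
  1000 (bootstrap, VPC, dose simulation).
* Real-data quantities (the ΔOFV of 70.12 for dose inclusion, bootstrap
  medians, the 96.5% bootstrap convergence rate, the Ka-sensitivity CL
  range) depend on the unavailable original dataset and are covered only
  by property-level analogues on synthetic data.
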
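# Methods

This note documents the models, algorithms, and numerical choices behind
`voripk`, in the order the analysis uses them.

## Scientific setting

Voriconazole is a triazole antifungal cleared mainly by CYP2C19.  Two
patient-level factors interact to determine exposure: the CYP2C19
metabolizer phenotype (normal / intermediate / poor: NM / IM / PM) and
systemic inflammation, because pro-inflammatory cytokines down-regulate
CYP transcription.  C-reactive protein (CRP, mg/L) serves as the
inflammation marker.  The package implements a population-pharmacokinetic
(PPK) analysis in which CRP lowers clearance in NM and IM patients but
not in PM patients — patients with little functional enzyme have little
activity left to suppress — and uses the fitted model to ask which
twice-daily intravenous maintenance dose keeps steady-state troughs in
the 0.5–5.0 µg/mL therapeutic window.

## Structural and statistical model

One-compartment kinetics with first-order absorption (oral) or
zero-order infusion (IV), parameterized by clearance CL (L/h), volume V
(L), absorption rate constant ka (fixed at 1.1 h⁻¹ — trough-only data
carry no absorption-phase information), and bioavailability F.
Concentrations are in mg/L ≡ µg/mL.  All closed forms (single dose,
multiple-dose superposition, finite-dose and steady-state troughs) are
validated against an adaptive Runge–Kutta integration of the underlying
ODEs to ≤1e-6 relative error.  A Michaelis–Menten elimination variant is
available as a numerical-ODE comparison model only; superposition is
refused for it.

Covariates enter multiplicatively on the typical values:

    TVCL = CL_typ · 0.794^IM · 0.635^PM · exp(−0.155·CRP/59)[NM,IM]
           · (AGE/71)^−0.582 · (ALB/34.8)^0.644 · 1.41^female
    TVV  = V_typ · (WT/65)^2.21

with CL_typ = 3.83 L/h, V_typ = 134 L, F = 0.965.  Continuous covariates
are centered at the cohort medians; the reference patient is a 71-year-old
65-kg man with albumin 34.8 g/L.  The CRP factor is referenced to CRP = 0
(factor 1), and the generic covariate machinery supports linear, power,
and exponential forms for continuous covariates and a power form for
categorical ones, including per-phenotype effect masks (the pooled NM+IM
CRP slope is one such mask; per-phenotype slopes are a config away).

Inter-individual variability is exponential on CL and V
(P_i = TVP·exp(η), η ~ N(0, ω²); ω_CL = 0.389, ω_V = 0.452 stored as SDs
on the log scale and displayed ×100 as approximate CV%).  No IIV is
placed on F or ka.  Residual error is combined exponential-proportional
plus additive: y = f·exp(ε₁) + ε₂ with SD(ε₁) = 0.147 and SD(ε₂) = 0.58
µg/mL.  Observations below the 0.1 µg/mL quantification limit (the lower
edge of the assay's linear range) are discarded before estimation (M1),
with the removal logged.

## FOCE-I estimation

The marginal likelihood of each subject's trough vector is approximated
by first-order conditional estimation with interaction: the model is
linearized at the subject's conditional mode η̂ (the minimizer of the
penalized individual objective), and the residual variance
v = f²σ₁² + σ₂² is evaluated at η̂ rather than at η = 0.  The subject
contribution is log|C| + r′C⁻¹r with C = GΩG′ + diag(v),
r = y − f(η̂) + Gη̂, and G = ∂f/∂η at η̂.  The n·log 2π constant is
dropped (so differences between nested models compare directly to χ²
quantiles, 3.84 / 6.63 at 1 df); the full-constant value is exposed for
the quadrature cross-check below.

Numerical choices, in decreasing order of consequence:

* **Inner problem.**  The conditional mode is found by a damped
  Gauss–Newton iteration, vectorized across all subjects at once, with
  analytic ∂f/∂CL and ∂f/∂V from the closed forms.  Convergence is
  declared when the Newton decrement g′H⁻¹g falls below 1e-11; steps are
  trust-region-capped at 4 log units and a backtracking line search
  guarantees monotone descent.  The inner solve always starts from
  η = 0: this makes the outer objective an exactly deterministic function
  of the parameters, which the finite-difference outer gradient requires
  (warm-starting across outer iterations left history-dependent noise of
  ~1e-2 in the objective, larger than any usable difference step).
* **Outer problem.**  L-BFGS-B on transformed parameters (log scale for
  CL, V, F, ω, σ and categorical factors; untransformed slopes and
  exponents), difference step 1e-5, relative tolerance 1e-6, with an
  optional Nelder–Mead polish (on by default; replicate studies switch it
  off).  ka is never estimated; F is automatically fixed when a dataset
  contains no post-oral-dose observations, where it is unidentifiable,
  and is capped at 1.2.
* **Uncertainty.**  Relative standard errors come from the central
  finite-difference Hessian of the objective (step 1e-4 on the
  transformed scale), Cov = 2H⁻¹, delta method back to natural scale.  A
  non-positive-definite Hessian marks the fit unconverged.
* **Shrinkage.**  η-shrinkage = (1 − SD(η̂)/ω)·100 per effect;
  ε-shrinkage = (1 − SD(IWRES))·100.  With trough-only sampling the V
  shrinkage is expected to be far larger than the CL shrinkage — there
  is no distribution-phase information — and the test suite asserts that
  ordering.

An independent oracle guards the approximation: −2 log L by 31-node
adaptive Gauss–Hermite quadrature (tensor grid over the two random
effects, centered at η̂ and scaled by the curvature of the log
integrand).  On small cohorts the FOCE-I value stays within 2 units of
the quadrature value.

## Covariate model building

Candidate effects are screened pairwise with Spearman rank correlations
(which doubles as a point-biserial analogue for binary covariates); pairs
with |r| > 0.5 may not enter a model together.  Stepwise covariate
modeling is greedy best-first: every admissible (covariate, parameter,
form) extension is fitted per forward round, the largest OFV drop ≥ 3.84
is accepted (ties broken lexicographically), and backward elimination
then removes any effect whose removal costs < 6.63.  Each candidate fit
is warm-started from the incumbent with the new coefficient at its
neutral value; a failed candidate fit is logged and treated as
non-improving.  The step log is a complete replayable audit.  The same
3.84 yardstick is applied to every candidate regardless of the number of
parameters it adds (the phenotype pair adds two); a stricter
per-df threshold is a one-line change.

`crp_phenotype_test` compares the three nested treatments of the
CRP-phenotype interaction — a separate exponential slope per phenotype, a
pooled NM+IM slope with PM excluded, and no CRP effect — and reports the
pairwise ΔOFV under the same decision rules.

**Calibration checks.**  Two simulation studies accompany the selection
machinery.  (1) Type-I error follows the textbook construction: cohorts
generated with no covariate effects, base model vs base + CRP slope; the
null ΔOFV tracks χ²₁ (observed median ≈ 0.49 vs 0.455) and the ≥3.84
rejection rate stays at its nominal ~5%.  (2) Power is evaluated for the
decisive CRP step given the other final-model covariates: model without
CRP vs with CRP, with the nuisance covariate coefficients held at their
generating values (the LRT df is unchanged and the comparison is exact in
the simulation setting).  This conditional form is used because a single
CRP candidate added to the covariate-free base under the full final-model
truth is confounded by five other unmodelled effects and its ΔOFV is
erratic; the conditional step yields ΔOFV ≈ 25–45 at n = 300, the same
magnitude as the published inclusion statistic, and is detected in
essentially every replicate.

## Model validation

* **CWRES / GOF.**  Conditional weighted residuals use the FOCE
  linearization and full-covariance (Cholesky) decorrelation, alongside
  PRED (η = 0), IPRED (η = η̂), and IWRES; the four-panel GOF plot
  mirrors the standard layout.
* **Bootstrap.**  Subjects are resampled with replacement and refitted;
  medians and 2.5/97.5 percentiles are reported per parameter, with
  non-converged replicates counted and excluded.  Fixed seeds make runs
  bit-reproducible; an explicit index hook supports the identity-resample
  check.
* **VPC.**  Observed 5/50/95th percentiles per equal-count bin of time
  after last dose, stratified by route, against the 95% interval of the
  same percentiles over simulated replicates of the design.  Trough-only
  designs collapse to a single 12-h bin per stratum, which is handled
  explicitly.  Default 6 bins; prediction correction is not implemented.
* **NPDE.**  Per subject, the observed vector and n_sim simulated vectors
  are decorrelated with the simulated mean and lower-Cholesky factor of
  the simulated covariance; the prediction-distribution error (rank of
  the observation among its simulations, ties jittered with seeded 1e-10
  noise, clipped to (1/2K, 1−1/2K)) maps through the inverse normal.
  Tests: one-sample t (mean 0), a two-sided χ² variance test against 1
  (the "Fisher" variance test), Shapiro–Wilk normality, and a Bonferroni
  global p = min(1, 3·min p).  An exact-replica simulation (zero
  variance) raises rather than returning NaNs.  Under a correct model at
  the study scale (~232 troughs) the NPDE mean is ≈0.03 and variance
  ≈0.8–1.1.

## Synthetic cohorts

The generator emulates the studied inpatient cohort (167 adults, 232
steady-state troughs):

* **Covariates.**  Truncated normals for age (68.87 ± 14.87, 16–97 y),
  weight (64.48 ± 12.24, 37–100 kg), albumin (36.36 ± 8.54, 18.3–75.1
  g/L) and hemoglobin; truncated log-normals for the right-skewed labs
  — CRP (77.10 ± 68.74, 0.9–306.6 mg/L), AST, ALT, total bilirubin,
  platelets, creatinine, urate.  Each marginal is moment-matched so the
  *truncated* distribution has the reported mean and SD (naively
  truncating a normal at the observed range would, e.g., bias the age
  mean by about −1 y).  Phenotype frequencies 0.395/0.431/0.174
  (NM/IM/PM), P(male) = 119/167, proton-pump-inhibitor flag 0.701,
  glucocorticoid flag 0.257.  Covariates are independent by default (the
  study reports only a collinearity screen); a Gaussian-copula hook
  accepts a user correlation matrix.
* **Regimens.**  Three arms with the observed mix 57:4:106 — IV loading
  (two doses on day 1; 400→200 mg under 70 kg, 600→300 mg above) then IV
  maintenance bid; oral loading (400 mg bid day 1) then 200 mg oral bid;
  flat 200 mg bid without loading, split 50/50 IV/oral (the split within
  the flat arm is unreported).  Infusions default to 2 h, stretched
  whenever 3 mg/kg/h would otherwise be exceeded.
* **Sampling.**  Trough-only, immediately before a dose: day 3 for
  loading arms, day 5 otherwise, with a second trough 48 h later at
  probability 65/167 so the expected count is 232 per 167 subjects.
  Simulated concentrations apply the full residual model; non-positive
  draws are truncated to LLOQ/2 and flagged BQL (rather than resampled)
  so the M1 path stays exercised; under the default truth the BQL
  fraction is well under 5%.

What the generator does **not** emulate: physician dose adjustments
between the two troughs, time-varying CRP trajectories, covariate
correlations (unless supplied), and any real per-patient data — the
study's records are not public.  Passing tests therefore demonstrate
internal consistency and statistical calibration of the methods under
the published design and parameters, not a reanalysis of the original
patients.

## Dose simulation

`simulate_pta` draws (η_CL, η_V) for the typical patient at a given
phenotype and CRP, computes each individual's trough before the 11th
twice-daily dose — i.e. after five days of treatment, the sampling day
of the study's non-loading patients — and classifies it against the
0.5/5.0 µg/mL cut-offs (boundary values count as therapeutic; the three
fractions partition to 1 exactly).  The day-5 convention matters: at
CRP 250 mg/L the NM clearance falls to ≈2 L/h and the accumulation
half-life approaches 47 h, so day-5 troughs sit well below the
infinite-time steady state, and reproducing the published attainment
percentages requires the finite horizon.  `n_doses=None` selects the
analytic steady-state trough instead.  Residual error is excluded by
default (attainment reflects true individual exposure); a flag includes
it for sensitivity.  CRP strata are represented by single values — 5
mg/L for "<10" and 250 mg/L for ">200" — because the values used inside
the published strata are not stated.  `recommend_dose` maximizes the
therapeutic fraction over the 50–250 mg grid, ties to the lower dose.

## Problem sizes used by the tests and acceptance script

Parameter recovery runs one 300-subject cohort; selection calibration
runs 30 null replicates at n = 150 and 10 power replicates at n = 300;
bootstrap behavior is exercised at 8–10 replicates on small cohorts;
NPDE calibration uses the study-sized design with 1000 simulations; PTA
uses 1e5 draws per cell (Monte Carlo SE < 0.2 percentage points).  These
sizes are the package's choice of a desk-scale experiment battery; the
module APIs accept the full-size settings (e.g. 1000 bootstrap
replicates) unchanged.

## Known limitations

* FOCE-I with one–two troughs per subject carries the usual small-data
  biases: V is weakly identified (shrinkage ≈ 60–70%) and its estimate
  can sit 10–25% above the generating value while remaining inside the
  reported confidence band; ω_V is similarly soft.
* The exponential residual component is linearized to proportional in
  the variance expression (standard practice); the quadrature oracle
  integrates the same linearized conditional density.
* The printed per-phenotype CL-decrease percentages in the source
  analysis are not mutually consistent with any single parameterization
  of the exponential CRP model; the package implements the pooled-slope
  final equation and the per-phenotype slopes as reported, without
  attempting to reconcile those percentages.
* Dose-adjustment feedback ("adjust to the measured trough") is not
  modelled; all simulated regimens are fixed.
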
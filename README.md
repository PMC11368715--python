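# voripk

Population pharmacokinetics of voriconazole with a CYP2C19-phenotype–
dependent C-reactive-protein (CRP) effect on clearance.

Voriconazole exposure in adult inpatients varies several-fold between
patients.  Two drivers interact: the CYP2C19 metabolizer phenotype
(normal / intermediate / poor — NM / IM / PM) and inflammation, which
down-regulates CYP-mediated metabolism.  `voripk` implements the full
analysis cycle a pharmacometrician would run on such a cohort:

* **synthetic cohorts** matching the demographics, dosing regimens, and
  trough-only sampling of a 167-patient inpatient study;
* **one-compartment structural PK** (first-order absorption, IV
  infusion, superposition, steady state) with an ODE oracle;
* **FOCE-I nonlinear mixed-effects estimation** (conditional modes,
  objective function, standard errors, EBEs, shrinkage) with an adaptive
  Gauss–Hermite cross-check;
* **stepwise covariate modeling** (forward ΔOFV ≥ 3.84 / backward 6.63,
  collinearity prescreen, phenotype-specific CRP comparison);
* **validation**: CWRES goodness of fit, nonparametric bootstrap, visual
  predictive checks, normalized prediction distribution errors;
* **Monte Carlo dose simulation** with probability-of-target-attainment
  (PTA) reporting for the 0.5–5.0 µg/mL trough window.

## The model

Individual parameters follow log-normal inter-individual variability
around covariate-adjusted typical values:

    CL_i = TVCL · exp(η₁),  V_i = TVV · exp(η₂),  η ~ N(0, ω²)

    TVCL = 3.83 · 0.794^IM · 0.635^PM · e^(−0.155·CRP/59) [NM, IM only]
           · (AGE/71)^−0.582 · (ALB/34.8)^0.644 · 1.41^female   [L/h]
    TVV  = 134 · (WT/65)^2.21                                   [L]

with F = 96.5%, ka fixed at 1.1 h⁻¹, combined residual error
y = f·e^(ε₁) + ε₂, and the M1 convention (discard) for concentrations
below the 0.1 µg/mL quantification limit.  The CRP term is the model's
headline: clearance falls with inflammation in NM and IM patients and is
CRP-independent in PM patients.

## Worked example

```python
import voripk as vp

# 1. a synthetic cohort at the study design
subjects = vp.generate_cohort(vp.CohortConfig(n_subjects=300), seed=2026)

# 2. refit the final model by FOCE-I from neutral starting values
init = vp.ThetaOmegaSigma(cl=3.0, v=100.0, f=0.9, crp_slope=0.0,
                          im_factor=1.0, pm_factor=1.0, alb_exp=0.0,
                          sex_factor=1.0, age_exp=0.0, wt_exp=0.0,
                          omega_cl=0.3, omega_v=0.3,
                          sigma_prop=0.2, sigma_add=0.3)
fit = vp.fit(subjects, vp.final_model_spec(), init,
             compute_se=False, polish=False)
print(f"CL {fit.estimates.cl:.2f} L/h  V {fit.estimates.v:.0f} L  "
      f"CRP slope {fit.estimates.crp_slope:.3f}")

# 3. probability of target attainment, 200 mg q12h IV, typical patient
for crp in (5.0, 250.0):
    r = vp.simulate_pta(vp.Regimen(dose=200.0), "NM", crp,
                        n_sim=100_000, seed=1)
    print(f"NM, CRP {crp:>5.0f} mg/L: {100*r.fraction_therapeutic:.1f}% "
          f"therapeutic, {100*r.fraction_toxic:.1f}% above 5 µg/mL")
```

Output:

```
CL 4.07 L/h  V 166 L  CRP slope -0.154
NM, CRP     5 mg/L: 83.4% therapeutic, 16.5% above 5 µg/mL
NM, CRP   250 mg/L: 28.2% therapeutic, 71.8% above 5 µg/mL
```

The refit recovers the generating parameters (CL 3.83, V 134, slope
−0.155) within the sampling uncertainty of a 300-subject trough-only
design, and the dose simulation shows the clinical point: at 200 mg
twice daily, a typical NM patient with high CRP has a ~70% chance of a
potentially toxic trough, so inflamed patients need lower doses.
`vp.recommend_dose("NM", 250.0)` returns the grid dose with the best
therapeutic fraction.

A command-line interface mirrors the library
(`voripk generate|fit|scm|bootstrap|vpc|npde|gof|pta`); every stochastic
verb takes `--seed`.

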
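# lvfda

Functional data analysis of left-ventricular strain and torsion curves in
hemodialysis patients: does diastolic *untwist* protect systolic blood
pressure during fluid removal, and does it predict survival?

During dialysis, ultrafiltration induces intravascular hypovolemia; the
rapid untwisting of the LV after its systolic torsion peak generates the
diastolic suction that keeps the ventricle filling. `lvfda` treats
speckle-tracking strain traces — global longitudinal strain (GLS), LV
torsion (apical − basal rotation) and RV free-wall strain — as functions of
the cardiac cycle and fits **penalized-spline scalar-on-function
regressions**:

* a **multilevel Gaussian model** for repeated intradialytic SBP
  (7 measurements × 3 sessions per patient),

      SBP_ikj = α + occ_j + z_i'γ + Σ_m ∫ β_m(t) X_im(t) dt + b_i + ε_ikj,
      b_i ~ N(0, σ_b²),  ε ~ N(0, σ_ε²),

* a **binomial logit model** for all-cause mortality with the GLS and
  torsion curves as predictors, where β(t) is a log-odds curve.

Each coefficient function β(t) is a K = 9 cubic B-spline expansion with a
second-order difference penalty; smoothing parameters, the random-intercept
variance and σ_ε are selected jointly by REML (Laplace-approximate REML for
the binomial family). Inference includes pointwise Wald bands, cluster
(patient-level) bootstrap percentile bands, Wald/edf global tests per
functional term, and interpretable *curve-perturbation* effects: the odds
ratio or mmHg change implied by shifting a covariate curve by δ units over a
window of the cycle (default the diastolic half, t > 0.5).

Because the study's patient data are external, the package ships a
**synthetic cohort generator** calibrated to the published cohort
characteristics (curve peak amplitudes/timings, covariate moments, an 8%
marginal death rate) so every stage — normalization, fitting, inference,
reporting — is testable end to end, including parameter-recovery
experiments at the study size (70 patients).

Intended users: biostatisticians and cardiology/nephrology researchers
working with exported speckle-tracking curves and repeated hemodynamic
measurements.

## Worked example

```python
from lvfda import (SyntheticConfig, generate_cohort, fit_sofr_gaussian,
                   fit_sofr_binomial, Perturbation, perturbation_effect)

cohort = generate_cohort(SyntheticConfig(), seed=2024)   # 70 patients
fit = fit_sofr_gaussian(cohort)                          # SBP model
for name in ("ultrafiltrate", "age", "ivc_diameter"):
    t = fit.scalar(name)
    print(f"{name:14s} {t.estimate: .4f}  [{t.ci_low: .4f}, {t.ci_high: .4f}]  p={t.p:.3f}")
print(f"sigma_b={fit.sigma_b:.2f}  sigma_eps={fit.sigma_eps:.2f}  R2={fit.variance_explained:.2f}")

mort = fit_sofr_binomial(cohort)                         # mortality model
e = perturbation_effect(mort, Perturbation("torsion", +5.0))  # +5 deg after t=0.5
print(f"mortality OR: {e.estimate:.2f} [{e.ci_low:.2f}, {e.ci_high:.2f}]")
```

prints (this exact seed):

```
ultrafiltrate  -0.0014  [-0.0045,  0.0016]  p=0.356
age            -0.1681  [-0.3165, -0.0196]  p=0.026
ivc_diameter    0.6037  [-0.0871,  1.2945]  p=0.087
sigma_b=7.32  sigma_eps=9.80  R2=0.56
mortality OR: 1.59 [0.30, 8.47]
```

Reading this: in this synthetic cohort each extra year of age is associated
with 0.17 mmHg lower intradialytic SBP (95% CI excludes 0); the
random-intercept and residual SDs recover the generating values (8 and
10 mmHg); and a patient whose torsion curve sits 5° above the mean over the
diastolic half-cycle has 1.59× the odds of death — with a wide CI, as
expected from 5 events in 70 patients. A single cohort of this size often
cannot resolve the functional terms (here global p for torsion is 0.89);
the replicated recovery experiments below show the estimator is unbiased.

The same pipeline from the shell:

```bash
lvfda simulate --seed 7 --out run/data
lvfda fit-sbp --data run/data --out run/fit_sbp.json
lvfda fit-mortality --data run/data --out run/fit_mort.json
lvfda effects --fit run/fit_mort.json --term gls --delta -5 --from 0.5
lvfda report --fit run/fit_sbp.json --fit run/fit_mort.json --out run/report
lvfda run --synthetic --seed 7 --out run/all     # everything + manifest
```

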
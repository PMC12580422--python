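# Methods

## The problem

During a hemodialysis session fluid is removed faster than the vasculature
refills, and systolic blood pressure (SBP) tends to fall. Whether a patient
tolerates this hypovolemia depends on left-ventricular diastolic mechanics:
the *untwisting* of the LV (the decay of torsion after its systolic peak)
generates the suction that keeps the ventricle filling when preload drops.
This package analyzes speckle-tracking strain data — global longitudinal
strain (GLS), LV torsion (apical minus basal rotation) and RV free-wall
strain — as *functions of the cardiac cycle*, and relates the whole curves
to repeated intradialytic SBP and to mortality.

## Curve preparation

Exported traces have an arbitrary number of frames per cycle. Every trace is
resampled by piecewise-linear interpolation onto the fixed 33-point grid
t_l = (l−1)/32, l = 1…33, with time expressed as cycle proportion t ∈ [0, 1]
(endpoints included, input endpoints preserved exactly). Linear interpolation
is shape-preserving: the resampled curve never overshoots the input range.
Torsion is the pointwise difference apical − basal rotation. A curve's peak
is the maximum (torsion, rotations) or the most negative value (GLS, RV
free-wall strain); ties are broken by the earliest time. Traces are assumed
to cover exactly one cardiac cycle starting at t = 0; no cardiac-phase
detection is attempted.

## The scalar-on-function models

**SBP model (Gaussian, multilevel).** For patient i, session k, occasion j
(7 SBP measurements × 3 sessions):

    SBP_ikj = α + occ_j + z_i'γ + Σ_m ∫ β_m(t) X_im(t) dt + b_i + ε_ikj,

with b_i ~ N(0, σ_b²) a patient random intercept and ε ~ N(0, σ_ε²). The
scalar covariates z are age, sex, hypertension, diabetes, dialysis vintage,
ultrafiltrate volume, IVC diameter and indexed LV mass; the functional
covariates X_m are the torsion, GLS and RV free-wall curves, centered at the
sample mean curve (the centering curve is stored and re-applied at
prediction). The 7 occasions enter as fixed indicators (toggleable) to absorb
the within-session SBP decline. Missing SBP entries are dropped row-wise;
curves and scalar covariates must be complete.

**Mortality model (binomial, patient level).** logit P(death_i) =
α + Σ_m ∫ β_m(t) X_im(t) dt with GLS and torsion as the only predictors (the
primary analysis is unadjusted to limit overfitting with few events); an
age-adjusted sensitivity variant is provided. β(t) is on the log-odds scale.

**Functional coefficients.** Each β(t) is expanded in K = 9 cubic B-splines
on an equally spaced clamped knot vector over [0, 1] with a second-order
difference penalty on the basis coefficients (the standard P-spline default;
configurable via `BasisSpec`). The integral ∫ β(t) X(t) dt is approximated by
trapezoid quadrature on the 33-point grid, which is exact for the
piecewise-linear curves that time normalization produces.

## Estimation

The penalties are handled in their mixed-model representation: each
difference penalty is eigen-decomposed into an unpenalized null space
(constant + linear coefficient trends, treated as fixed effects) and a
penalized range space whose scaled coefficients act as i.i.d. Gaussian
random effects. The patient random intercept is one more such block. All
variance ratios (smoothing parameters λ_m = σ_ε²/σ_m² and the intercept
ratio σ_ε²/σ_b²) are selected jointly:

* **Gaussian:** profiled REML in the Bates et al. form — one blocked
  Cholesky of the penalized normal equations per evaluation gives the
  penalized RSS and both log-determinants; Nelder–Mead over the log
  variance ratios. With the cross-products precomputed a 70-patient,
  1470-observation fit takes ~0.15 s.
* **Binomial:** penalized IRLS with step-halving on the penalized deviance
  inside; outside, a Laplace-approximate restricted marginal likelihood
  (deviance + u'u + log|penalized information|, which in the scaled
  coordinates needs no separate prior-normalization term) minimized over the
  log smoothing parameters. This matches mgcv's REML selection for binomial
  models (verified against `mgcv::gam` in the test suite). Complete
  separation is reported as an error only when the penalized deviance
  collapses to zero with diverging log-odds.

Fixed smoothing can be requested per term: `fixed_lambda[term] = 0` gives an
unpenalized fit (equal to the ML solution when it exists), a finite value
gives the generalized-ridge solution in closed form, and `inf` removes the
term (β ≡ 0 exactly).

Reported quantities: scalar coefficients with large-sample Wald 95% CIs,
σ_b, σ_ε, variance explained 1 − RSS/TSS using fixed + random fitted values
(defined as 1 for a constant response), a conditional AIC (−2·conditional
log-likelihood + 2·effective dof), and per-term effective degrees of freedom
from the trace of the influence decomposition.

## Inference on β(t)

* **Pointwise bands:** β̂(t) ± z·SE(t), SE propagated from the Bayesian
  covariance of the penalized coefficients (C'C + S)⁻¹σ̂² (φ = 1 for the
  binomial model). Under a true null these bands cover 0 at ~95% of
  replicates per grid point (measured 92–98% over 500 null cohorts).
* **Global test:** Wald-type statistic on the grid evaluation of β with a
  rank-truncated pseudo-inverse of its covariance, rank = round(effective
  dof of the term), referred to χ² at that rank. Measured type-I error at
  nominal 0.05: 0.065 over 500 null replicates (within [0.02, 0.09]).
* **Cluster bootstrap:** patients are resampled with replacement with all
  their sessions/curves, the model is refitted per replicate, and a
  pointwise percentile band is formed (deterministic given a seed;
  replicates that fail to converge are counted, >20% failures is an error).
  By default the smoothing parameters are pinned at the full-data estimates
  during replicate refits; re-selecting them per replicate
  (`refit_smoothing=True`) is substantially noisier because smoothing
  selection itself is highly variable in small cohorts, but gives better
  null coverage and is used where coverage matters.

## Effect measures

A fitted β is summarized by the consequence of adding a constant δ (curve
units: % strain or degrees) over a window of the cycle, default the
diastolic half (0.5, 1]: η = δ·∫_window β(t) dt by trapezoid quadrature with
the window endpoints snapped to grid points (keeping the integral exact and
the window decomposition additive). Binomial fits report OR = exp(η) with a
delta-method Wald CI; Gaussian fits report η in mmHg. Log-odds are exactly
linear in δ and sign-symmetric.

## The synthetic cohort generator

The generator emulates the statistical structure the models assume, with
defaults calibrated to the published cohort characteristics:

* **Curves:** amplitude_i · pulse(t; τ_i) + smooth noise, where the pulse is
  a beta-density bump renormalized to unit peak (zero at cycle start,
  skew-capable, concentration 6), amplitude ~ N(peak mean, peak SD) (torsion
  25.5/8.4°, GLS −20.0/3.83%, RV free wall −24/4% — the last is an
  implementer default, the source cohort reports no RV values), and peak
  time τ ~ N(0.453/0.463, 0.05) truncated to (0.1, 0.9). The noise is a
  low-rank squared-exponential Gaussian process (length-scale 0.2 cycles,
  SD 0.5 curve units) tapered by sin(πt) so curves stay anchored at 0.
* **Covariates:** normal (age 50.4/14.9 y, ultrafiltrate 2350/663 mL, IVC
  16.3/3.15 mm, LVMI 111/39 g/m², truncated to physiologic ranges),
  Bernoulli (female 0.414, hypertension 0.657, diabetes 0.10), and gamma
  dialysis vintage with mean 7.84 / SD 5.90 y (non-negative support).
* **SBP:** from the Gaussian model above with true scalar effects set to the
  published point estimates, a torsion effect concentrated in diastole
  (0.4·half-sine over t > 0.5 — illustrative of the qualitative finding,
  not an estimate of the real coefficient), a linear occasion decline of
  −1.5 mmHg per step, intercept 115 mmHg (putting typical first-occasion
  SBP near 135), σ_b = 8 and σ_ε = 10 mmHg. The source reports no
  within-patient correlation structure, so the two SDs are implementer
  choices exposed in the config.
* **Mortality:** Bernoulli with logit = α_m + Σ ∫β_m(t)X(t)dt, diastolic
  half-sine effects sized so that constant ±5-unit shifts after t = 0.5
  give odds ratios near the published 1.57 (GLS) and 0.85 (torsion); α_m is
  calibrated by bisection so the cohort-average event probability equals
  the target rate (default 0.08).

Everything is a pure function of (config, seed). What the generator does
*not* emulate: measurement drift within traces, curve-covariate correlation
(covariates are independent of the curves), informative missingness (none
by default), session-level random effects, and intradialytic hypotension
events. Passing tests therefore demonstrate correctness of the machinery
under the assumed model, not robustness to real-data violations of it.

With ~6 events per 70 patients and two smooth terms the mortality response
is quasi-separable in a nontrivial fraction of generated cohorts (~10%);
the fitters report this honestly (separation error) and the bootstrap
counts such replicates as failures. The reference implementation in mgcv
behaves identically on the same data.

## Numerical choices

* Log variance ratios are box-constrained to ±30; a Nelder–Mead run that
  ends with a flat simplex (spread < 1e−2 deviance units) is accepted.
* Scalar covariates are standardized internally (centered/scaled) and the
  response is centered; coefficients and covariances are transformed back,
  so reported estimates are in raw units and the closed-form ridge
  equivalence holds exactly.
* Constant covariates raise a rank-deficiency error naming the column; a
  constant response yields intercept = that constant and variance explained
  1 by convention.
* Peak ties in curve summaries break to the earliest time; perturbation
  windows snap to the nearest grid points.

## Problem sizes used in the test suite

Replicated simulations run at sizes chosen to keep the default suite deep
but quick: the null calibration of the global test and bands uses 500
cohorts of 30 patients with a single functional term; power and
band/test-agreement checks use 25 and 12 cohorts of 40 patients with a
strong injected effect; bootstrap checks use B = 60–400 on 24–40-patient
cohorts; parameter recovery runs 20 replicates at the full study size
(70 patients × 21 SBP values). The acceptance harness
(`scripts/acceptance.py`) regenerates everything from scratch in a few
seconds.

## Known limitations

* The binomial smoothing criterion is a Laplace approximation; with very
  few events its curvature is flat and selected smoothing can sit at the
  box bound (the fit is then effectively unpenalized or linear).
* The global test is a Wald-type approximation with estimated smoothing
  treated as fixed; its measured null behavior is slightly liberal (0.065
  at nominal 0.05) at n = 30.
* Percentile bootstrap bands at B = 200 carry quantile Monte-Carlo noise of
  a few tenths of a model SE; B ≥ 400 is advisable for publication-grade
  bands.
* The variance-explained statistic conditions on the predicted random
  intercepts and is not comparable across random-effects structures.
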
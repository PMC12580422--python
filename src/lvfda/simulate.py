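"""Synthetic dialysis cohorts with the statistical structure of the study.

The generator produces, per patient: smooth strain/rotation-style curves on
the 33-point cycle grid (a skewed beta-density pulse with random peak
amplitude and timing plus smooth Gaussian-process noise), scalar covariates
drawn from the published cohort moments, repeated SBP measurements from the
multilevel scalar-on-function model (3 sessions x 7 occasions, patient
random intercept, linearly declining occasion trend), and a binary death
indicator from a logistic scalar-on-function model whose intercept is
calibrated by bisection to a target marginal event rate.

Every draw is a pure function of (config, seed): same inputs, same cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .basis import quadrature_weights
from .curves import GRID_LENGTH, cycle_grid
from .data import N_OCCASIONS, N_SESSIONS, SCALAR_COVARIATES, CohortDataset
from .sofr import BasisSpec, FitOptions, fit_sofr_gaussian

__all__ = [
    "CurveShape",
    "SyntheticConfig",
    "generate_curves",
    "generate_cohort",
    "recovery_experiment",
    "default_torsion_effect",
    "default_mortality_effects",
]


class CalibrationError(RuntimeError):
    """The target marginal event rate cannot be reached."""


@dataclass(frozen=True)
class CurveShape:
    """Shape parameters of one curve family.

    ``peak_mean``/``peak_sd`` set the distribution of the signed peak value
    (negative for strain modalities), ``time_mean``/``time_sd`` the peak
    timing as cycle proportion (truncated to (0.1, 0.9)), ``concentration``
    the width of the beta-density pulse, and ``noise_sd`` the magnitude of
    the smooth residual curve noise.
    """

    peak_mean: float
    peak_sd: float
    time_mean: float
    time_sd: float
    concentration: float = 6.0
    noise_sd: float = 0.5
    noise_length_scale: float = 0.2


def default_torsion_effect() -> np.ndarray:
    """True SBP effect of torsion: a diastolic bump over t in (0.5, 1]."""
    t = cycle_grid(GRID_LENGTH)
    out = np.zeros(GRID_LENGTH)
    late = t > 0.5
    out[late] = 0.4 * np.sin(np.pi * (t[late] - 0.5) / 0.5)
    return out


def default_mortality_effects() -> dict[str, np.ndarray]:
    """True log-odds effects: diastolic bumps sized so that constant +-5
    curve shifts after t = 0.5 give odds ratios near the published ones."""
    t = cycle_grid(GRID_LENGTH)
    late = t > 0.5
    bump = np.zeros(GRID_LENGTH)
    bump[late] = np.sin(np.pi * (t[late] - 0.5) / 0.5)
    return {"gls": -0.283 * bump, "torsion": -0.102 * bump}


def _default_curve_shapes() -> dict[str, CurveShape]:
    return {
        "torsion": CurveShape(25.5, 8.4, 0.453, 0.05),
        "gls": CurveShape(-20.0, 3.83, 0.463, 0.05),
        "rv_free_wall": CurveShape(-24.0, 4.0, 0.46, 0.05),
    }


def _default_scalar_effects() -> dict[str, float]:
    # true SBP effects used for parameter-recovery experiments
    return {
        "ultrafiltrate": -0.001,
        "sex": 1.4,
        "age": -0.30,
        "hypertension": 5.85,
        "diabetes": 0.97,
        "ivc_diameter": 1.33,
        "dialysis_vintage": -0.45,
        "lv_mass_indexed": 0.12,
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Every distributional parameter of the cohort generator.

    Covariate moments reproduce the published cohort: age 50.4 (14.9) y,
    41.4% female, 65.7% hypertensive, 10% diabetic, ultrafiltrate 2350
    (663) mL, IVC diameter 16.3 (3.15) mm, indexed LV mass 111 (39) g/m2,
    dialysis vintage mean 7.84 SD 5.90 y (gamma, non-negative support).
    """

    n_patients: int = 70
    curve_shapes: dict[str, CurveShape] = field(default_factory=_default_curve_shapes)
    # covariate moments
    age_mean: float = 50.4
    age_sd: float = 14.9
    p_female: float = 0.414
    p_hypertension: float = 0.657
    p_diabetes: float = 0.10
    ultrafiltrate_mean: float = 2350.0
    ultrafiltrate_sd: float = 663.0
    ivc_mean: float = 16.3
    ivc_sd: float = 3.15
    lvmi_mean: float = 111.0
    lvmi_sd: float = 39.0
    vintage_mean: float = 7.84
    vintage_sd: float = 5.90
    # SBP model truths
    sbp_intercept: float = 115.0
    occasion_slope: float = -1.5          # mmHg per occasion step (declining)
    scalar_effects: dict[str, float] = field(default_factory=_default_scalar_effects)
    functional_effects: dict[str, np.ndarray] | None = None   # None -> defaults
    sigma_b: float = 8.0
    sigma_eps: float = 10.0
    # mortality model truths
    mortality_effects: dict[str, np.ndarray] | None = None    # None -> defaults
    death_rate: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        errors = []
        if self.n_patients < 2:
            errors.append(f"n_patients must be >= 2 (got {self.n_patients})")
        for name in ("age_sd", "ultrafiltrate_sd", "ivc_sd", "lvmi_sd",
                     "vintage_sd", "sigma_eps"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be > 0 (got {getattr(self, name)})")
        if self.sigma_b < 0:
            errors.append("sigma_b must be >= 0")
        for name in ("p_female", "p_hypertension", "p_diabetes", "death_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"{name} must lie in [0, 1] (got {v})")
        for mod, shape in self.curve_shapes.items():
            if shape.peak_sd < 0 or shape.time_sd < 0:
                errors.append(f"curve_shapes[{mod!r}]: SDs must be >= 0")
            if not 0.1 < shape.time_mean < 0.9:
                errors.append(f"curve_shapes[{mod!r}]: time_mean must be in (0.1, 0.9)")
        if errors:
            raise ValueError("invalid SyntheticConfig: " + "; ".join(errors))

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("functional_effects", "mortality_effects"):
            if d[key] is not None:
                d[key] = {k: np.asarray(v).tolist() for k, v in d[key].items()}
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "curve_shapes" in d:
            d["curve_shapes"] = {
                k: (v if isinstance(v, CurveShape) else CurveShape(**v))
                for k, v in d["curve_shapes"].items()
            }
        for key in ("functional_effects", "mortality_effects"):
            if d.get(key) is not None:
                d[key] = {k: np.asarray(v, float) for k, v in d[key].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# curves
# ---------------------------------------------------------------------------

def _pulse_template(tau: float, concentration: float) -> np.ndarray:
    """Skewed unimodal pulse on the grid: 0 at t=0, unit peak at t=tau."""
    t = cycle_grid(GRID_LENGTH)
    a = tau * concentration
    b = (1.0 - tau) * concentration
    with np.errstate(divide="ignore", invalid="ignore"):
        log_g = a * np.log(t) + b * np.log(1.0 - t)
    log_peak = a * np.log(tau) + b * np.log(1.0 - tau)
    g = np.exp(log_g - log_peak)
    g[~np.isfinite(g)] = 0.0
    return g


def _smooth_noise(rng: np.random.Generator, n: int, sd: float, length_scale: float
                  ) -> np.ndarray:
    """Low-rank squared-exponential GP noise, tapered to vanish at t=0, 1."""
    if sd <= 0:
        return np.zeros((n, GRID_LENGTH))
    t = cycle_grid(GRID_LENGTH)
    K = np.exp(-0.5 * ((t[:, None] - t[None, :]) / length_scale) ** 2)
    vals, vecs = np.linalg.eigh(K)
    keep = vals > vals.max() * 1e-8
    root = vecs[:, keep] * np.sqrt(vals[keep])
    z = rng.standard_normal((n, int(keep.sum())))
    return sd * (z @ root.T) * np.sin(np.pi * t)


def _truncated_normal(rng, mean, sd, lo, hi, size) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    bad = (out <= lo) | (out >= hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out <= lo) | (out >= hi)
    return out


def generate_curves(
    config: SyntheticConfig, n: int, seed: int | None = None
) -> dict[str, np.ndarray]:
    """Draw n curve triplets; returns modality -> (n, 33) array.

    Each curve is amplitude * pulse(t; tau) + smooth noise with
    amplitude ~ N(peak_mean, peak_sd) (sign preserved) and
    tau ~ N(time_mean, time_sd) truncated to (0.1, 0.9).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out: dict[str, np.ndarray] = {}
    for modality in ("torsion", "gls", "rv_free_wall"):
        shape = config.curve_shapes[modality]
        sign = -1.0 if shape.peak_mean < 0 else 1.0
        if shape.peak_sd > 0:
            amp = sign * _truncated_normal(
                rng, abs(shape.peak_mean), shape.peak_sd, 0.5, np.inf, n
            )
        else:
            amp = np.full(n, shape.peak_mean)
        if shape.time_sd > 0:
            tau = _truncated_normal(rng, shape.time_mean, shape.time_sd, 0.1, 0.9, n)
        else:
            tau = np.full(n, shape.time_mean)
        curves = np.empty((n, GRID_LENGTH))
        for i in range(n):
            curves[i] = amp[i] * _pulse_template(tau[i], shape.concentration)
        curves += _smooth_noise(rng, n, shape.noise_sd, shape.noise_length_scale)
        out[modality] = curves
    return out


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _functional_part(curves: dict[str, np.ndarray],
                     effects: dict[str, np.ndarray]) -> np.ndarray:
    """Per-patient contribution sum_terms int beta(t) X_i(t) dt (trapezoid)."""
    w = quadrature_weights()
    n = next(iter(curves.values())).shape[0]
    eta = np.zeros(n)
    for term, beta in effects.items():
        eta += curves[term] @ (w * np.asarray(beta, float))
    return eta


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Bisection on alpha so that mean(expit(alpha + eta)) == target."""
    from scipy.special import expit

    def rate(alpha: float) -> float:
        return float(np.mean(expit(alpha + eta)))

    lo, hi = -40.0, 40.0
    if not (rate(lo) <= target <= rate(hi)):
        raise CalibrationError(
            f"target event rate {target} unreachable for the given effects"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if rate(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(config: SyntheticConfig, seed: int | None = None) -> CohortDataset:
    """Draw a full cohort: covariates, curves, SBP series, death indicator."""
    base = np.random.default_rng(config.seed if seed is None else seed)
    curve_seed, cov_seed, sbp_seed, death_seed = base.integers(0, 2**31 - 1, 4)
    n = config.n_patients
    curves = generate_curves(config, n, int(curve_seed))

    rng = np.random.default_rng(int(cov_seed))
    shape_k = (config.vintage_mean / config.vintage_sd) ** 2
    scale_k = config.vintage_sd**2 / config.vintage_mean
    cov = pd.DataFrame(
        {
            "ultrafiltrate": _truncated_normal(
                rng, config.ultrafiltrate_mean, config.ultrafiltrate_sd, 0.0, np.inf, n
            ),
            "sex": rng.binomial(1, config.p_female, n).astype(float),
            "age": _truncated_normal(rng, config.age_mean, config.age_sd, 18.0, 95.0, n),
            "hypertension": rng.binomial(1, config.p_hypertension, n).astype(float),
            "diabetes": rng.binomial(1, config.p_diabetes, n).astype(float),
            "ivc_diameter": _truncated_normal(rng, config.ivc_mean, config.ivc_sd, 4.0, 40.0, n),
            "dialysis_vintage": rng.gamma(shape_k, scale_k, n),
            "lv_mass_indexed": _truncated_normal(rng, config.lvmi_mean, config.lvmi_sd, 30.0, 300.0, n),
        },
        index=[f"P{i:04d}" for i in range(n)],
    )

    # linear predictor of the SBP model
    gamma = config.scalar_effects
    eta_scalar = sum(
        gamma.get(name, 0.0) * cov[name].to_numpy() for name in SCALAR_COVARIATES
    )
    f_effects = config.functional_effects
    if f_effects is None:
        f_effects = {"torsion": default_torsion_effect()}
    eta_func = _functional_part(curves, f_effects)

    rng_sbp = np.random.default_rng(int(sbp_seed))
    b = rng_sbp.normal(0.0, config.sigma_b, n) if config.sigma_b > 0 else np.zeros(n)
    occ = config.occasion_slope * np.arange(N_OCCASIONS)
    mean_ij = (
        config.sbp_intercept
        + eta_scalar[:, None, None]
        + eta_func[:, None, None]
        + b[:, None, None]
        + occ[None, None, :]
    )
    eps = (
        rng_sbp.normal(0.0, config.sigma_eps, (n, N_SESSIONS, N_OCCASIONS))
        if config.sigma_eps > 0
        else np.zeros((n, N_SESSIONS, N_OCCASIONS))
    )
    sbp = np.clip(mean_ij + eps, 30.5, 299.5)

    m_effects = config.mortality_effects
    if m_effects is None:
        m_effects = default_mortality_effects()
    eta_m = _functional_part(curves, m_effects)
    alpha_m = _calibrate_intercept(eta_m, config.death_rate)
    rng_death = np.random.default_rng(int(death_seed))
    from scipy.special import expit

    death = rng_death.binomial(1, expit(alpha_m + eta_m))

    return CohortDataset(covariates=cov, curves=curves, sbp=sbp, death=death)


# ---------------------------------------------------------------------------
# parameter-recovery harness
# ---------------------------------------------------------------------------

def recovery_experiment(
    config: SyntheticConfig,
    n_replicates: int,
    seed: int | None = None,
    spec: BasisSpec | None = None,
    options: FitOptions | None = None,
) -> pd.DataFrame:
    """Repeatedly generate a cohort, fit the SBP model, record recovery.

    Returns one row per (replicate, scalar coefficient) with the estimate,
    its SE, whether the 95% CI covered the generating truth, and per
    replicate the integrated squared error of each functional estimate.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    base = np.random.default_rng(config.seed if seed is None else seed)
    rep_seeds = base.integers(0, 2**31 - 1, n_replicates)
    truths = dict(config.scalar_effects)
    f_true = config.functional_effects
    if f_true is None:
        f_true = {"torsion": default_torsion_effect()}
    w = quadrature_weights()
    scalar_names = options.scalar_terms if options is not None else SCALAR_COVARIATES
    rows = []
    for r, s in enumerate(rep_seeds):
        cohort = generate_cohort(config, int(s))
        try:
            fit = fit_sofr_gaussian(cohort, spec, options)
        except Exception as err:
            raise RuntimeError(f"replicate {r} failed to fit: {err}") from err
        for name in scalar_names:
            term = fit.scalar(name)
            truth = truths.get(name, 0.0)
            rows.append(
                {
                    "replicate": r,
                    "parameter": name,
                    "truth": truth,
                    "estimate": term.estimate,
                    "se": term.se,
                    "covered": int(term.ci_low <= truth <= term.ci_high),
                }
            )
        for term_name, fc in fit.functional_terms.items():
            bt = np.asarray(f_true.get(term_name, np.zeros(GRID_LENGTH)), float)
            ise = float(np.sum(w * (fc.beta - bt) ** 2))
            rows.append(
                {
                    "replicate": r,
                    "parameter": f"beta[{term_name}]_ise",
                    "truth": 0.0,
                    "estimate": ise,
                    "se": np.nan,
                    "covered": np.nan,
                }
            )
    return pd.DataFrame(rows)


def summarize_recovery(table: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter mean estimate, empirical bias, mean SE and coverage."""
    g = table.groupby("parameter", sort=False)
    out = pd.DataFrame(
        {
            "truth": g["truth"].first(),
            "mean_estimate": g["estimate"].mean(),
            "bias": g["estimate"].mean() - g["truth"].first(),
            "mean_se": g["se"].mean(),
            "coverage": g["covered"].mean(),
        }
    )
    return out
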
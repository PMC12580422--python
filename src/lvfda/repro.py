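"""Reproduction harness: recompute the package's headline quantities.

Every quantity is computed from scratch by running the generator and the
fitters at the study's design sizes: curve-shape calibration on 2000
synthetic curves, covariate calibration and mortality calibration on a
5000-patient cohort, and scalar-coefficient recovery over 20 replicate
cohorts of 70 patients whose generating effects are the published point
estimates.
"""

from __future__ import annotations

import numpy as np

from .curves import NormalizedCurve, summarize_curve
from .simulate import SyntheticConfig, generate_cohort, generate_curves, recovery_experiment, summarize_recovery

__all__ = ["compute_targets", "TARGET_DESCRIPTIONS"]

TARGET_DESCRIPTIONS = {
    "t3": "mean peak LV torsion (degrees), n = 2000 synthetic curves",
    "t4": "mean peak (most negative) GLS (%), n = 2000 synthetic curves",
    "t5": "median time-to-peak torsion (cycle proportion), n = 2000",
    "t6": "mean recovered ultrafiltrate coefficient (mmHg/mL), 20 x 70-patient cohorts",
    "t7": "mean recovered age coefficient (mmHg/year), 20 x 70-patient cohorts",
    "t8": "mean recovered IVC-diameter coefficient (mmHg/mm), 20 x 70-patient cohorts",
    "t9": "mean ultrafiltrate volume (mL), n = 5000 synthetic patients",
}


def compute_targets(seed: int = 1, n_curves: int = 2000, n_recovery: int = 20,
                    n_large: int = 5000) -> dict[str, dict]:
    """Recompute all headline quantities; returns {id: {value, n}}."""
    root = np.random.default_rng(seed)
    s_curves, s_recovery, s_large = (int(v) for v in root.integers(0, 2**31 - 1, 3))
    out: dict[str, dict] = {}

    # curve-shape calibration
    config = SyntheticConfig()
    curves = generate_curves(config, n_curves, seed=s_curves)
    tor_summ = [
        summarize_curve(NormalizedCurve(values=row, modality="torsion"))
        for row in curves["torsion"]
    ]
    gls_summ = [
        summarize_curve(NormalizedCurve(values=row, modality="gls"))
        for row in curves["gls"]
    ]
    out["t3"] = {"value": float(np.mean([s.peak_value for s in tor_summ])),
                 "n": n_curves}
    out["t4"] = {"value": float(np.mean([s.peak_value for s in gls_summ])),
                 "n": n_curves}
    out["t5"] = {"value": float(np.median([s.time_to_peak for s in tor_summ])),
                 "n": n_curves}

    # scalar-coefficient recovery at the study size (70 patients, 3 x 7 SBP)
    table = recovery_experiment(config, n_replicates=n_recovery, seed=s_recovery)
    summary = summarize_recovery(table)
    for tid, name in (("t6", "ultrafiltrate"), ("t7", "age"), ("t8", "ivc_diameter")):
        out[tid] = {"value": float(summary.loc[name, "mean_estimate"]),
                    "n": n_recovery * config.n_patients}

    # covariate calibration on a large cohort
    big = generate_cohort(SyntheticConfig(n_patients=n_large), seed=s_large)
    out["t9"] = {"value": float(big.covariates["ultrafiltrate"].mean()),
                 "n": n_large}
    return out
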
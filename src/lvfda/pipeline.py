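"""End-to-end pipeline: simulate/ingest -> fit -> effects -> report.

The pipeline either generates a synthetic cohort or reads the three cohort
CSVs, fits the SBP and mortality models, computes the standard diastolic
curve-perturbation effects, renders the report, and writes a manifest that
lists every artifact with its SHA-256 checksum (equal config + seed gives
a checksum-identical manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GRID_LENGTH, SCALAR_COVARIATES, SBP_RANGE
from .effects import Perturbation, perturbation_effect, render_report
from .io import fit_to_json, read_cohort, write_cohort
from .simulate import SyntheticConfig, generate_cohort
from .sofr import (
    BasisSpec,
    SeparationError,
    binomial_options,
    bootstrap_band,
    fit_sofr_binomial,
    fit_sofr_gaussian,
)

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]

log = logging.getLogger("lvfda")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``synthetic`` or the three real-input paths
    (``cohort_path``, ``sbp_path``, ``curves_path``) must be provided.
    """

    out_dir: Path
    synthetic: SyntheticConfig | None = None
    cohort_path: Path | None = None
    sbp_path: Path | None = None
    curves_path: Path | None = None
    spec: BasisSpec = field(default_factory=BasisSpec)
    bootstrap_B: int = 0          # 0 disables the bootstrap stage
    seed: int = 0
    age_adjusted_mortality: bool = False
    verbose: bool = False

    def __post_init__(self) -> None:
        real = [self.cohort_path, self.sbp_path, self.curves_path]
        has_real = any(p is not None for p in real)
        if has_real and any(p is None for p in real):
            raise ValueError(
                "real-input mode needs all of cohort_path, sbp_path, curves_path"
            )
        if (self.synthetic is None) == (not has_real):
            raise ValueError(
                "provide exactly one of: a synthetic config, or the three input paths"
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_inputs(cohort_path, sbp_path, curves_path) -> list[dict]:
    """Schema / range / referential-integrity checks on the input CSVs.

    Returns a machine-readable list of violations (empty when clean).
    """
    violations: list[dict] = []
    for p in (cohort_path, sbp_path, curves_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")

    cov = pd.read_csv(cohort_path)
    if "subject_id" not in cov.columns:
        violations.append({"file": str(cohort_path), "kind": "schema",
                           "detail": "missing column subject_id"})
        return violations
    missing_cols = [c for c in SCALAR_COVARIATES if c not in cov.columns]
    for c in missing_cols:
        violations.append({"file": str(cohort_path), "kind": "schema",
                           "detail": f"missing covariate column {c}"})
    subjects = set(cov["subject_id"].astype(str))

    sdf = pd.read_csv(sbp_path)
    need = {"subject_id", "session", "occasion", "sbp"}
    if not need <= set(sdf.columns):
        violations.append({"file": str(sbp_path), "kind": "schema",
                           "detail": f"missing columns {sorted(need - set(sdf.columns))}"})
    else:
        lo, hi = SBP_RANGE
        for _, row in sdf.iterrows():
            if not (lo < row["sbp"] < hi):
                violations.append({
                    "file": str(sbp_path), "kind": "range",
                    "detail": f"SBP {row['sbp']} outside ({lo}, {hi})",
                    "subject_id": str(row["subject_id"]),
                    "session": int(row["session"]),
                    "occasion": int(row["occasion"]),
                })
        sbp_subjects = set(sdf["subject_id"].astype(str))
        for sid in sorted(sbp_subjects - subjects):
            violations.append({"file": str(sbp_path), "kind": "integrity",
                               "detail": f"SBP rows for unknown subject {sid}",
                               "subject_id": sid})

    cdf = pd.read_csv(curves_path)
    need = {"subject_id", "modality", "t", "value"}
    if not need <= set(cdf.columns):
        violations.append({"file": str(curves_path), "kind": "schema",
                           "detail": f"missing columns {sorted(need - set(cdf.columns))}"})
        return violations
    counts = cdf.groupby(["subject_id", "modality"]).size()
    for (sid, mod), nsamp in counts.items():
        if nsamp != GRID_LENGTH:
            violations.append({"file": str(curves_path), "kind": "range",
                               "detail": f"curve {mod} for {sid} has {nsamp} samples, "
                                         f"expected {GRID_LENGTH}",
                               "subject_id": str(sid)})
    curve_subjects = set(cdf["subject_id"].astype(str))
    if "subject_id" in sdf.columns:
        for sid in sorted(set(sdf["subject_id"].astype(str)) - curve_subjects):
            violations.append({"file": str(curves_path), "kind": "integrity",
                               "detail": f"subject {sid} has SBP but no curves",
                               "subject_id": sid})
    return violations


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest dict (also written to disk).

    Stage order: simulate/ingest -> fit-sbp -> fit-mortality -> effects ->
    report [-> bootstrap].  On stage failure the manifest of completed
    stages is written before the exception propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.DEBUG if config.verbose else logging.INFO)

    manifest: dict = {"seed": config.seed, "stages": [], "files": {}}

    def record(stage: str, paths, t0: float) -> None:
        manifest["stages"].append({"stage": stage, "wall_s": round(time.time() - t0, 3)})
        for p in paths:
            p = Path(p)
            manifest["files"][str(p.relative_to(out))] = _sha256(p)
        log.info("stage %s done (%.2fs)", stage, time.time() - t0)

    def flush() -> None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    try:
        t0 = time.time()
        if config.synthetic is not None:
            log.info("stage simulate: n=%d seed=%d",
                     config.synthetic.n_patients, config.seed)
            cohort = generate_cohort(config.synthetic, seed=config.seed)
            paths = write_cohort(cohort, out / "data")
            config.synthetic.to_yaml(out / "data" / "config.yaml")
            record("simulate", list(paths.values()) + [out / "data" / "config.yaml"], t0)
        else:
            log.info("stage ingest: %s", config.cohort_path)
            issues = validate_inputs(config.cohort_path, config.sbp_path,
                                     config.curves_path)
            if issues:
                raise ValueError(f"input validation failed: {issues[:5]}")
            cohort = read_cohort(config.cohort_path, config.sbp_path,
                                 config.curves_path)
            record("ingest", [], t0)

        t0 = time.time()
        sbp_fit = fit_sofr_gaussian(cohort, config.spec)
        fit_to_json(sbp_fit, out / "fit_sbp.json")
        record("fit-sbp", [out / "fit_sbp.json"], t0)

        t0 = time.time()
        mort_fit = None
        try:
            mort_fit = fit_sofr_binomial(
                cohort, config.spec,
                binomial_options(age_adjusted=config.age_adjusted_mortality),
            )
            fit_to_json(mort_fit, out / "fit_mortality.json")
            record("fit-mortality", [out / "fit_mortality.json"], t0)
        except (SeparationError, ValueError) as err:
            log.warning("mortality model not fitted: %s", err)
            manifest["stages"].append({"stage": "fit-mortality",
                                       "skipped": str(err)})

        t0 = time.time()
        effects = {}
        for term, delta in (("gls", -5.0), ("torsion", 5.0)):
            effects[f"sbp:{term}:{delta:+g}"] = perturbation_effect(
                sbp_fit, Perturbation(term, delta)
            )
            if mort_fit is not None:
                effects[f"mortality:{term}:{delta:+g}"] = perturbation_effect(
                    mort_fit, Perturbation(term, delta)
                )
        record("effects", [], t0)

        t0 = time.time()
        fits = [sbp_fit] + ([mort_fit] if mort_fit is not None else [])
        files = render_report(fits, effects, out / "report", curves=cohort.curves)
        record("report", files, t0)

        if config.bootstrap_B >= 50:
            t0 = time.time()
            band = bootstrap_band(
                cohort, config.spec, term="torsion", B=config.bootstrap_B,
                seed=config.seed, family="gaussian",
            )
            bpath = out / "bootstrap_torsion.csv"
            pd.DataFrame({"t": band.grid, "lower": band.lower,
                          "upper": band.upper}).to_csv(
                bpath, index=False, float_format="%.10g")
            record("bootstrap", [bpath], t0)
    finally:
        flush()
        log.removeHandler(handler)
        handler.close()
    return manifest
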
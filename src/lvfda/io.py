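"""Readers and writers for traces, normalized curves, cohort tables and fits.

All formats are plain delimited text (CSV/TSV by extension) or JSON:

* raw traces — long format with columns subject_id, modality, frame_index,
  value; frame_index contiguous from 0 or 1 within each trace;
* normalized curves — long format with columns subject_id, modality, t,
  value (t printed with >= 6 decimals);
* cohort — one row per patient with the scalar covariates and death;
* SBP — long format with columns subject_id, session (1-3), occasion
  (1-7), sbp (mmHg).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import GRID_LENGTH, NormalizedCurve, StrainTrace
from .data import N_OCCASIONS, N_SESSIONS, CohortDataset
from .sofr import BasisSpec, FitResult, FunctionalCoefficient, ScalarTerm

__all__ = [
    "read_traces",
    "write_curves",
    "read_curves",
    "write_cohort",
    "read_cohort",
    "fit_to_json",
    "fit_from_json",
]


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_traces(path) -> list[StrainTrace]:
    """Read raw exported traces from a long-format delimited file."""
    df = pd.read_csv(path, sep=_sep(path))
    required = {"subject_id", "modality", "frame_index", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    traces = []
    for (sid, mod), grp in df.groupby(["subject_id", "modality"], sort=False):
        grp = grp.sort_values("frame_index")
        frames = grp["frame_index"].to_numpy()
        start = frames[0]
        if start not in (0, 1) or not np.array_equal(
            frames, np.arange(start, start + len(frames))
        ):
            raise ValueError(
                f"{path}: frame_index for subject {sid!r} modality {mod!r} "
                "must be contiguous from 0 or 1"
            )
        traces.append(
            StrainTrace(values=grp["value"].to_numpy(float), modality=str(mod),
                        subject_id=str(sid))
        )
    return traces


def write_curves(curves, path) -> None:
    """Write normalized curves as long-format CSV (subject_id, modality, t, value)."""
    rows = []
    for c in curves:
        for t, v in zip(c.grid, c.values):
            rows.append((c.subject_id, c.modality, t, v))
    df = pd.DataFrame(rows, columns=["subject_id", "modality", "t", "value"])
    df.to_csv(path, sep=_sep(path), index=False, float_format="%.10g")


def read_curves(path) -> list[NormalizedCurve]:
    df = pd.read_csv(path, sep=_sep(path))
    required = {"subject_id", "modality", "t", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    curves = []
    for (sid, mod), grp in df.groupby(["subject_id", "modality"], sort=False):
        grp = grp.sort_values("t")
        if len(grp) != GRID_LENGTH:
            raise ValueError(
                f"{path}: subject {sid!r} modality {mod!r} has {len(grp)} samples, "
                f"expected {GRID_LENGTH}"
            )
        curves.append(
            NormalizedCurve(values=grp["value"].to_numpy(float), modality=str(mod),
                            subject_id=str(sid))
        )
    return curves


# ---------------------------------------------------------------------------
# cohort round trip
# ---------------------------------------------------------------------------

def write_cohort(data: CohortDataset, out_dir) -> dict[str, Path]:
    """Write cohort.csv, sbp.csv and curves.csv into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": out / "cohort.csv",
        "sbp": out / "sbp.csv",
        "curves": out / "curves.csv",
    }
    cov = data.covariates.copy()
    cov.insert(0, "subject_id", data.subjects)
    cov["death"] = data.death
    cov.to_csv(paths["cohort"], index=False, float_format="%.10g")

    rows = []
    for i, sid in enumerate(data.subjects):
        for s in range(N_SESSIONS):
            for o in range(N_OCCASIONS):
                v = data.sbp[i, s, o]
                if np.isfinite(v):
                    rows.append((sid, s + 1, o + 1, v))
    pd.DataFrame(rows, columns=["subject_id", "session", "occasion", "sbp"]).to_csv(
        paths["sbp"], index=False, float_format="%.10g"
    )

    curve_objs = [
        NormalizedCurve(values=data.curves[m][i], modality=m, subject_id=str(sid))
        for i, sid in enumerate(data.subjects)
        for m in sorted(data.curves)
    ]
    write_curves(curve_objs, paths["curves"])
    return paths


def read_cohort(cohort_path, sbp_path, curves_path) -> CohortDataset:
    """Assemble a CohortDataset from the three CSVs written by write_cohort."""
    cov = pd.read_csv(cohort_path)
    if "subject_id" not in cov.columns:
        raise ValueError(f"{cohort_path}: missing subject_id column")
    cov = cov.set_index("subject_id")
    cov.index = cov.index.astype(str)
    cov.index.name = None
    death = cov.pop("death").to_numpy(int) if "death" in cov.columns else None
    subjects = list(cov.index)
    pos = {s: i for i, s in enumerate(subjects)}

    sbp = np.full((len(subjects), N_SESSIONS, N_OCCASIONS), np.nan)
    sdf = pd.read_csv(sbp_path)
    for col in ("subject_id", "session", "occasion", "sbp"):
        if col not in sdf.columns:
            raise ValueError(f"{sbp_path}: missing column {col!r}")
    for _, row in sdf.iterrows():
        sid = str(row["subject_id"])
        if sid not in pos:
            raise ValueError(f"{sbp_path}: SBP for unknown subject {sid!r}")
        sbp[pos[sid], int(row["session"]) - 1, int(row["occasion"]) - 1] = row["sbp"]

    curves: dict[str, np.ndarray] = {}
    for c in read_curves(curves_path):
        if c.subject_id not in pos:
            raise ValueError(f"{curves_path}: curve for unknown subject {c.subject_id!r}")
        arr = curves.setdefault(c.modality, np.full((len(subjects), GRID_LENGTH), np.nan))
        arr[pos[c.subject_id]] = c.values
    return CohortDataset(covariates=cov, curves=curves, sbp=sbp, death=death)


# ---------------------------------------------------------------------------
# FitResult JSON round trip
# ---------------------------------------------------------------------------

def fit_to_json(fit: FitResult, path) -> None:
    """Serialize the parts of a fit needed for reporting and effect measures."""
    doc = {
        "family": fit.family,
        "scalar_terms": [dataclasses.asdict(t) for t in fit.scalar_terms],
        "functional_terms": {
            name: {
                "coefs": fc.coefs.tolist(),
                "beta": fc.beta.tolist(),
                "se": fc.se.tolist(),
                "cov_beta": fc.cov_beta.tolist(),
                "edf": fc.edf,
                "units": fc.units,
            }
            for name, fc in fit.functional_terms.items()
        },
        "lambdas": {k: (None if not np.isfinite(v) else v) for k, v in fit.lambdas.items()},
        "global_p": fit.global_p,
        "variance_components": {"sigma_b": fit.sigma_b, "sigma_eps": fit.sigma_eps},
        "fit_stats": {
            "loglik": fit.loglik,
            "aic": fit.aic,
            "edf_total": fit.edf_total,
            "n_obs": fit.n_obs,
            "variance_explained": fit.variance_explained,
        },
        "basis_spec": dataclasses.asdict(fit.spec),
        "centering": {k: v.tolist() for k, v in fit.centering.items()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def fit_from_json(path) -> FitResult:
    """Rebuild a lightweight FitResult (enough for bands, effects, reports)."""
    from .basis import build_basis
    from .sofr import FitOptions

    with open(path) as fh:
        doc = json.load(fh)
    spec = BasisSpec(**doc["basis_spec"])
    B, _ = build_basis(spec)
    func = {}
    for name, d in doc["functional_terms"].items():
        func[name] = FunctionalCoefficient(
            name=name,
            coefs=np.asarray(d["coefs"]),
            basis=B,
            beta=np.asarray(d["beta"]),
            se=np.asarray(d["se"]),
            cov_beta=np.asarray(d["cov_beta"]),
            edf=float(d["edf"]),
            units=d["units"],
        )
    stats = doc["fit_stats"]
    vc = doc["variance_components"]
    return FitResult(
        family=doc["family"],
        scalar_terms=[ScalarTerm(**t) for t in doc["scalar_terms"]],
        functional_terms=func,
        lambdas={k: (np.inf if v is None else v) for k, v in doc["lambdas"].items()},
        global_p=doc["global_p"],
        loglik=stats["loglik"],
        aic=stats["aic"],
        edf_total=stats["edf_total"],
        n_obs=stats["n_obs"],
        spec=spec,
        options=FitOptions(),
        centering={k: np.asarray(v) for k, v in doc["centering"].items()},
        sigma_b=vc["sigma_b"],
        sigma_eps=vc["sigma_eps"],
        variance_explained=stats["variance_explained"],
    )
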
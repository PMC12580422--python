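"""Cohort container: curves, scalar covariates, SBP series, death indicator."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import GRID_LENGTH

__all__ = ["SCALAR_COVARIATES", "FUNCTIONAL_TERMS", "N_SESSIONS", "N_OCCASIONS", "CohortDataset"]

#: Scalar covariates of the blood-pressure model, in reporting order.
SCALAR_COVARIATES = (
    "ultrafiltrate",
    "sex",
    "age",
    "hypertension",
    "diabetes",
    "ivc_diameter",
    "dialysis_vintage",
    "lv_mass_indexed",
)

#: Functional covariates available to the models.
FUNCTIONAL_TERMS = ("torsion", "gls", "rv_free_wall")

N_SESSIONS = 3
N_OCCASIONS = 7

SBP_RANGE = (30.0, 300.0)


@dataclass
class CohortDataset:
    """One dialysis cohort: the regression input.

    Attributes
    ----------
    covariates
        DataFrame indexed by subject_id with the columns in
        :data:`SCALAR_COVARIATES` (age in years, sex/hypertension/diabetes
        as 0/1, dialysis_vintage in years, ultrafiltrate in mL,
        ivc_diameter in mm, lv_mass_indexed in g/m2).
    curves
        Mapping modality -> (n_patients, 33) array, aligned with
        ``covariates.index``; must contain every entry of
        :data:`FUNCTIONAL_TERMS`.
    sbp
        (n_patients, 3 sessions, 7 occasions) systolic blood pressure in
        mmHg; NaN marks a missing measurement.
    death
        (n_patients,) 0/1 all-cause mortality indicator.
    """

    covariates: pd.DataFrame
    curves: dict[str, np.ndarray]
    sbp: np.ndarray
    death: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.covariates)
        self.sbp = np.asarray(self.sbp, dtype=float)
        if self.death is None:
            self.death = np.zeros(n, dtype=int)
        self.death = np.asarray(self.death, dtype=int)
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def subjects(self) -> np.ndarray:
        return np.asarray(self.covariates.index)

    @property
    def n_patients(self) -> int:
        return len(self.covariates)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        n = self.n_patients
        if n < 1:
            raise ValueError("cohort is empty")
        missing = [c for c in SCALAR_COVARIATES if c not in self.covariates.columns]
        if missing:
            raise ValueError(f"missing covariate columns: {missing}")
        vals = self.covariates[list(SCALAR_COVARIATES)].to_numpy(float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("scalar covariates must be complete and finite")
        for term in FUNCTIONAL_TERMS:
            if term not in self.curves:
                raise ValueError(f"missing curves for term {term!r}")
            arr = np.asarray(self.curves[term], dtype=float)
            if arr.shape != (n, GRID_LENGTH):
                raise ValueError(
                    f"curves[{term!r}] must have shape ({n}, {GRID_LENGTH}), got {arr.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"curves[{term!r}] contain non-finite values")
            self.curves[term] = arr
        if self.sbp.shape != (n, N_SESSIONS, N_OCCASIONS):
            raise ValueError(
                f"sbp must have shape ({n}, {N_SESSIONS}, {N_OCCASIONS}), got {self.sbp.shape}"
            )
        present = self.sbp[np.isfinite(self.sbp)]
        lo, hi = SBP_RANGE
        if present.size and (present.min() <= lo or present.max() >= hi):
            raise ValueError(f"SBP values must lie in ({lo}, {hi}) mmHg")
        if self.death.shape != (n,) or not np.isin(self.death, [0, 1]).all():
            raise ValueError("death must be a 0/1 vector, one entry per patient")

    # -- resampling (cluster bootstrap) ---------------------------------
    def take(self, indices: np.ndarray) -> "CohortDataset":
        """Select patients by positional index (repeats allowed).

        Repeated subjects get unique suffixed ids so that each resampled
        patient keeps its own random intercept.
        """
        indices = np.asarray(indices, dtype=int)
        cov = self.covariates.iloc[indices].copy()
        cov.index = [f"{s}#{k}" for k, s in enumerate(cov.index)]
        return CohortDataset(
            covariates=cov,
            curves={m: a[indices] for m, a in self.curves.items()},
            sbp=self.sbp[indices],
            death=self.death[indices],
        )
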
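"""Time-normalization and summary of speckle-tracking strain/rotation traces.

Raw traces exported from echocardiographic strain software have an arbitrary
number of frames per cardiac cycle (it depends on heart rate and acquisition
frame rate).  Before any functional-data modelling every trace is resampled
onto a common 33-point grid covering one cardiac cycle, with time expressed
as cycle proportion t in [0, 1].  LV torsion (twist) is the pointwise
difference between apical and basal rotation over the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GRID_LENGTH",
    "MODALITIES",
    "NEGATIVE_PEAK_MODALITIES",
    "StrainTrace",
    "NormalizedCurve",
    "CurveSummary",
    "cycle_grid",
    "resample_trace",
    "compute_torsion",
    "summarize_curve",
]

#: Number of samples per normalized cardiac cycle.
GRID_LENGTH = 33

#: Recognised curve modalities.  Strain modalities (gls, rv_free_wall) are
#: negative-valued (% shortening); rotations and torsion are in degrees.
MODALITIES = frozenset(
    {"gls", "rotation_apical", "rotation_basal", "rv_free_wall", "torsion"}
)

#: Modalities whose physiological peak is the most negative value.
NEGATIVE_PEAK_MODALITIES = frozenset({"gls", "rv_free_wall"})


class InvalidTraceError(ValueError):
    """Raised for traces that violate the input contract."""


def cycle_grid(length: int = GRID_LENGTH) -> np.ndarray:
    """Uniform cardiac-cycle grid t_l = (l-1)/(L-1), endpoints included."""
    if length < 2:
        raise InvalidTraceError(f"grid length must be >= 2, got {length}")
    return np.linspace(0.0, 1.0, length)


def _check_values(values: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise InvalidTraceError(f"{what} must be one-dimensional")
    if arr.size < 2:
        raise InvalidTraceError(f"{what} must contain at least 2 samples, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise InvalidTraceError(f"{what} contains non-finite values")
    return arr


def _check_modality(modality: str) -> None:
    if modality not in MODALITIES:
        raise InvalidTraceError(
            f"unknown modality {modality!r}; expected one of {sorted(MODALITIES)}"
        )


@dataclass(frozen=True)
class StrainTrace:
    """A raw exported strain or rotation trace for one cardiac cycle.

    Parameters
    ----------
    values
        Ordered samples (strain in % or rotation in degrees), length >= 2.
    modality
        One of ``gls``, ``rotation_apical``, ``rotation_basal``,
        ``rv_free_wall``, ``torsion``.
    subject_id
        Opaque patient identifier.
    """

    values: np.ndarray
    modality: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _check_values(self.values, "trace"))
        _check_modality(self.modality)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class NormalizedCurve:
    """A curve sampled on the fixed cardiac-cycle grid t in [0, 1]."""

    values: np.ndarray
    modality: str
    subject_id: str = ""
    grid: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = _check_values(self.values, "curve")
        if arr.size != GRID_LENGTH:
            raise InvalidTraceError(
                f"normalized curve must have length {GRID_LENGTH}, got {arr.size}"
            )
        object.__setattr__(self, "values", arr)
        _check_modality(self.modality)
        object.__setattr__(self, "grid", cycle_grid(arr.size))

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class CurveSummary:
    """Peak value and its timing for a normalized curve."""

    peak_value: float
    time_to_peak: float


def resample_trace(trace: StrainTrace, length: int = GRID_LENGTH) -> NormalizedCurve:
    """Resample a raw trace to the fixed-length cycle grid.

    Input samples are placed at equally spaced positions spanning [0, 1] and
    the curve is evaluated on the target grid by piecewise-linear
    interpolation, so the trace endpoints are preserved exactly and the
    output never overshoots the input range.
    """
    if length < 2:
        raise InvalidTraceError(f"target length must be >= 2, got {length}")
    src = np.linspace(0.0, 1.0, len(trace))
    dst = cycle_grid(length)
    values = np.interp(dst, src, trace.values)
    return NormalizedCurve(values=values, modality=trace.modality, subject_id=trace.subject_id)


def compute_torsion(apical: NormalizedCurve, basal: NormalizedCurve) -> NormalizedCurve:
    """LV torsion: apical minus basal rotation, pointwise over the cycle."""
    if apical.modality != "rotation_apical":
        raise InvalidTraceError(f"expected rotation_apical, got {apical.modality!r}")
    if basal.modality != "rotation_basal":
        raise InvalidTraceError(f"expected rotation_basal, got {basal.modality!r}")
    if len(apical) != len(basal):
        raise InvalidTraceError("apical and basal curves have mismatched lengths")
    subject = apical.subject_id or basal.subject_id
    return NormalizedCurve(
        values=apical.values - basal.values, modality="torsion", subject_id=subject
    )


def summarize_curve(curve: NormalizedCurve) -> CurveSummary:
    """Extract the physiological peak and its cycle-proportion timing.

    For negative-valued strain modalities (GLS, RV free wall) the peak is
    the minimum; for rotations and torsion it is the maximum.  Ties are
    broken by the earliest time (numpy's arg scan returns the first hit).
    """
    if curve.modality in NEGATIVE_PEAK_MODALITIES:
        idx = int(np.argmin(curve.values))
    else:
        idx = int(np.argmax(curve.values))
    return CurveSummary(
        peak_value=float(curve.values[idx]), time_to_peak=float(curve.grid[idx])
    )
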
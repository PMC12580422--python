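"""Penalized B-spline bases and numerical integration on the cycle grid.

The functional coefficient beta(t) of a scalar-on-function term is
represented as a linear combination of K B-spline basis functions with a
difference penalty on the basis coefficients (the standard P-spline
construction).  The integral term  int X_i(t) beta(t) dt  is approximated by
trapezoid quadrature on the 33-point grid, which is exact for the
piecewise-linear curves produced by time normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .curves import GRID_LENGTH, NormalizedCurve, cycle_grid

__all__ = ["BasisSpec", "quadrature_weights", "build_basis", "functional_design"]


@dataclass(frozen=True)
class BasisSpec:
    """Specification of the spline basis for a functional coefficient.

    Attributes
    ----------
    n_basis
        Number of basis functions K (default 9).
    order
        Spline order (4 = cubic).
    penalty_order
        Order of the difference penalty on basis coefficients (2 penalizes
        deviation from a straight line).
    """

    n_basis: int = 9
    order: int = 4
    penalty_order: int = 2

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError(f"spline order must be >= 1, got {self.order}")
        if self.penalty_order < 0:
            raise ValueError("penalty order must be >= 0")
        if self.n_basis <= self.penalty_order:
            raise ValueError(
                f"n_basis ({self.n_basis}) must exceed penalty_order ({self.penalty_order})"
            )
        if self.n_basis > GRID_LENGTH:
            raise ValueError(f"n_basis must be <= {GRID_LENGTH}, got {self.n_basis}")
        if self.n_basis < self.order:
            raise ValueError(
                f"n_basis ({self.n_basis}) must be >= spline order ({self.order})"
            )


def quadrature_weights(length: int = GRID_LENGTH) -> np.ndarray:
    """Trapezoid weights on the uniform [0, 1] grid; they sum to 1."""
    if length < 2:
        raise ValueError(f"need at least 2 grid points, got {length}")
    h = 1.0 / (length - 1)
    w = np.full(length, h)
    w[0] = w[-1] = h / 2.0
    return w


def knot_vector(spec: BasisSpec) -> np.ndarray:
    """Clamped, equally spaced knot vector on [0, 1] for the given spec."""
    degree = spec.order - 1
    n_interior = spec.n_basis - spec.order
    interior = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
    return np.concatenate(
        [np.zeros(spec.order), interior, np.ones(spec.order)]
    )


def build_basis(
    spec: BasisSpec, length: int = GRID_LENGTH
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the B-spline basis on the cycle grid and build its penalty.

    Returns
    -------
    B : (length, K) array
        Basis functions evaluated at the grid points; rows sum to 1
        (partition of unity on the clamped knot vector).
    P : (K, K) array
        Difference penalty ``D' D`` with ``D`` the penalty_order-th
        difference operator; symmetric PSD with null space of dimension
        penalty_order.
    """
    t = knot_vector(spec)
    x = cycle_grid(length)
    B = BSpline.design_matrix(x, t, spec.order - 1, extrapolate=False).toarray()
    if spec.penalty_order == 0:
        P = np.eye(spec.n_basis)
    else:
        D = np.diff(np.eye(spec.n_basis), n=spec.penalty_order, axis=0)
        P = D.T @ D
    return B, P


def _curve_matrix(curves) -> np.ndarray:
    rows = []
    for c in curves:
        rows.append(c.values if isinstance(c, NormalizedCurve) else np.asarray(c, float))
    X = np.asarray(rows, dtype=float)
    if X.ndim != 2 or X.shape[1] != GRID_LENGTH:
        raise ValueError(f"curves must all have length {GRID_LENGTH}")
    return X


def functional_design(
    curves,
    basis: np.ndarray,
    weights: np.ndarray,
    centering: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature design block for one functional term.

    Row (i, k) approximates  int (X_i(t) - Xbar(t)) b_k(t) dt  by trapezoid
    quadrature.  The centering curve Xbar defaults to the sample mean curve
    and is returned so it can be stored and re-applied at prediction time.

    Parameters
    ----------
    curves
        Sequence of :class:`NormalizedCurve` or raw length-33 arrays.
    basis
        (33, K) basis matrix from :func:`build_basis`.
    weights
        Quadrature weights from :func:`quadrature_weights`.
    centering
        Optional explicit centering curve (length 33).

    Returns
    -------
    design : (n, K) array
    centering : (33,) array actually used
    """
    X = _curve_matrix(curves)
    if X.shape[0] == 0:
        raise ValueError("empty curve list")
    if centering is None:
        centering = X.mean(axis=0)
    else:
        centering = np.asarray(centering, dtype=float)
        if centering.shape != (X.shape[1],):
            raise ValueError("centering curve has wrong length")
    Xc = X - centering
    design = (Xc * weights) @ basis
    return design, centering
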
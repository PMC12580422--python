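"""Interpretable effect measures and report rendering for fitted models.

A fitted functional coefficient is hard to read directly, so effects are
summarized as the consequence of a concrete curve perturbation: add a
constant ``delta`` (curve units: % strain or degrees) to the covariate
curve over a window of the cardiac cycle and report the implied odds ratio
(binomial fit) or expected SBP change in mmHg (Gaussian fit) with a
delta-method Wald interval.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .curves import GRID_LENGTH, cycle_grid
from .sofr import FitResult, pointwise_band

__all__ = ["Perturbation", "PerturbationEffect", "perturbation_effect", "render_report"]


@dataclass(frozen=True)
class Perturbation:
    """A constant additive shift of one covariate curve over a cycle window.

    ``delta`` is in the curve's own units, e.g. ``-5`` for "5% more
    negative GLS" or ``+5`` for 5 degrees more torsion; the default window
    (0.5, 1.0] is the diastolic half of the cycle.
    """

    term: str
    delta: float
    t_start: float = 0.5
    t_end: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.t_start < self.t_end <= 1.0):
            raise ValueError(
                f"perturbation window [{self.t_start}, {self.t_end}] must satisfy "
                "0 <= t_start < t_end <= 1"
            )


@dataclass(frozen=True)
class PerturbationEffect:
    estimate: float
    ci_low: float
    ci_high: float
    scale: str                 # "or" | "mmHg"
    log_estimate: float        # linear-predictor change (log-OR or mmHg)
    log_se: float


def _window_weights(t_start: float, t_end: float) -> np.ndarray:
    """Trapezoid weights restricted to the window, endpoints snapped to the
    nearest grid points so the integral stays exact for piecewise-linear
    coefficients."""
    grid = cycle_grid(GRID_LENGTH)
    h = 1.0 / (GRID_LENGTH - 1)
    i0 = int(round(t_start / h))
    i1 = int(round(t_end / h))
    if i1 <= i0:
        i1 = min(i0 + 1, GRID_LENGTH - 1)
        i0 = i1 - 1
    w = np.zeros(GRID_LENGTH)
    w[i0: i1 + 1] = h
    w[i0] = w[i1] = h / 2.0
    return w


def perturbation_effect(fit: FitResult, pert: Perturbation, level: float = 0.95
                        ) -> PerturbationEffect:
    """Effect of shifting a covariate curve by ``delta`` over the window.

    The linear-predictor change is  eta = delta * int_window beta(t) dt,
    evaluated by trapezoid quadrature on the snapped window.  For binomial
    fits the estimate is the odds ratio exp(eta); for Gaussian fits it is
    eta itself in mmHg.  The Wald interval propagates the penalized
    coefficient covariance through the same linear functional.
    """
    fc = fit.functional_terms[pert.term]
    w = _window_weights(pert.t_start, pert.t_end)
    eta = pert.delta * float(w @ fc.beta)
    var = pert.delta**2 * float(w @ fc.cov_beta @ w)
    se = math.sqrt(max(var, 0.0))
    z = float(norm.ppf(0.5 + level / 2.0))
    if fit.family == "binomial":
        return PerturbationEffect(
            estimate=math.exp(eta),
            ci_low=math.exp(eta - z * se),
            ci_high=math.exp(eta + z * se),
            scale="or",
            log_estimate=eta,
            log_se=se,
        )
    return PerturbationEffect(
        estimate=eta, ci_low=eta - z * se, ci_high=eta + z * se,
        scale="mmHg", log_estimate=eta, log_se=se,
    )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _coef_table(fit: FitResult) -> pd.DataFrame:
    rows = [
        {
            "term": t.name,
            "coefficient": t.estimate,
            "ci_low": t.ci_low,
            "ci_high": t.ci_high,
            "p": t.p,
        }
        for t in fit.scalar_terms
    ]
    return pd.DataFrame(rows)


def _band_frame(fit: FitResult, term: str, level: float = 0.95) -> pd.DataFrame:
    fc = fit.functional_terms[term]
    band = pointwise_band(fit, term, level)
    return pd.DataFrame(
        {
            "t": fc.grid,
            "beta": fc.beta,
            "se": fc.se,
            "lower": band.lower,
            "upper": band.upper,
        }
    )


def _plot_band(df: pd.DataFrame, term: str, ylabel: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.fill_between(df["t"], df["lower"], df["upper"], alpha=0.25, lw=0)
    ax.plot(df["t"], df["beta"], lw=1.5)
    ax.axhline(0.0, ls="--", lw=0.8, color="k")
    ax.set_xlabel("cardiac cycle proportion")
    ax.set_ylabel(ylabel)
    ax.set_title(term)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_mean_curves(curves: dict[str, np.ndarray], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = cycle_grid(GRID_LENGTH)
    fig, axes = plt.subplots(1, len(curves), figsize=(4 * len(curves), 3))
    if len(curves) == 1:
        axes = [axes]
    for ax, (name, arr) in zip(axes, curves.items()):
        mean = arr.mean(axis=0)
        sem = arr.std(axis=0) / math.sqrt(arr.shape[0])
        ax.fill_between(grid, mean - 2 * sem, mean + 2 * sem, alpha=0.25, lw=0)
        ax.plot(grid, mean, lw=1.5)
        ax.set_title(name)
        ax.set_xlabel("cardiac cycle proportion")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_report(
    fits,
    effects: dict[str, PerturbationEffect] | None = None,
    out_dir="report",
    curves: dict[str, np.ndarray] | None = None,
) -> list[Path]:
    """Write coefficient tables, beta(t) band plots and effect summaries.

    Each fit yields a ``<family>_coefficients.csv`` and per functional term
    a ``<family>_<term>_beta.csv`` + PNG pair (estimate, pointwise band,
    dashed zero line, x = cycle proportion).  When ``curves`` is given a
    mean-curve figure is added.  Returns the list of files written.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("need at least one fit to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for fit in fits:
        prefix = fit.family
        table = _coef_table(fit)
        path = out / f"{prefix}_coefficients.csv"
        table.to_csv(path, index=False, float_format="%.10g")
        written.append(path)
        ylabel = ("log-OR per curve-unit" if fit.family == "binomial"
                  else "mmHg per curve-unit")
        for term in fit.functional_terms:
            df = _band_frame(fit, term)
            cpath = out / f"{prefix}_{term}_beta.csv"
            df.to_csv(cpath, index=False, float_format="%.12g")
            written.append(cpath)
            ppath = out / f"{prefix}_{term}_beta.png"
            _plot_band(df, term, ylabel, ppath)
            written.append(ppath)
    if effects:
        epath = out / "effects.json"
        with open(epath, "w") as fh:
            json.dump(
                {
                    name: {
                        "estimate": e.estimate,
                        "ci_low": e.ci_low,
                        "ci_high": e.ci_high,
                        "scale": e.scale,
                    }
                    for name, e in effects.items()
                },
                fh,
                indent=2,
            )
        written.append(epath)
    if curves is not None:
        mpath = out / "mean_curves.png"
        _plot_mean_curves(curves, mpath)
        written.append(mpath)
    return written
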
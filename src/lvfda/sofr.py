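"""Penalized scalar-on-function regression for repeated SBP and mortality.

The blood-pressure model is a multilevel Gaussian regression

    SBP_ij = alpha + occasion_j + z_i' gamma
             + sum_terms  int beta_term(t) X_i,term(t) dt  + b_i + eps_ij,

with a patient random intercept b_i ~ N(0, sigma_b^2) and functional
coefficients beta(t) expanded in a penalized B-spline basis.  Mortality is
a binomial logit model on the same functional terms fitted at patient
level.  Estimation uses the mixed-model representation of penalized
splines: each difference penalty is eigen-decomposed into an unpenalized
null space (fixed effects) and a penalized range space whose coefficients
act as i.i.d. random effects, so smoothing parameters and the random
intercept variance are selected jointly by REML (profiled deviance in the
Bates et al. form).  The binomial fit alternates IRLS with REML smoothing
selection on the working model (performance iteration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_solve, cholesky
from scipy.special import expit, logit
from scipy.stats import chi2, norm

from .basis import BasisSpec, build_basis, functional_design, quadrature_weights
from .curves import GRID_LENGTH, cycle_grid
from .data import FUNCTIONAL_TERMS, SCALAR_COVARIATES, CohortDataset

__all__ = [
    "FitOptions",
    "ScalarTerm",
    "FunctionalCoefficient",
    "ConfidenceBand",
    "FitResult",
    "fit_sofr_gaussian",
    "fit_sofr_binomial",
    "pointwise_band",
    "global_pvalue",
    "bootstrap_band",
    "build_gaussian_design",
    "RankDeficiencyError",
    "ConvergenceError",
    "SeparationError",
    "BootstrapError",
]


class RankDeficiencyError(ValueError):
    """The scalar design is singular (e.g. a constant covariate)."""


class ConvergenceError(RuntimeError):
    """The (penalized) likelihood optimizer did not converge."""


class SeparationError(RuntimeError):
    """Complete separation in the binomial fit: the MLE diverges."""


class BootstrapError(RuntimeError):
    """Too many bootstrap replicates failed to converge."""


_LOG_GAMMA_BOUND = 30.0  # log variance-ratio box; exp(+-30) covers any practical lambda


@dataclass(frozen=True)
class FitOptions:
    """Tuning switches for the scalar-on-function fitters.

    ``fixed_lambda`` pins the smoothing parameter of a functional term
    instead of selecting it by REML; ``0`` gives an unpenalized fit and
    ``inf`` removes the term (beta identically zero).
    ``fixed_random_intercept_ratio`` pins lambda_b = sigma_eps^2/sigma_b^2
    (``inf`` drops the random intercept).
    """

    functional_terms: tuple[str, ...] = FUNCTIONAL_TERMS
    scalar_terms: tuple[str, ...] = SCALAR_COVARIATES
    include_occasion: bool = True
    fixed_lambda: dict[str, float] = field(default_factory=dict)
    fixed_random_intercept_ratio: float | None = None
    max_iter: int = 200
    tol: float = 1e-8


@dataclass(frozen=True)
class ScalarTerm:
    name: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class FunctionalCoefficient:
    """A fitted functional coefficient beta(t) on the cycle grid."""

    name: str
    coefs: np.ndarray          # basis coefficients, length K
    basis: np.ndarray          # (33, K) basis matrix
    beta: np.ndarray           # beta(t_l), length 33
    se: np.ndarray             # pointwise SE, length 33
    cov_beta: np.ndarray       # (33, 33) covariance of beta on the grid
    edf: float
    units: str

    @property
    def grid(self) -> np.ndarray:
        return cycle_grid(self.beta.size)


@dataclass(frozen=True)
class ConfidenceBand:
    grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    method: str


@dataclass
class FitResult:
    family: str
    scalar_terms: list[ScalarTerm]
    functional_terms: dict[str, FunctionalCoefficient]
    lambdas: dict[str, float]
    global_p: dict[str, float]
    loglik: float
    aic: float
    edf_total: float
    n_obs: int
    spec: BasisSpec
    options: FitOptions
    centering: dict[str, np.ndarray]
    sigma_b: float | None = None
    sigma_eps: float | None = None
    variance_explained: float | None = None
    random_effects: pd.Series | None = None
    fitted: np.ndarray | None = None

    def scalar(self, name: str) -> ScalarTerm:
        for t in self.scalar_terms:
            if t.name == name:
                return t
        raise KeyError(name)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

@dataclass
class _TermMap:
    name: str
    mode: str                      # excluded | unpenalized | penalized
    fixed_idx: np.ndarray          # global column indices of the null-space part
    rand_idx: np.ndarray           # global column indices of the penalized part
    T_fixed: np.ndarray            # K x d0 map from fixed coefs to basis coefs
    T_rand: np.ndarray             # K x r map from penalized coefs to basis coefs


@dataclass
class _Block:
    name: str
    sl: slice                      # columns of C (random part lives in [0, q))
    free: bool
    gamma_fixed: float | None


@dataclass
class _Design:
    y: np.ndarray                  # centered response
    y_mean: float
    C: np.ndarray                  # [random blocks | fixed columns]
    q: int
    p: int
    blocks: list[_Block]
    fixed_names: list[str]
    term_maps: dict[str, _TermMap]
    scalar_cols: dict[str, tuple[int, float, float]]  # name -> (global col, center, scale)
    intercept_col: int
    basis: np.ndarray
    penalty: np.ndarray
    centering: dict[str, np.ndarray]
    subject_of_rand_col: list[str] | None = None      # for the random-intercept block
    weights: np.ndarray | None = None                 # prior weights (binomial IRLS)


def _penalty_reparam(P: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split the penalty into null space U0 and scaled range space.

    Returns (U0, U_plus, scale) with beta-coefs = U0 d + U_plus diag(scale) u
    and penalty quadratic form = u'u.
    """
    vals, vecs = np.linalg.eigh(P)
    tol = vals.max() * 1e-10
    null = vals <= tol
    U0 = vecs[:, null]
    Up = vecs[:, ~null]
    scale = 1.0 / np.sqrt(vals[~null])
    return U0, Up, scale


def _scalar_matrix(
    data: CohortDataset, names: tuple[str, ...]
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    cols, trans = [], []
    for name in names:
        x = data.covariates[name].to_numpy(float)
        m, s = float(x.mean()), float(x.std())
        if s <= 0:
            raise RankDeficiencyError(
                f"scalar covariate {name!r} is constant: the design is singular"
            )
        cols.append((x - m) / s)
        trans.append((m, s))
    X = np.column_stack(cols) if cols else np.empty((data.n_patients, 0))
    return X, trans


def _assemble(
    y: np.ndarray,
    fixed_cols: list[np.ndarray],
    fixed_names: list[str],
    rand_parts: list[tuple[str, np.ndarray, bool, float | None]],
    term_info: list[tuple[str, str, np.ndarray | None, np.ndarray | None, list[int], str]],
    scalar_entries: list[tuple[str, int, float, float]],
    basis: np.ndarray,
    penalty: np.ndarray,
    centering: dict[str, np.ndarray],
    subject_of_rand_col: list[str] | None,
    weights: np.ndarray | None,
) -> _Design:
    """Glue the pieces into a _Design with random columns first."""
    blocks, zmats = [], []
    start = 0
    for name, Z, free, gfix in rand_parts:
        blocks.append(_Block(name, slice(start, start + Z.shape[1]), free, gfix))
        zmats.append(Z)
        start += Z.shape[1]
    q = start
    X = np.column_stack(fixed_cols) if fixed_cols else np.empty((y.size, 0))
    C = np.hstack(zmats + [X]) if zmats else X
    p = X.shape[1]

    term_maps: dict[str, _TermMap] = {}
    for name, mode, Tf, Tr, fcols, bname in term_info:
        rand_idx = np.empty(0, dtype=int)
        if bname:
            for b in blocks:
                if b.name == bname:
                    rand_idx = np.arange(b.sl.start, b.sl.stop)
        term_maps[name] = _TermMap(
            name=name,
            mode=mode,
            fixed_idx=np.asarray([q + j for j in fcols], dtype=int),
            rand_idx=rand_idx,
            T_fixed=Tf if Tf is not None else np.empty((basis.shape[1], 0)),
            T_rand=Tr if Tr is not None else np.empty((basis.shape[1], 0)),
        )
    scalar_cols = {name: (q + j, m, s) for name, j, m, s in scalar_entries}
    ymean = float(y.mean())
    return _Design(
        y=y - ymean,
        y_mean=ymean,
        C=C,
        q=q,
        p=p,
        blocks=blocks,
        fixed_names=fixed_names,
        term_maps=term_maps,
        scalar_cols=scalar_cols,
        intercept_col=q + fixed_names.index("intercept"),
        basis=basis,
        penalty=penalty,
        centering=centering,
        subject_of_rand_col=subject_of_rand_col,
        weights=weights,
    )


def _functional_parts(
    data: CohortDataset,
    spec: BasisSpec,
    options: FitOptions,
    fixed_cols: list[np.ndarray],
    fixed_names: list[str],
    rand_parts: list,
    term_info: list,
    centering: dict[str, np.ndarray],
    expand: np.ndarray | None,
) -> None:
    """Append the functional-term design pieces (in place)."""
    B, P = build_basis(spec)
    w = quadrature_weights()
    U0, Up, scale = _penalty_reparam(P)
    for term in options.functional_terms:
        lam = options.fixed_lambda.get(term)
        Zraw, cent = functional_design(data.curves[term], B, w)
        centering[term] = cent
        if expand is not None:
            Zraw = Zraw[expand]
        if lam is not None and math.isinf(lam):
            term_info.append((term, "excluded", None, None, [], ""))
            continue
        if lam is not None and lam == 0.0:
            fcols = list(range(len(fixed_names), len(fixed_names) + Zraw.shape[1]))
            for k in range(Zraw.shape[1]):
                fixed_cols.append(Zraw[:, k])
                fixed_names.append(f"{term}:b{k}")
            term_info.append(
                (term, "unpenalized", np.eye(spec.n_basis), None, fcols, "")
            )
            continue
        # penalized: null space -> fixed, range space -> random block
        Fnull = Zraw @ U0
        fcols = list(range(len(fixed_names), len(fixed_names) + Fnull.shape[1]))
        for k in range(Fnull.shape[1]):
            fixed_cols.append(Fnull[:, k])
            fixed_names.append(f"{term}:null{k}")
        Zr = Zraw @ (Up * scale)
        gfix = None if lam is None else 1.0 / lam
        rand_parts.append((term, Zr, lam is None, gfix))
        term_info.append((term, "penalized", U0, Up * scale, fcols, term))


def build_gaussian_design(
    data: CohortDataset, spec: BasisSpec, options: FitOptions | None = None
) -> _Design:
    """Long-format design for the multilevel SBP model.

    One row per non-missing SBP measurement; fixed columns are the
    intercept, occasion indicators, standardized scalar covariates and the
    penalty null spaces of the functional terms; penalized columns are the
    spline range spaces and the patient indicators of the random intercept.
    """
    options = options or FitOptions()
    n, S, O = data.sbp.shape
    mask = np.isfinite(data.sbp)
    if not mask.any():
        raise ValueError("no SBP measurements present")
    pat_idx, ses_idx, occ_idx = np.nonzero(mask)
    y = data.sbp[mask]
    n_obs = y.size
    per_patient = mask.reshape(n, -1).sum(axis=1)
    if data.n_patients < 2 or (per_patient > 0).sum() < 2:
        raise ValueError("need at least 2 patients with SBP measurements")

    fixed_cols = [np.ones(n_obs)]
    fixed_names = ["intercept"]
    if options.include_occasion:
        for j in range(1, O):
            fixed_cols.append((occ_idx == j).astype(float))
            fixed_names.append(f"occasion_{j + 1}")
    Xs, trans = _scalar_matrix(data, options.scalar_terms)
    scalar_entries = []
    for j, name in enumerate(options.scalar_terms):
        scalar_entries.append((name, len(fixed_names), trans[j][0], trans[j][1]))
        fixed_cols.append(Xs[pat_idx, j])
        fixed_names.append(name)

    rand_parts: list = []
    term_info: list = []
    centering: dict[str, np.ndarray] = {}
    _functional_parts(
        data, spec, options, fixed_cols, fixed_names, rand_parts, term_info,
        centering, expand=pat_idx,
    )

    subject_names = None
    ratio = options.fixed_random_intercept_ratio
    if ratio is None or not math.isinf(ratio):
        Zb = np.zeros((n_obs, n))
        Zb[np.arange(n_obs), pat_idx] = 1.0
        gfix = None if ratio is None else 1.0 / ratio
        rand_parts.append(("patient", Zb, ratio is None, gfix))
        subject_names = list(data.subjects)

    B, P = build_basis(spec)
    return _assemble(
        y, fixed_cols, fixed_names, rand_parts, term_info, scalar_entries,
        B, P, centering, subject_names, weights=None,
    )


def build_binomial_design(
    data: CohortDataset, spec: BasisSpec, options: FitOptions
) -> tuple[_Design, np.ndarray]:
    """Patient-level design for the mortality model; returns (design, y)."""
    y = data.death.astype(float)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("binomial fit needs at least one event and one non-event")
    n = data.n_patients
    fixed_cols = [np.ones(n)]
    fixed_names = ["intercept"]
    Xs, trans = _scalar_matrix(data, options.scalar_terms)
    scalar_entries = []
    for j, name in enumerate(options.scalar_terms):
        scalar_entries.append((name, len(fixed_names), trans[j][0], trans[j][1]))
        fixed_cols.append(Xs[:, j])
        fixed_names.append(name)
    rand_parts: list = []
    term_info: list = []
    centering: dict[str, np.ndarray] = {}
    _functional_parts(
        data, spec, options, fixed_cols, fixed_names, rand_parts, term_info,
        centering, expand=None,
    )
    B, P = build_basis(spec)
    design = _assemble(
        np.zeros(n), fixed_cols, fixed_names, rand_parts, term_info,
        scalar_entries, B, P, centering, None, weights=None,
    )
    design.y = y          # binomial response is not centered
    design.y_mean = 0.0
    return design, y


# ---------------------------------------------------------------------------
# penalized least squares + REML
# ---------------------------------------------------------------------------

def _scale_vector(design: _Design, gammas: dict[str, float]) -> np.ndarray:
    s = np.ones(design.q + design.p)
    for b in design.blocks:
        g = gammas[b.name]
        s[b.sl] = math.sqrt(g) if g > 0 else 0.0
    return s


def _pls(
    M: np.ndarray, c: np.ndarray, yty: float, design: _Design, gammas: dict[str, float]
):
    """Solve the penalized normal equations for given variance ratios.

    Returns (solution in scaled coords, Cholesky factor, scale vector,
    penalized RSS, logdet of the random block, logdet of the fixed Schur
    complement).
    """
    q, p = design.q, design.p
    s = _scale_vector(design, gammas)
    A = M * s[:, None] * s[None, :]
    idx = np.arange(q)
    A[idx, idx] += 1.0
    try:
        L = cholesky(A, lower=True)
    except np.linalg.LinAlgError as err:
        raise RankDeficiencyError(
            "singular design: check for constant or collinear covariates"
        ) from err
    cs = c * s
    w = cho_solve((L, True), cs)
    r2 = max(yty - float(cs @ w), 0.0)
    d = np.log(np.diag(L))
    return w, L, s, r2, 2.0 * d[:q].sum(), 2.0 * d[q:].sum()


def _neg2_reml(
    M: np.ndarray, c: np.ndarray, yty: float, design: _Design,
    gammas: dict[str, float], n_obs: int,
) -> float:
    _, _, _, r2, ld_omega, ld_schur = _pls(M, c, yty, design, gammas)
    nm = n_obs - design.p
    r2 = max(r2, 1e-300)
    return ld_omega + ld_schur + nm * (1.0 + math.log(2.0 * math.pi * r2 / nm))


def _optimize_gammas(
    M: np.ndarray, c: np.ndarray, yty: float, design: _Design, n_obs: int,
    max_iter: int, tol: float, start: dict[str, float] | None = None,
) -> dict[str, float]:
    free = [b.name for b in design.blocks if b.free]
    gammas = {b.name: (b.gamma_fixed if b.gamma_fixed is not None else 1.0)
              for b in design.blocks}
    if start:
        gammas.update({k: v for k, v in start.items() if k in gammas})
    if not free:
        return gammas

    def objective(x: np.ndarray) -> float:
        g = dict(gammas)
        for name, xi in zip(free, x):
            g[name] = math.exp(float(np.clip(xi, -_LOG_GAMMA_BOUND, _LOG_GAMMA_BOUND)))
        return _neg2_reml(M, c, yty, design, g, n_obs)

    x0 = np.array([
        float(np.clip(math.log(max(gammas[name], 1e-13)), -_LOG_GAMMA_BOUND, _LOG_GAMMA_BOUND))
        for name in free
    ])
    res = optimize.minimize(
        objective, x0, method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 400 * max(1, len(free))},
    )
    if not np.isfinite(res.fun):
        raise ConvergenceError(
            f"REML optimization diverged (last objective {res.fun!r})"
        )
    spread = float(np.ptp(res.final_simplex[1]))
    if not res.success and spread > 1e-2:
        # tolerate a flat simplex (the profiled deviance is often nearly
        # constant in a smoothing parameter once a term is effectively
        # linear); only a genuinely unsettled optimum is an error
        raise ConvergenceError(
            f"REML optimization hit the iteration cap; final simplex spread {spread:.3e}"
        )
    for name, xi in zip(free, res.x):
        gammas[name] = math.exp(float(np.clip(xi, -_LOG_GAMMA_BOUND, _LOG_GAMMA_BOUND)))
    return gammas


# ---------------------------------------------------------------------------
# result extraction
# ---------------------------------------------------------------------------

_Z975 = float(norm.ppf(0.975))


def _natural_solution(M, c, yty, design, gammas):
    """Solve and return coefficients and unit-scale covariance (natural coords)."""
    w, L, s, r2, _, _ = _pls(M, c, yty, design, gammas)
    Ainv = cho_solve((L, True), np.eye(s.size))
    Ms = M * s[:, None] * s[None, :]
    edf_cols = np.einsum("ij,ji->i", Ainv, Ms)
    w_nat = s * w
    V_nat = (s[:, None] * Ainv * s[None, :])
    return w_nat, V_nat, r2, edf_cols


def _scalar_table(design: _Design, w_nat, V_nat, extra_offset=0.0) -> list[ScalarTerm]:
    dim = w_nat.size
    rows: list[tuple[str, np.ndarray, float]] = []
    a0 = np.zeros(dim)
    a0[design.intercept_col] = 1.0
    for name, (col, m, sc) in design.scalar_cols.items():
        a0[col] -= m / sc
    rows.append(("intercept", a0, design.y_mean + extra_offset))
    for j, name in enumerate(design.fixed_names):
        if name == "intercept":
            continue
        if name in design.scalar_cols:
            continue
        if ":" in name:  # functional null-space / basis columns
            continue
        a = np.zeros(dim)
        a[design.q + j] = 1.0
        rows.append((name, a, 0.0))
    for name, (col, m, sc) in design.scalar_cols.items():
        a = np.zeros(dim)
        a[col] = 1.0 / sc
        rows.append((name, a, 0.0))

    out = []
    for name, a, off in rows:
        est = float(a @ w_nat) + off
        se = float(math.sqrt(max(a @ V_nat @ a, 0.0)))
        z = est / se if se > 0 else math.inf * np.sign(est) if est else 0.0
        out.append(
            ScalarTerm(
                name=name, estimate=est, se=se,
                ci_low=est - _Z975 * se, ci_high=est + _Z975 * se,
                p=float(2.0 * norm.sf(abs(z))) if se > 0 else (0.0 if est else 1.0),
            )
        )
    return out


def _functional_table(
    design: _Design, w_nat, V_nat, edf_cols, units: str
) -> dict[str, FunctionalCoefficient]:
    B = design.basis
    K = B.shape[1]
    out: dict[str, FunctionalCoefficient] = {}
    for name, tm in design.term_maps.items():
        if tm.mode == "excluded":
            out[name] = FunctionalCoefficient(
                name=name, coefs=np.zeros(K), basis=B,
                beta=np.zeros(B.shape[0]), se=np.zeros(B.shape[0]),
                cov_beta=np.zeros((B.shape[0],) * 2), edf=0.0, units=units,
            )
            continue
        idx = np.concatenate([tm.fixed_idx, tm.rand_idx])
        T = np.hstack([tm.T_fixed, tm.T_rand])  # K x (d0 + r)
        theta = T @ w_nat[idx]
        Vt = T @ V_nat[np.ix_(idx, idx)] @ T.T
        beta = B @ theta
        covb = B @ Vt @ B.T
        se = np.sqrt(np.clip(np.diag(covb), 0.0, None))
        out[name] = FunctionalCoefficient(
            name=name, coefs=theta, basis=B, beta=beta, se=se,
            cov_beta=covb, edf=float(edf_cols[idx].sum()), units=units,
        )
    return out


def _lambdas_from_gammas(design: _Design, gammas: dict[str, float]) -> dict[str, float]:
    lams = {}
    for name, tm in design.term_maps.items():
        if tm.mode == "excluded":
            lams[name] = math.inf
        elif tm.mode == "unpenalized":
            lams[name] = 0.0
        else:
            g = gammas[name]
            lams[name] = math.inf if g <= 0 else 1.0 / g
    return lams


# ---------------------------------------------------------------------------
# public fitters
# ---------------------------------------------------------------------------

def fit_sofr_gaussian(
    data: CohortDataset, spec: BasisSpec | None = None, options: FitOptions | None = None
) -> FitResult:
    """Fit the multilevel Gaussian scalar-on-function SBP model by REML."""
    spec = spec or BasisSpec()
    options = options or FitOptions()
    design = build_gaussian_design(data, spec, options)
    y, C = design.y, design.C
    n_obs = y.size
    M = C.T @ C
    c = C.T @ y
    yty = float(y @ y)

    gammas = _optimize_gammas(M, c, yty, design, n_obs, options.max_iter, options.tol)
    w_nat, V_unit, r2, edf_cols = _natural_solution(M, c, yty, design, gammas)
    nm = max(n_obs - design.p, 1)
    sigma2 = r2 / nm
    V_nat = sigma2 * V_unit

    fitted_c = C @ w_nat
    resid = y - fitted_c
    rss = float(resid @ resid)
    tss = yty
    ve = 1.0 if tss <= 1e-12 * max(1.0, abs(design.y_mean)) else 1.0 - rss / tss
    sigma_eps = math.sqrt(sigma2)
    gamma_b = gammas.get("patient", 0.0)
    sigma_b = sigma_eps * math.sqrt(gamma_b) if "patient" in gammas else 0.0

    edf_total = float(edf_cols.sum())
    cond_ll = -0.5 * n_obs * math.log(2.0 * math.pi * max(sigma2, 1e-300)) \
        - rss / (2.0 * max(sigma2, 1e-300))
    aic = -2.0 * cond_ll + 2.0 * (edf_total + 1.0)

    scalar_terms = _scalar_table(design, w_nat, V_nat)
    func_terms = _functional_table(
        design, w_nat, V_nat, edf_cols, units="mmHg per curve-unit"
    )
    ranef = None
    for b in design.blocks:
        if b.name == "patient":
            ranef = pd.Series(
                w_nat[b.sl], index=design.subject_of_rand_col, name="random_intercept"
            )
    lams = _lambdas_from_gammas(design, gammas)
    if "patient" in gammas:
        lams["patient"] = math.inf if gamma_b <= 0 else 1.0 / gamma_b

    fit = FitResult(
        family="gaussian",
        scalar_terms=scalar_terms,
        functional_terms=func_terms,
        lambdas=lams,
        global_p={},
        loglik=cond_ll,
        aic=aic,
        edf_total=edf_total,
        n_obs=n_obs,
        spec=spec,
        options=options,
        centering=design.centering,
        sigma_b=sigma_b,
        sigma_eps=sigma_eps,
        variance_explained=float(np.clip(ve, 0.0, 1.0)),
        random_effects=ranef,
        fitted=fitted_c + design.y_mean,
    )
    fit.global_p = {t: global_pvalue(fit, t) for t in func_terms}
    return fit


_BINOMIAL_DEFAULTS = FitOptions(
    functional_terms=("gls", "torsion"), scalar_terms=(), include_occasion=False
)


def binomial_options(age_adjusted: bool = False, **kwargs) -> FitOptions:
    """Default mortality-model options: GLS + torsion curves, no scalar
    adjustment (age only in the sensitivity variant)."""
    scalars = ("age",) if age_adjusted else ()
    return replace(_BINOMIAL_DEFAULTS, scalar_terms=scalars, **kwargs)


def _binomial_deviance(y: np.ndarray, eta: np.ndarray) -> float:
    mu = expit(eta)
    mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
    return -2.0 * float(y @ np.log(mu) + (1.0 - y) @ np.log(1.0 - mu))


def _penalty_value(design: _Design, w_nat: np.ndarray, gammas: dict[str, float]) -> float:
    pen = 0.0
    for b in design.blocks:
        g = gammas[b.name]
        if g > 0:
            pen += float(w_nat[b.sl] @ w_nat[b.sl]) / g
    return pen


def _pirls_fixed(
    y: np.ndarray,
    design: _Design,
    gammas: dict[str, float],
    max_iter: int,
    w0: np.ndarray | None = None,
):
    """Penalized IRLS at fixed variance ratios with deviance step-halving.

    Returns the converged state plus the log-determinant of the penalized
    information matrix needed by the Laplace REML criterion.
    """
    C = design.C
    w_nat = np.zeros(design.q + design.p) if w0 is None else w0.copy()
    eta = C @ w_nat
    obj = _binomial_deviance(y, eta) + _penalty_value(design, w_nat, gammas)
    state = None
    converged = False
    for _ in range(max_iter):
        mu = expit(eta)
        wts = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / wts
        sw = np.sqrt(wts)
        Cw = C * sw[:, None]
        M = Cw.T @ Cw
        c = Cw.T @ (z * sw)
        zty = float((z * sw) @ (z * sw))
        w_new, V_unit, _, edf_cols = _natural_solution(M, c, zty, design, gammas)
        step = 1.0
        for _ in range(50):
            w_try = w_nat + step * (w_new - w_nat)
            eta_try = C @ w_try
            obj_try = _binomial_deviance(y, eta_try) + _penalty_value(design, w_try, gammas)
            if np.isfinite(obj_try) and obj_try <= obj + 1e-12:
                break
            step /= 2.0
        else:
            converged = True  # no descent direction left: at the optimum
            break
        improvement = obj - obj_try
        w_nat, eta, obj = w_try, eta_try, obj_try
        state = (M, c, zty, V_unit, edf_cols)
        if step == 1.0 and improvement < 1e-10 * (abs(obj) + 1.0):
            converged = True
            break
    if state is None:  # w0 was already optimal; rebuild curvature at w0
        mu = expit(eta)
        wts = np.clip(mu * (1.0 - mu), 1e-10, None)
        sw = np.sqrt(wts)
        Cw = C * sw[:, None]
        M = Cw.T @ Cw
        c = Cw.T @ ((eta + (y - mu) / wts) * sw)
        zty = float(eta @ eta) + 1.0
        _, V_unit, _, edf_cols = _natural_solution(M, c, zty, design, gammas)
        state = (M, c, zty, V_unit, edf_cols)
        converged = True
    M, c, zty, V_unit, edf_cols = state
    _, _, _, _, ld_omega, ld_schur = _pls(M, c, zty, design, gammas)
    return {
        "w": w_nat,
        "eta": eta,
        "V_unit": V_unit,
        "edf_cols": edf_cols,
        "deviance": _binomial_deviance(y, eta),
        "penalty": _penalty_value(design, w_nat, gammas),
        "logdet": ld_omega + ld_schur,
        "converged": converged,
    }


def fit_sofr_binomial(
    data: CohortDataset, spec: BasisSpec | None = None, options: FitOptions | None = None
) -> FitResult:
    """Penalized logistic scalar-on-function fit of the mortality model.

    Coefficients are estimated by penalized IRLS with step-halving on the
    penalized deviance.  Smoothing parameters are selected by maximizing a
    Laplace-approximate restricted marginal likelihood: in the scaled
    mixed-model coordinates the criterion is
    ``deviance + u'u + log|penalized information|`` (the prior
    normalization is parameter-free there), minimized over the log
    variance ratios.
    """
    spec = spec or BasisSpec()
    options = options or binomial_options()
    design, y = build_binomial_design(data, spec, options)
    n = y.size
    free = [b.name for b in design.blocks if b.free]
    gammas = {b.name: (b.gamma_fixed if b.gamma_fixed is not None else 1.0)
              for b in design.blocks}

    if free:

        def criterion(x: np.ndarray) -> float:
            g = dict(gammas)
            for name, xi in zip(free, x):
                g[name] = math.exp(
                    float(np.clip(xi, -_LOG_GAMMA_BOUND, _LOG_GAMMA_BOUND))
                )
            r = _pirls_fixed(y, design, g, options.max_iter)
            return r["deviance"] + r["penalty"] + r["logdet"]

        res = optimize.minimize(
            criterion, np.zeros(len(free)), method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 400 * len(free)},
        )
        if not np.isfinite(res.fun):
            raise ConvergenceError("Laplace REML criterion diverged")
        for name, xi in zip(free, res.x):
            gammas[name] = math.exp(
                float(np.clip(xi, -_LOG_GAMMA_BOUND, _LOG_GAMMA_BOUND))
            )

    final = _pirls_fixed(y, design, gammas, options.max_iter)
    w_nat, eta = final["w"], final["eta"]
    if final["deviance"] < 1e-6 and np.max(np.abs(eta)) > 30.0:
        raise SeparationError(
            "fitted log-odds diverged with deviance collapsing to zero: "
            "complete separation in the mortality model"
        )
    if not final["converged"]:
        raise ConvergenceError(
            f"penalized IRLS did not converge in {options.max_iter} iterations"
        )
    V_unit, edf_cols = final["V_unit"], final["edf_cols"]

    # covariance at convergence with the binomial scale fixed at 1
    V_nat = V_unit  # (C'WC + Pen)^{-1} in natural coordinates
    mu = expit(eta)
    y = y.astype(float)
    ll = float(np.sum(y * np.log(np.clip(mu, 1e-300, 1.0))
                      + (1.0 - y) * np.log(np.clip(1.0 - mu, 1e-300, 1.0))))
    edf_total = float(edf_cols.sum())
    aic = -2.0 * ll + 2.0 * edf_total

    scalar_terms = _scalar_table(design, w_nat, V_nat)
    func_terms = _functional_table(
        design, w_nat, V_nat, edf_cols, units="log-odds per curve-unit"
    )
    fit = FitResult(
        family="binomial",
        scalar_terms=scalar_terms,
        functional_terms=func_terms,
        lambdas=_lambdas_from_gammas(design, gammas),
        global_p={},
        loglik=ll,
        aic=aic,
        edf_total=edf_total,
        n_obs=n,
        spec=spec,
        options=options,
        centering=design.centering,
        fitted=mu,
    )
    fit.global_p = {t: global_pvalue(fit, t) for t in func_terms}
    return fit


# ---------------------------------------------------------------------------
# inference on functional terms
# ---------------------------------------------------------------------------

def pointwise_band(fit: FitResult, term: str, level: float = 0.95) -> ConfidenceBand:
    """Wald pointwise band beta(t) +- z * SE(t) from the penalized covariance."""
    fc = fit.functional_terms[term]
    z = float(norm.ppf(0.5 + level / 2.0))
    return ConfidenceBand(
        grid=fc.grid, lower=fc.beta - z * fc.se, upper=fc.beta + z * fc.se,
        level=level, method="wald",
    )


def global_pvalue(fit: FitResult, term: str) -> float:
    """Wald-type global test of beta_term(t) == 0.

    The grid evaluation of beta and its covariance are reduced by a
    rank-truncated pseudo-inverse, with the rank set by the term's
    effective degrees of freedom; the statistic is referred to a
    chi-square with that many degrees of freedom.
    """
    fc = fit.functional_terms[term]
    if fc.edf <= 0 or not np.any(fc.beta):
        return 1.0
    vals, vecs = np.linalg.eigh(fc.cov_beta)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > vals[0] * 1e-10
    rank = int(min(pos.sum(), max(1, round(fc.edf))))
    proj = vecs[:, :rank].T @ fc.beta
    stat = float(np.sum(proj**2 / vals[:rank]))
    return float(chi2.sf(stat, rank))


def bootstrap_band(
    data: CohortDataset,
    spec: BasisSpec | None = None,
    term: str = "torsion",
    B: int = 200,
    seed: int | None = None,
    level: float = 0.95,
    family: str = "gaussian",
    options: FitOptions | None = None,
    refit_smoothing: bool = False,
) -> ConfidenceBand:
    """Cluster (patient-level) bootstrap percentile band for beta_term(t).

    Patients are resampled with replacement together with all their
    sessions and curves, the model is refitted per replicate, and the band
    is the pointwise percentile interval across replicates.  Deterministic
    given ``seed``.

    By default the smoothing parameters (and, for the Gaussian model, the
    random-intercept variance ratio) are pinned at their full-data REML
    estimates during the replicate refits; re-selecting them per replicate
    (``refit_smoothing=True``) adds substantial smoothing-selection noise
    to the band, especially in small cohorts.
    """
    if B < 50:
        raise ValueError(f"need at least 50 bootstrap replicates, got {B}")
    spec = spec or BasisSpec()
    fitter = fit_sofr_gaussian if family == "gaussian" else fit_sofr_binomial
    if options is None and family == "binomial":
        options = binomial_options()
    if options is None:
        options = FitOptions()
    if not refit_smoothing:
        full = fitter(data, spec, options)
        lam = dict(options.fixed_lambda)
        for t, v in full.lambdas.items():
            if t == "patient":
                continue
            lam.setdefault(t, float(np.clip(v, 1e-8, 1e10)))
        ratio = options.fixed_random_intercept_ratio
        if family == "gaussian" and ratio is None:
            ratio = float(np.clip(full.lambdas.get("patient", 1.0), 1e-8, 1e10))
        options = replace(options, fixed_lambda=lam,
                          fixed_random_intercept_ratio=ratio)
    rng = np.random.default_rng(seed)
    n = data.n_patients
    betas, failures = [], 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        try:
            refit = fitter(data.take(idx), spec, options)
            betas.append(refit.functional_terms[term].beta)
        except (ValueError, RuntimeError):
            failures += 1
    if failures > 0.2 * B:
        raise BootstrapError(
            f"{failures}/{B} bootstrap replicates failed to converge"
        )
    betas = np.asarray(betas)
    alpha = (1.0 - level) / 2.0
    return ConfidenceBand(
        grid=cycle_grid(GRID_LENGTH),
        lower=np.quantile(betas, alpha, axis=0),
        upper=np.quantile(betas, 1.0 - alpha, axis=0),
        level=level,
        method="bootstrap",
    )
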
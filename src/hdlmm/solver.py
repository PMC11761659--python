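"""Coordinate descent for the penalized mixed-model likelihood at one lam.

One outer iteration consists of (i) a sweep over the fixed-effect
coordinates — all p of them every D-th iteration or whenever a forced full
sweep is due, otherwise only the active set (currently nonzero coefficients
plus the unpenalized ones) — each coordinate solved exactly against its
local quadratic surrogate; followed by (ii) a sweep over the q*+1 variance
parameters, each minimized by bounded scalar search of the negative
log-likelihood. Termination requires the convergence criterion to hold
after a *full* fixed-effect sweep; if it first holds after an active-set
sweep, a full sweep is forced so that zeroed coefficients get a chance to
re-enter.

With p > N and lam too small the objective is unbounded below: the
coefficients interpolate the response and sigma2 is driven to zero, sending
log det(V) to -infinity. This regime is detected (sigma2 under a floor with
at least N nonzero coefficients, or a numerically singular V) and reported
on the result rather than raised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar

from .data import ClusteredData
from .likelihood import (
    LikelihoodCache,
    ModelParams,
    VarParams,
    n_var_params,
    neg_log_likelihood,
)
from .penalties import PenaltySpec, penalty_total, univariate_update

__all__ = ["SolverControl", "FitResult", "fit_once", "update_variance_param",
           "convergence_check"]


@dataclass(frozen=True)
class SolverControl:
    """Solver configuration.

    tol : relative-objective convergence tolerance (parameter changes are
        compared against sqrt(tol)).
    max_iter : cap on outer iterations.
    D : full fixed-effect sweeps happen every D-th iteration.
    sigma2_floor : sigma2 below this flags the interpolation regime;
        defaults to 1e-4 times the sample variance of y.
    """

    tol: float = 1e-4
    max_iter: int = 1000
    D: int = 5
    sigma2_floor: float | None = None
    seed: int | None = None
    verbose: bool = False

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.D < 1:
            raise ValueError("D must be >= 1")


@dataclass
class FitResult:
    """Solution of one coordinate-descent run at a fixed lam."""

    params: ModelParams
    objective: float
    loglik: float
    n_iter: int
    converged: bool
    diverged_interpolating: bool
    lam: float
    penalty: PenaltySpec
    active_history: list = field(default_factory=list, repr=False)

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.params.beta))


def convergence_check(
    prev: ModelParams,
    curr: ModelParams,
    prev_obj: float,
    curr_obj: float,
    control: SolverControl,
) -> bool:
    """Relative objective change under tol and parameter change under sqrt(tol)."""
    if not (np.isfinite(prev_obj) and np.isfinite(curr_obj)):
        return False
    rel = abs(curr_obj - prev_obj) / (1.0 + abs(prev_obj))
    if rel >= control.tol:
        return False
    delta = max(
        float(np.max(np.abs(curr.beta - prev.beta), initial=0.0)),
        float(np.max(np.abs(curr.var.theta - prev.var.theta), initial=0.0)),
        abs(curr.var.sigma2 - prev.var.sigma2),
    )
    return delta < np.sqrt(control.tol)


def _safe_nll(params: ModelParams, data: ClusteredData) -> float:
    try:
        return neg_log_likelihood(params, data)
    except np.linalg.LinAlgError:
        return np.inf


def update_variance_param(
    j: int,
    params: ModelParams,
    data: ClusteredData,
    bounds: tuple[float, float] | None = None,
    xatol: float = 1e-6,
) -> float:
    """Scalar minimizer of -l in the j-th variance parameter.

    Indices 0..q*-1 address theta entries (diagonal entries of L bounded
    below by 0); index q* addresses sigma2 (bounded below by a small
    positive value). If the minimizer lands on the upper bound, the bracket
    is widened geometrically up to a cap.
    """
    var = params.var
    qs = var.n_params
    if not 0 <= j <= qs:
        raise IndexError(f"variance-parameter index {j} out of range")
    is_sigma2 = j == qs
    if is_sigma2:
        current = var.sigma2

        def objective(v):
            return _safe_nll(replace(params, var=var.with_sigma2(v)), data)

        lo_default = 1e-12 * (1.0 + float(np.var(data.y)))
    else:
        current = var.theta[j]

        def objective(v):
            return _safe_nll(replace(params, var=var.with_theta_entry(j, v)), data)

        lo_default = 0.0 if var.diag_param_mask()[j] else None

    scale = max(abs(current), 1.0)
    if bounds is not None:
        lo, hi = bounds
    elif lo_default is None:  # unconstrained off-diagonal entry
        lo, hi = current - 4.0 * scale, current + 4.0 * scale
    else:
        lo, hi = lo_default, max(4.0 * scale, current + 4.0 * scale)

    for _ in range(12):
        res = minimize_scalar(
            objective, bounds=(lo, hi), method="bounded",
            options={"xatol": xatol},
        )
        x = float(res.x)
        width = hi - lo
        at_hi = hi - x < 2.0 * xatol
        at_lo = lo_default is None and x - lo < 2.0 * xatol
        if not (at_hi or at_lo):
            # never move uphill: keep the incumbent if it is already at
            # least as good (bounded Brent stops within xatol of the min)
            if lo <= current <= hi and objective(current) <= res.fun:
                return current
            return x
        if width > 1e8 * scale:
            raise RuntimeError(
                f"variance-parameter bracket failed to contain minimizer "
                f"(index {j}, bracket ({lo}, {hi}))"
            )
        if at_hi:
            hi = lo + 4.0 * width
        if at_lo:
            lo = hi - 4.0 * width
    raise RuntimeError(f"variance-parameter update did not settle (index {j})")


def _plain_penalized_ls(
    data: ClusteredData, spec: PenaltySpec, beta0: np.ndarray,
    max_sweeps: int = 200, tol: float = 1e-8,
) -> np.ndarray:
    """Penalized least squares ignoring the cluster covariance (V = I).

    A cheap cyclic soft-threshold descent used only to initialize beta:
    starting the mixed-model solve from the residual scale of an ordinary
    sparse fit keeps the initial sigma2 (and hence the coordinate
    curvatures) on the scale the lam grid addresses.
    """
    X, y = data.X, data.y
    beta = beta0.copy()
    r = y - X @ beta
    pen = data.penalized_mask()
    col_ss = np.einsum("ij,ij->j", X, X)
    scale = max(1.0, float(np.max(np.abs(beta), initial=1.0)))
    lasso = PenaltySpec("lasso", spec.lam)
    for _ in range(max_sweeps):
        delta = 0.0
        for j in range(data.n_fixed):
            h = col_ss[j]
            if h <= 0:
                continue
            g = -float(X[:, j] @ r)
            d = univariate_update(g, h, beta[j], lasso,
                                  is_penalized=bool(pen[j]))
            if d != 0.0:
                beta[j] += d
                r -= d * X[:, j]
                delta = max(delta, abs(d))
        if delta < tol * scale:
            break
    return beta


def _default_init(
    data: ClusteredData, structure: str, spec: PenaltySpec
) -> ModelParams:
    """Interior start: least squares on the unpenalized columns, penalized
    coefficients from an ordinary (independence working covariance) sparse
    fit at the same lam, and the residual variance split evenly between
    the random effects and the error."""
    p, q = data.n_fixed, data.n_random
    beta = np.zeros(p)
    nonpen = sorted(data.nonpen)
    if nonpen:
        Xn = data.X[:, nonpen]
        coef, *_ = np.linalg.lstsq(Xn, data.y, rcond=None)
        beta[nonpen] = coef
    beta = _plain_penalized_ls(data, spec, beta)
    resid = data.y - data.X @ beta
    v = float(np.var(resid))
    v = max(v, 1e-8)
    half = v / 2.0
    qs = n_var_params(structure, q)
    theta = np.zeros(qs)
    if structure == "scalar":
        theta[0] = np.sqrt(half)
    elif structure == "diagonal":
        theta[:] = np.sqrt(half)
    else:
        # diagonal entries of L in column-major lower-triangle storage
        pos = 0
        for c in range(q):
            theta[pos] = np.sqrt(half)
            pos += q - c
    return ModelParams(beta=beta, var=VarParams(structure, theta, half, q))


def fit_once(
    data: ClusteredData,
    spec: PenaltySpec,
    cov_structure: str = "scalar",
    init: ModelParams | None = None,
    control: SolverControl | None = None,
) -> FitResult:
    """Run coordinate descent to a stationary point at one lam."""
    control = control or SolverControl()
    params = init if init is not None else _default_init(data, cov_structure, spec)
    if params.var.structure != cov_structure:
        raise ValueError("init covariance structure does not match cov_structure")
    sigma2_floor = (
        control.sigma2_floor
        if control.sigma2_floor is not None
        else 1e-4 * float(np.var(data.y))
    )
    pen_mask = data.penalized_mask()
    N, p = data.X.shape
    qs = params.var.n_params
    nonpen_sorted = sorted(data.nonpen)

    beta = params.beta.copy()
    var = params.var
    cache = LikelihoodCache(data, ModelParams(beta, var))
    obj = cache.neg_loglik() + penalty_total(beta, pen_mask, spec)
    history = []
    force_full = False
    converged = False
    diverged = False
    n_iter = 0

    for k in range(1, control.max_iter + 1):
        n_iter = k
        prev_params = ModelParams(beta.copy(), var)
        prev_obj = obj
        full_sweep = (k % control.D == 0) or force_full
        force_full = False

        if full_sweep:
            J = range(p)
        else:
            active = np.flatnonzero(beta)
            J = sorted(set(active.tolist()) | set(nonpen_sorted))

        # (i) fixed-effect sweep with immediately refreshed residuals
        for j in J:
            g, h = cache.grad_hess(j)
            d = univariate_update(g, h, beta[j], spec, is_penalized=bool(pen_mask[j]))
            if d != 0.0:
                beta[j] += d
                cache.apply_beta_step(j, d)

        # (ii) variance sweep: theta entries in storage order, then sigma2
        params_now = ModelParams(beta, var)
        try:
            for j in range(qs):
                new_t = update_variance_param(j, params_now, data)
                var = var.with_theta_entry(j, new_t)
                params_now = ModelParams(beta, var)
            new_s2 = update_variance_param(qs, params_now, data)
            var = var.with_sigma2(new_s2)
            cache.refresh(ModelParams(beta, var))
            nll = cache.neg_loglik()
        except (np.linalg.LinAlgError, RuntimeError):
            diverged = True
            break

        obj = nll + penalty_total(beta, pen_mask, spec)
        nnz = int(np.count_nonzero(beta))
        history.append(
            {"iter": k, "full": full_sweep, "n_active": nnz,
             "objective": obj, "sigma2": var.sigma2}
        )
        if control.verbose:  # pragma: no cover
            print(f"iter {k:4d} full={full_sweep} nnz={nnz} obj={obj:.6f}")

        # interpolation-divergence detection: sigma2 driven under the floor
        # while the cluster-level fit interpolates. The conditional
        # residuals r - Z Psi Z' V^-1 r equal sigma2 * V^-1 r, so their
        # vanishing marks y = X beta + Z b_hat exactly.
        blup_resid = var.sigma2 * cache.Vinv_r
        blup_rss = float(blup_resid @ blup_resid)
        if var.sigma2 < sigma2_floor and (
            nnz >= N or blup_rss < sigma2_floor * N
        ):
            diverged = True
            break

        curr_params = ModelParams(beta.copy(), var)
        if convergence_check(prev_params, curr_params, prev_obj, obj, control):
            if full_sweep:
                converged = True
                break
            force_full = True

    if not converged and not diverged:
        warnings.warn(
            f"coordinate descent reached max_iter={control.max_iter} "
            "without converging",
            RuntimeWarning,
            stacklevel=2,
        )

    final = ModelParams(beta, var)
    loglik = -_safe_nll(final, data)
    objective = np.inf if diverged else -loglik + penalty_total(beta, pen_mask, spec)
    return FitResult(
        params=final,
        objective=objective,
        loglik=loglik,
        n_iter=n_iter,
        converged=converged,
        diverged_interpolating=diverged,
        lam=spec.lam,
        penalty=spec,
        active_history=history,
    )
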
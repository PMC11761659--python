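"""Marginal Gaussian likelihood of the linear mixed-effects model.

For cluster i with design (X_i, Z_i) the marginal covariance of y_i is

    V_i(theta, sigma2) = Z_i Psi_theta Z_i' + sigma2 * I,

where Psi_theta = L L' is parameterized through the entries theta of its
lower-triangular Cholesky factor L (diagonal entries constrained
nonnegative). Three covariance structures are supported: ``scalar``
(L = theta[0] * I, q* = 1), ``diagonal`` (q* = q) and ``unstructured``
(q* = q(q+1)/2, theta holding the lower triangle column-major).

The negative log-likelihood is assembled cluster by cluster from per-cluster
Cholesky factorizations; nothing N x N is ever formed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .data import ClusteredData

__all__ = [
    "VarParams",
    "ModelParams",
    "build_cluster_cov",
    "neg_log_likelihood",
    "coord_grad_hess",
    "LikelihoodCache",
]

_STRUCTURES = ("scalar", "diagonal", "unstructured")

_LOG2PI = np.log(2.0 * np.pi)


def n_var_params(structure: str, q: int) -> int:
    """Number of free Cholesky parameters q* for a covariance structure."""
    if structure == "scalar":
        return 1
    if structure == "diagonal":
        return q
    if structure == "unstructured":
        return q * (q + 1) // 2
    raise ValueError(f"unknown structure {structure!r}")


def tril_indices_colmajor(q: int) -> tuple[np.ndarray, np.ndarray]:
    """Lower-triangle (row, col) indices in column-major storage order."""
    cols, rows = [], []
    for c in range(q):
        for r in range(c, q):
            rows.append(r)
            cols.append(c)
    return np.array(rows), np.array(cols)


@dataclass(frozen=True)
class VarParams:
    """Variance components: Cholesky parameters of Psi and error variance."""

    structure: str
    theta: np.ndarray
    sigma2: float
    q: int

    def __post_init__(self):
        if self.structure not in _STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        theta = np.asarray(self.theta, dtype=float).ravel()
        expected = n_var_params(self.structure, self.q)
        if theta.shape[0] != expected:
            raise ValueError(
                f"theta has length {theta.shape[0]}, expected {expected} "
                f"for {self.structure} with q={self.q}"
            )
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "sigma2", float(self.sigma2))

    @property
    def n_params(self) -> int:
        """q*: number of free parameters in theta."""
        return self.theta.shape[0]

    def cholesky(self) -> np.ndarray:
        """The q x q lower-triangular factor L with Psi = L L'."""
        q = self.q
        L = np.zeros((q, q))
        if self.structure == "scalar":
            np.fill_diagonal(L, self.theta[0])
        elif self.structure == "diagonal":
            np.fill_diagonal(L, self.theta)
        else:
            r, c = tril_indices_colmajor(q)
            L[r, c] = self.theta
        return L

    def psi(self) -> np.ndarray:
        L = self.cholesky()
        return L @ L.T

    def diag_param_mask(self) -> np.ndarray:
        """True for theta entries on the diagonal of L (sign-constrained)."""
        if self.structure in ("scalar", "diagonal"):
            return np.ones(self.n_params, dtype=bool)
        r, c = tril_indices_colmajor(self.q)
        return r == c

    def with_theta_entry(self, j: int, value: float) -> "VarParams":
        theta = self.theta.copy()
        theta[j] = value
        return replace(self, theta=theta)

    def with_sigma2(self, value: float) -> "VarParams":
        return replace(self, sigma2=value)


@dataclass(frozen=True)
class ModelParams:
    """Full parameter vector phi = (beta, theta, sigma2)."""

    beta: np.ndarray
    var: VarParams

    def __post_init__(self):
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float).ravel())


class ClusterCov:
    """V_i = Z_i Psi Z_i' + sigma2 I with a Cholesky solve handle."""

    def __init__(self, Z_i: np.ndarray, var: VarParams):
        Z_i = np.atleast_2d(np.asarray(Z_i, dtype=float))
        if Z_i.shape[1] != var.q:
            raise ValueError(
                f"Z_i has {Z_i.shape[1]} columns, expected q={var.q}"
            )
        if var.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        L = var.cholesky()
        ZL = Z_i @ L
        V = ZL @ ZL.T
        V[np.diag_indices_from(V)] += var.sigma2
        self.matrix = V
        try:
            self._cf = cho_factor(V, lower=True)
        except LinAlgError as exc:  # pragma: no cover - sigma2>0 keeps V PD
            raise np.linalg.LinAlgError(f"V_i not positive definite: {exc}")

    def solve(self, b: np.ndarray) -> np.ndarray:
        """Solve V_i x = b."""
        return cho_solve(self._cf, b)

    @property
    def logdet(self) -> float:
        return 2.0 * float(np.sum(np.log(np.diag(self._cf[0]))))


def build_cluster_cov(Z_i: np.ndarray, var: VarParams) -> ClusterCov:
    """Per-cluster marginal covariance with factorization handle."""
    return ClusterCov(Z_i, var)


def neg_log_likelihood(params: ModelParams, data: ClusteredData) -> float:
    """-l(phi), assembled as a sum over clusters.

    Raises ``np.linalg.LinAlgError`` if some V_i is numerically singular
    (the interpolation signal when sigma2 -> 0); callers in the solver
    catch this and report divergence rather than crash.
    """
    r = data.y - data.X @ params.beta
    total = data.n_obs * _LOG2PI
    for idx in data.cluster_indices:
        cov = build_cluster_cov(data.Z[idx], params.var)
        ri = r[idx]
        total += cov.logdet + float(ri @ cov.solve(ri))
    return 0.5 * total


class LikelihoodCache:
    """Per-sweep cache of V^-1-solved quantities for coordinate descent.

    Holds, for the current variance parameters eta = (theta, sigma2):
    the per-cluster factorizations, the stacked solves V^-1 X and V^-1 r,
    the residual r = y - X beta, and the coordinate curvatures
    h_j = x_j' V^-1 x_j. Residual-dependent entries are refreshed
    incrementally after each beta_j update; any change to eta invalidates
    the whole cache (a fingerprint of eta is checked on access).
    """

    def __init__(self, data: ClusteredData, params: ModelParams):
        self.data = data
        self.refresh(params)

    @staticmethod
    def _eta_key(var: VarParams) -> tuple:
        return (var.structure, var.theta.tobytes(), var.sigma2)

    def refresh(self, params: ModelParams) -> None:
        """Full rebuild for the given parameters (O(sum n_i^3 + n_i^2 p))."""
        data = self.data
        self._key = self._eta_key(params.var)
        self.covs = [
            build_cluster_cov(data.Z[idx], params.var)
            for idx in data.cluster_indices
        ]
        N, p = data.X.shape
        self.Vinv_X = np.empty((N, p))
        for cov, idx in zip(self.covs, data.cluster_indices):
            self.Vinv_X[idx] = cov.solve(data.X[idx])
        self.hess = np.einsum("ij,ij->j", data.X, self.Vinv_X)
        self.logdet = sum(c.logdet for c in self.covs)
        self.set_beta(params.beta)

    def set_beta(self, beta: np.ndarray) -> None:
        """Recompute residual caches for a new beta under the cached eta."""
        data = self.data
        self.beta = np.asarray(beta, dtype=float).copy()
        self.resid = data.y - data.X @ self.beta
        self.Vinv_r = np.empty(data.n_obs)
        for cov, idx in zip(self.covs, data.cluster_indices):
            self.Vinv_r[idx] = cov.solve(self.resid[idx])

    def check(self, params: ModelParams) -> None:
        if self._key != self._eta_key(params.var) or not np.array_equal(
            self.beta, params.beta
        ):
            raise RuntimeError("stale likelihood cache: parameters changed")

    def grad_hess(self, j: int) -> tuple[float, float]:
        """(d/d beta_j, d^2/d beta_j^2) of -l at the cached parameters."""
        g = -float(self.Vinv_X[:, j] @ self.resid)
        return g, float(self.hess[j])

    def apply_beta_step(self, j: int, d: float) -> None:
        """Incremental residual refresh after beta_j <- beta_j + d."""
        if d == 0.0:
            return
        self.beta[j] += d
        self.resid -= d * self.data.X[:, j]
        self.Vinv_r -= d * self.Vinv_X[:, j]

    def neg_loglik(self) -> float:
        """-l at the cached parameters, from cached solves."""
        quad = float(self.resid @ self.Vinv_r)
        return 0.5 * (self.data.n_obs * _LOG2PI + self.logdet + quad)


def coord_grad_hess(
    j: int,
    params: ModelParams,
    data: ClusteredData,
    cache: LikelihoodCache,
) -> tuple[float, float]:
    """First and second partial derivatives of -l with respect to beta_j.

    ``cache`` must be consistent with ``params``; a stale cache raises.
    The curvature x_j' V^-1 x_j is strictly positive for sigma2 > 0 and
    x_j != 0.
    """
    cache.check(params)
    return cache.grad_hess(j)
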
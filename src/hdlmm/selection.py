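"""Regularization-path machinery: lam grids, BIC, and selection metrics.

The final model over a grid of lams is the non-diverged fit minimizing

    BIC_lam = -2 l(beta_hat, theta_hat, sigma2_hat) + df_hat * log N,

with df_hat the number of nonzero coefficients plus the q* variance
parameters (sigma2 is not counted). Grid bounds, when not supplied, are
bracketed empirically: the upper bound is a lam at which every penalized
coefficient is zeroed, the lower bound a lam at which the solver flags the
interpolation regime.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .data import ClusteredData
from .penalties import PenaltySpec
from .solver import FitResult, SolverControl, fit_once

__all__ = [
    "bic",
    "lambda_grid",
    "select_best",
    "selection_metrics",
    "fit_path",
    "PathResult",
    "SelectionReport",
]


def bic(fit: FitResult, data: ClusteredData) -> float:
    """BIC of a fit; +inf for a diverged (interpolating) fit."""
    if fit.diverged_interpolating:
        return np.inf
    df = fit.n_nonzero + fit.params.var.n_params
    return -2.0 * fit.loglik + df * np.log(data.n_obs)


@dataclass
class PathResult:
    """All fits over a lam grid plus the BIC-selected index."""

    fits: list
    lams: np.ndarray
    bic_values: np.ndarray
    best_index: int

    @property
    def best(self) -> FitResult:
        return self.fits[self.best_index]

    def to_frame(self):
        import pandas as pd

        rows = []
        for lam, f, b in zip(self.lams, self.fits, self.bic_values):
            status = (
                "diverged" if f.diverged_interpolating
                else ("converged" if f.converged else "max_iter")
            )
            rows.append(
                {
                    "lam": lam,
                    "bic": b,
                    "df": f.n_nonzero + f.params.var.n_params,
                    "loglik": f.loglik,
                    "sigma2": f.params.var.sigma2,
                    "n_nonzero": f.n_nonzero,
                    "status": status,
                }
            )
        return pd.DataFrame(rows)


def select_best(path: PathResult) -> FitResult:
    """BIC-argmin non-diverged fit; ties broken toward larger lam."""
    return path.fits[path.best_index]


def _choose_best(lams, fits, bics) -> int:
    ok = [i for i, f in enumerate(fits) if not f.diverged_interpolating]
    if not ok:
        raise RuntimeError(
            "every fit on the lam grid diverged to an interpolating solution; "
            "increase the upper end of the grid"
        )
    # argmin BIC; on ties prefer the larger lam (sparser solution)
    best = ok[0]
    for i in ok[1:]:
        if bics[i] < bics[best] or (bics[i] == bics[best] and lams[i] > lams[best]):
            best = i
    return best


def fit_path(
    data: ClusteredData,
    spec: PenaltySpec,
    lams,
    cov_structure: str = "scalar",
    control: SolverControl | None = None,
) -> PathResult:
    """Fit every lam on the grid independently and select by BIC."""
    lams = np.asarray(lams, dtype=float)
    fits = [
        fit_once(data, dc_replace(spec, lam=float(lam)), cov_structure,
                 control=control)
        for lam in lams
    ]
    bics = np.array([bic(f, data) for f in fits])
    best = _choose_best(lams, fits, bics)
    return PathResult(fits=fits, lams=lams, bic_values=bics, best_index=best)


def _all_penalized_zero(fit: FitResult, data: ClusteredData) -> bool:
    return not np.any(fit.params.beta[data.penalized_mask()])


def lambda_grid(
    data: ClusteredData,
    spec: PenaltySpec,
    n_points: int = 10,
    bounds: tuple[float, float] | None = None,
    cov_structure: str = "scalar",
    control: SolverControl | None = None,
    spacing: str = "log",
    lam_init: float = 1.0,
    max_probes: int = 40,
) -> np.ndarray:
    """A lam grid, either on explicit bounds or auto-bracketed by probing.

    Without explicit bounds: double lam from ``lam_init`` until the fit
    zeroes every penalized coefficient (upper bound), halve until the
    interpolation flag is raised (lower bound, only reachable when p > N),
    then log-space strictly inside (low, up].
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if bounds is not None:
        lo, hi = bounds
        if spacing == "linear":
            return np.linspace(lo, hi, n_points)
        return np.geomspace(lo, hi, n_points)

    probes = 0

    def probe(lam: float) -> FitResult:
        nonlocal probes
        probes += 1
        if probes > max_probes:
            raise RuntimeError(
                f"lam bracket search exceeded probe budget ({max_probes}); "
                "supply explicit bounds"
            )
        return fit_once(data, dc_replace(spec, lam=lam), cov_structure,
                        control=control)

    lam_up = lam_init
    while not _all_penalized_zero(probe(lam_up), data):
        lam_up *= 2.0
    lam_low = lam_up / 2.0
    if data.n_fixed > data.n_obs:
        while not probe(lam_low).diverged_interpolating:
            lam_low /= 2.0
            if lam_low < 1e-8 * lam_up:
                break
    else:
        lam_low = max(lam_up / 256.0, 1e-8 * lam_up)
    grid = np.geomspace(lam_low, lam_up, n_points + 1)[1:]
    return grid


@dataclass(frozen=True)
class SelectionReport:
    """Confusion summary of a sparse estimate against the generating truth."""

    fpr: float
    n_true_pos: int
    n_false_pos: int
    recovered_all: bool
    beta_hat: np.ndarray
    beta_true: np.ndarray


def selection_metrics(beta_hat, beta_true) -> SelectionReport:
    """False-positive rate and true-positive counts of the support estimate.

    FPR is the share of truly zero coefficients estimated nonzero;
    ``recovered_all`` flags perfect recall of the true support.
    """
    beta_hat = np.asarray(beta_hat, dtype=float).ravel()
    beta_true = np.asarray(beta_true, dtype=float).ravel()
    if beta_hat.shape != beta_true.shape:
        raise ValueError("beta_hat and beta_true must have equal length")
    true_zero = beta_true == 0
    hat_nonzero = beta_hat != 0
    n_fp = int(np.count_nonzero(true_zero & hat_nonzero))
    n_tp = int(np.count_nonzero(~true_zero & hat_nonzero))
    n_zero = int(np.count_nonzero(true_zero))
    fpr = n_fp / n_zero if n_zero else 0.0
    return SelectionReport(
        fpr=fpr,
        n_true_pos=n_tp,
        n_false_pos=n_fp,
        recovered_all=n_tp == int(np.count_nonzero(~true_zero)),
        beta_hat=beta_hat,
        beta_true=beta_true,
    )
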
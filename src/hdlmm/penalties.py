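"""LASSO and SCAD penalties and the exact univariate coordinate update.

The SCAD penalty is defined through its derivative

    P'(t) = lam                               for t <= lam
    P'(t) = max(0, a*lam - t) / (a - 1)       for t >  lam

(zero beyond a*lam), giving the piecewise value

    P(t) = lam * t                                   on [0, lam]
    P(t) = (2*a*lam*t - t^2 - lam^2) / (2*(a-1))     on (lam, a*lam]
    P(t) = lam^2 * (a + 1) / 2                       beyond a*lam.

The coordinate update minimizes the local quadratic surrogate

    s(d) = g*d + h*d^2/2 + P~(|beta_j + d|)

where (g, h) are the first two derivatives of the negative log-likelihood
in beta_j. For LASSO, P~ = P and the minimizer is the classical
soft-threshold step. For SCAD the surrogate uses the *adaptively rescaled*
penalty P~(|t|) = P(h*|t|): the minimizer is found exactly by enumerating
the stationary point of each quadratic piece (clipped to its region) plus
the region boundaries and zero. With h != 1 this rescaled update is not a
minimizer of the original objective, only of the rescaled surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PenaltySpec", "penalty_value", "penalty_deriv", "univariate_update"]


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty family with regularization strength lam and SCAD shape a."""

    family: str  # "lasso" | "scad"
    lam: float
    a: float = 3.7

    def __post_init__(self):
        family = self.family.lower()
        if family not in ("lasso", "scad"):
            raise ValueError(f"unknown penalty family {self.family!r}")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if family == "scad" and self.a <= 2:
            raise ValueError("SCAD shape parameter a must exceed 2")
        object.__setattr__(self, "family", family)
        object.__setattr__(self, "lam", float(self.lam))
        object.__setattr__(self, "a", float(self.a))


def penalty_value(t: float, spec: PenaltySpec) -> float:
    """P_lam(t) for t = |beta_j| >= 0."""
    if t < 0:
        raise ValueError("penalty argument must be nonnegative")
    lam, a = spec.lam, spec.a
    if spec.family == "lasso":
        return lam * t
    if t <= lam:
        return lam * t
    if t <= a * lam:
        return (2.0 * a * lam * t - t * t - lam * lam) / (2.0 * (a - 1.0))
    return lam * lam * (a + 1.0) / 2.0


def penalty_deriv(t: float, spec: PenaltySpec) -> float:
    """P'_lam(t) for t >= 0 (for LASSO, the subgradient magnitude lam)."""
    if t < 0:
        raise ValueError("penalty argument must be nonnegative")
    lam, a = spec.lam, spec.a
    if spec.family == "lasso":
        return lam
    if t <= lam:
        return lam
    return max(0.0, a * lam - t) / (a - 1.0)


def penalty_total(beta: np.ndarray, penalized: np.ndarray, spec: PenaltySpec) -> float:
    """Sum of P_lam(|beta_j|) over the penalized coordinates."""
    t = np.abs(np.asarray(beta, dtype=float)[penalized])
    lam, a = spec.lam, spec.a
    if spec.family == "lasso":
        return float(lam * t.sum())
    out = np.where(
        t <= lam,
        lam * t,
        np.where(
            t <= a * lam,
            (2.0 * a * lam * t - t * t - lam * lam) / (2.0 * (a - 1.0)),
            lam * lam * (a + 1.0) / 2.0,
        ),
    )
    return float(out.sum())


def _soft(z: float, thresh: float) -> float:
    return np.sign(z) * max(abs(z) - thresh, 0.0)


def univariate_update(
    grad: float,
    hess: float,
    beta_j: float,
    spec: PenaltySpec,
    is_penalized: bool = True,
) -> float:
    """Exact minimizer d* of the univariate coordinate surrogate.

    Returns the step d*; the new coefficient is beta_j + d*.
    """
    if hess <= 0:
        raise ValueError("hess must be strictly positive")
    if not np.isfinite(grad):
        raise ValueError("non-finite gradient")
    # m/h is the unpenalized Newton target for the new coefficient
    m = hess * beta_j - grad
    if not is_penalized or spec.lam == 0.0:
        return m / hess - beta_j
    if spec.family == "lasso":
        return _soft(m, spec.lam) / hess - beta_j
    return _scad_argmin(m, hess, spec) - beta_j


def _scad_argmin(m: float, h: float, spec: PenaltySpec) -> float:
    """argmin_t  h*t^2/2 - m*t + P_lam(h*|t|)  by candidate enumeration.

    The rescaled penalty is piecewise quadratic in u = h*|t| with breaks at
    lam and a*lam; candidates are the clipped stationary points of the three
    pieces, the region boundaries, and zero. Ties prefer smaller |t|.
    """
    lam, a = spec.lam, spec.a
    b1 = lam / h        # |t| at which h|t| = lam
    b2 = a * lam / h    # |t| at which h|t| = a*lam

    candidates = [0.0, b1, -b1, b2, -b2]
    # inner piece: penalty lam*h*|t|  -> soft threshold at lam*h... stationary
    # t = (m -/+ lam*h)/h, valid on its sign branch, clipped to |t| <= b1
    t_in = _soft(m, lam * h) / h
    candidates.append(np.clip(t_in, -b1, b1))
    # middle piece: penalty (2*a*lam*h|t| - h^2 t^2 - lam^2)/(2(a-1));
    # for t > 0 stationarity: t*(h - h^2/(a-1)) = m - a*lam*h/(a-1)
    denom = h * (a - 1.0) - h * h
    if denom != 0.0:
        t_mid_pos = (m * (a - 1.0) - a * lam * h) / denom
        t_mid_neg = (m * (a - 1.0) + a * lam * h) / denom
        candidates.append(min(max(t_mid_pos, b1), b2))
        candidates.append(max(min(t_mid_neg, -b1), -b2))
    # outer piece: penalty constant -> pure Newton target
    t_out = m / h
    if abs(t_out) >= b2:
        candidates.append(t_out)

    def surrogate(t: float) -> float:
        return 0.5 * h * t * t - m * t + penalty_value(h * abs(t), spec)

    best_t, best_val = 0.0, surrogate(0.0)
    for t in candidates:
        v = surrogate(t)
        # prefer strictly better values; on (near-)ties prefer smaller |t|
        if v < best_val - 1e-12 or (v <= best_val + 1e-12 and abs(t) < abs(best_t)):
            best_t, best_val = t, v
    return best_t
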
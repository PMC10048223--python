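"""Bayesian P-splines: B-spline bases and the locally adaptive random-walk prior.

The smooth term g(t) is expanded in H B-spline basis functions,
g(t) = sum_h xi_h B_h(t).  The coefficients follow a first-order random walk
xi_h = xi_{h-1} + v_h with heterogeneous increments v_h ~ N(0, tau2 / delta_h),
h = 2..H, and a flat prior on xi_1.  In matrix form the (improper) prior is

    p(xi | tau2, delta)  ~  exp( -xi' Q xi / (2 tau2) ),   Q = D' diag(delta) D,

with D the (H-1) x H first-difference matrix.  tau2 is the global smoothing
variance; the local weights delta_h allow the effective penalty to vary along
the curve, accommodating functions whose curvature changes across the domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "SplineConfig",
    "SplineState",
    "build_basis",
    "penalty_matrix",
    "difference_penalty",
    "log_prior_xi",
]


@dataclass(frozen=True)
class SplineConfig:
    """Basis layout: ``num_basis`` functions of a given degree over ``domain``."""

    num_basis: int = 20
    degree: int = 3
    domain: tuple[float, float] = (0.0, 1.0)
    knot_rule: str = "equidistant"

    def __post_init__(self) -> None:
        if self.num_basis < self.degree + 1:
            raise ValueError(
                f"num_basis={self.num_basis} incompatible with degree={self.degree}; "
                f"need at least degree + 1 basis functions"
            )
        if self.num_basis < 4:
            raise ValueError("num_basis must be >= 4")
        lo, hi = self.domain
        if not (hi > lo):
            raise ValueError(f"degenerate domain {self.domain}")
        if self.knot_rule not in ("equidistant", "quantile"):
            raise ValueError(f"unknown knot_rule {self.knot_rule!r}")

    def knot_vector(self, times: np.ndarray | None = None) -> np.ndarray:
        """Full (padded) knot vector; quantile rule requires the data times."""
        lo, hi = self.domain
        n_inner = self.num_basis - self.degree + 1  # including both boundaries
        if self.knot_rule == "equidistant" or times is None:
            inner = np.linspace(lo, hi, n_inner)
        else:
            qs = np.linspace(0.0, 1.0, n_inner)
            inner = np.quantile(np.clip(np.asarray(times, float), lo, hi), qs)
            inner[0], inner[-1] = lo, hi
            inner = np.maximum.accumulate(inner)
            # collapse ties that would create degenerate basis functions
            if np.any(np.diff(inner) <= 0):
                inner = np.linspace(lo, hi, n_inner)
        return np.r_[np.full(self.degree, lo), inner, np.full(self.degree, hi)]


@dataclass
class SplineState:
    """Coefficients and smoothing hyperparameters of the spline block."""

    xi: np.ndarray
    tau2: float
    delta: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=float)
        if self.delta is None:
            self.delta = np.ones(len(self.xi) - 1)
        self.delta = np.asarray(self.delta, dtype=float)
        if len(self.delta) != len(self.xi) - 1:
            raise ValueError("delta must have length H - 1")
        if not (self.tau2 > 0.0):
            raise ValueError("tau2 must be positive")
        if np.any(self.delta <= 0.0):
            raise ValueError("all local weights delta must be positive")


def build_basis(times, config: SplineConfig) -> np.ndarray:
    """Evaluate the B-spline design matrix (len(times) x H).

    Times outside the configured domain are clamped to the boundary with a
    warning.  Rows sum to one (partition of unity).
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if t.size == 0:
        raise ValueError("times must be nonempty")
    lo, hi = config.domain
    if np.any(t < lo) or np.any(t > hi):
        warnings.warn(
            "evaluation times outside the spline domain were clamped to the boundary",
            RuntimeWarning,
        )
        t = np.clip(t, lo, hi)
    knots = config.knot_vector(t)
    dm = BSpline.design_matrix(t, knots, config.degree, extrapolate=False)
    return np.asarray(dm.todense())


def penalty_matrix(delta) -> np.ndarray:
    """Random-walk penalty Q = D' diag(delta) D for local weights delta_2..delta_H."""
    delta = np.asarray(delta, dtype=float)
    if delta.ndim != 1 or delta.size < 1:
        raise ValueError("delta must be a vector of length H - 1 >= 1")
    if np.any(delta <= 0.0):
        raise ValueError("all penalty weights must be positive")
    h = delta.size + 1
    d = np.diff(np.eye(h), axis=0)  # (H-1) x H first-difference matrix
    return d.T @ (delta[:, None] * d)


def difference_penalty(xi, delta) -> float:
    """The quadratic form xi' Q xi = sum_h delta_h (xi_h - xi_{h-1})^2."""
    xi = np.asarray(xi, dtype=float)
    delta = np.asarray(delta, dtype=float)
    return float(np.sum(delta * np.diff(xi) ** 2))


def log_prior_xi(state: SplineState) -> float:
    """Log of the (partially improper) spline prior, up to its xi-free constant."""
    return -difference_penalty(state.xi, state.delta) / (2.0 * state.tau2)
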
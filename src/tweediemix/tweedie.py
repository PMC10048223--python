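"""Tweedie compound-Poisson distribution with power parameter 1 < p < 2.

A Tweedie variable with index ``p`` strictly between 1 and 2 is semicontinuous:
it places positive probability on the single point 0 and a continuous density
on the positive half-line.  It admits the stochastic representation

    Y = X_1 + ... + X_U,   U ~ Poisson(lam),   X_i ~ Gamma(shape, scale) iid,

so that ``Y = 0`` exactly when the latent count ``U`` is 0.  The mean
parameterization ``(mu, phi, p)`` with E(Y) = mu and Var(Y) = phi * mu**p is
linked bijectively to the compound parameterization ``(lam, shape, scale)``.

The normalizing constant of the marginal Tweedie density is an intractable
series; all model fitting in this package therefore works with the *augmented*
joint density of ``(Y, U)``, which is available in closed form.  The marginal
log-density is provided here only for testing and plotting, via adaptive
truncation of the series over ``u``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "TweedieParams",
    "NaturalParams",
    "AugmentedObservation",
    "to_natural",
    "to_mean",
    "sample",
    "sample_arrays",
    "joint_logpdf",
    "augmented_loglik",
    "marginal_logpdf",
]

#: terms whose log falls this far below the running maximum are negligible
_LOG_TOL = 37.0


@dataclass(frozen=True)
class TweedieParams:
    """Mean parameterization: mean ``mu``, dispersion ``phi``, power ``p``."""

    mu: float
    phi: float
    p: float

    def __post_init__(self) -> None:
        if not (self.mu > 0.0):
            raise ValueError(f"mu must be positive, got {self.mu}")
        if not (self.phi > 0.0):
            raise ValueError(f"phi must be positive, got {self.phi}")
        if not (1.0 < self.p < 2.0):
            raise ValueError(f"p must lie in the open interval (1, 2), got {self.p}")


@dataclass(frozen=True)
class NaturalParams:
    """Compound parameterization: Poisson rate ``lam``, gamma ``shape``/``scale``."""

    lam: float
    shape: float
    scale: float

    def __post_init__(self) -> None:
        for name in ("lam", "shape", "scale"):
            if not (getattr(self, name) > 0.0):
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


@dataclass(frozen=True)
class AugmentedObservation:
    """An outcome ``y`` together with its latent Poisson count ``u``.

    Consistency requires ``y = 0`` exactly when ``u = 0``.
    """

    y: float
    u: int

    def __post_init__(self) -> None:
        if self.y < 0.0:
            raise ValueError(f"y must be nonnegative, got {self.y}")
        if self.u < 0 or int(self.u) != self.u:
            raise ValueError(f"u must be a nonnegative integer, got {self.u}")

    @property
    def consistent(self) -> bool:
        return (self.y == 0.0) == (self.u == 0)


def to_natural(params: TweedieParams) -> NaturalParams:
    """Convert mean parameters to the compound (Poisson-gamma) parameters."""
    mu, phi, p = params.mu, params.phi, params.p
    lam = mu ** (2.0 - p) / (phi * (2.0 - p))
    shape = (2.0 - p) / (p - 1.0)
    scale = phi * (p - 1.0) * mu ** (p - 1.0)
    return NaturalParams(lam=lam, shape=shape, scale=scale)


def to_mean(nat: NaturalParams) -> TweedieParams:
    """Convert compound parameters back to the mean parameterization."""
    lam, shape, scale = nat.lam, nat.shape, nat.scale
    mu = lam * shape * scale
    p = (shape + 2.0) / (shape + 1.0)
    phi = lam ** (1.0 - p) * (shape * scale) ** (2.0 - p) / (2.0 - p)
    return TweedieParams(mu=mu, phi=phi, p=p)


def natural_arrays(mu: np.ndarray, phi: float, p: float):
    """Vectorized (lam, shape, scale) for a vector of means and common phi, p."""
    mu = np.asarray(mu, dtype=float)
    lam = mu ** (2.0 - p) / (phi * (2.0 - p))
    shape = (2.0 - p) / (p - 1.0)
    scale = phi * (p - 1.0) * mu ** (p - 1.0)
    return lam, shape, scale


def sample_arrays(mu, phi: float, p: float, rng: np.random.Generator):
    """Draw ``(y, u)`` arrays from Tw_p(mu, phi) via the compound representation."""
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    lam, shape, scale = natural_arrays(mu, phi, p)
    u = rng.poisson(lam)
    y = np.zeros_like(mu)
    pos = u > 0
    if np.any(pos):
        y[pos] = rng.gamma(u[pos] * shape, np.broadcast_to(scale, mu.shape)[pos])
    return y, u


def sample(params: TweedieParams, count: int, rng: np.random.Generator):
    """Draw ``count`` augmented observations from the compound representation."""
    if count < 1:
        raise ValueError("count must be >= 1")
    y, u = sample_arrays(np.full(count, params.mu), params.phi, params.p, rng)
    return [AugmentedObservation(y=float(yi), u=int(ui)) for yi, ui in zip(y, u)]


def joint_logpdf(obs: AugmentedObservation, nat: NaturalParams) -> float:
    """Log of the joint (density x mass) of (Y, U) at one augmented observation.

    Returns -inf for inconsistent pairs (positive y with u = 0, or y = 0 with
    u > 0); the zero pair contributes exp(-lam).
    """
    y, u = obs.y, obs.u
    lam, a, g = nat.lam, nat.shape, nat.scale
    if (y == 0.0) != (u == 0):
        return -math.inf
    if u == 0:
        return -lam
    ua = u * a
    return (
        (ua - 1.0) * math.log(y)
        - y / g
        - math.lgamma(ua)
        - ua * math.log(g)
        + u * math.log(lam)
        - math.lgamma(u + 1.0)
        - lam
    )


def augmented_loglik(y, u, mu, phi: float, p: float) -> np.ndarray:
    """Vectorized per-cell joint log-density of (y, u) given means ``mu``.

    Inconsistent cells receive -inf.  This is the workhorse of the sampler:
    every Metropolis target involving the outcome goes through it.
    """
    y = np.asarray(y, dtype=float)
    u = np.asarray(u)
    mu = np.asarray(mu, dtype=float)
    lam, a, g = natural_arrays(mu, phi, p)
    out = -lam
    pos = y > 0.0
    bad = pos != (u > 0)
    if np.any(pos):
        ua = u[pos] * a
        gp = g[pos] if g.ndim else g
        lamp = lam[pos] if lam.ndim else lam
        out = np.array(out, dtype=float, copy=True)
        out[pos] = (
            (ua - 1.0) * np.log(y[pos])
            - y[pos] / gp
            - gammaln(ua)
            - ua * np.log(gp)
            + u[pos] * np.log(lamp)
            - gammaln(u[pos] + 1.0)
            - lamp
        )
    else:
        out = np.array(out, dtype=float, copy=True)
    if np.any(bad):
        out[bad] = -np.inf
    return out


def marginal_logpdf(y: float, params: TweedieParams, max_terms: int = 10_000) -> float:
    """Marginal Tweedie log-density at ``y`` by summing the series over ``u``.

    The series is expanded adaptively: once past its (unimodal) peak, terms are
    added until they fall ~37 nats below the running maximum; if ``max_terms``
    is reached first a convergence warning is emitted.  Exists for testing and
    plotting only -- inference never evaluates the marginal density.
    """
    if y < 0.0:
        return -math.inf
    nat = to_natural(params)
    if y == 0.0:
        return -nat.lam
    lam, a, g = nat.lam, nat.shape, nat.scale
    # log term(u) = (u*a - 1) log y - y/g - lgamma(u*a) - u*a*log g
    #             + u log lam - lgamma(u+1) - lam
    const = -math.log(y) - y / g - lam
    logc = math.log(lam) + a * math.log(y / g)
    terms = []
    best = -math.inf
    converged = False
    for u in range(1, max_terms + 1):
        t = u * logc - math.lgamma(u * a) - math.lgamma(u + 1.0)
        terms.append(t)
        if t > best:
            best = t
        elif t < best - _LOG_TOL:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"marginal_logpdf series not converged after {max_terms} terms "
            f"(last term within {best - terms[-1]:.1f} nats of the maximum)",
            RuntimeWarning,
        )
    return const + logsumexp(np.asarray(terms))
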
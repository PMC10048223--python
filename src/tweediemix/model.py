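"""Partial linear mixed model core: containers, linear predictor, complete-data
log-likelihood.

Conditional on a subject-level random effect b_i, each visit's semicontinuous
outcome is Tweedie, Y_ij | b_i ~ Tw_p(mu_ij, phi), with

    log mu_ij = x_ij' beta + z_ij' b_i + g(t_ij),

a parametric fixed-effect part, a random-effect part with b_i ~ N_r(0, Sigma),
and a nonparametric time trend g represented by the P-spline of
:mod:`tweediemix.pspline`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from . import tweedie
from .pspline import SplineConfig, SplineState, build_basis

__all__ = [
    "FixedEffects",
    "RandomEffectsBlock",
    "DispersionBlock",
    "LongitudinalData",
    "linear_predictor",
    "eta_vector",
    "complete_loglik",
    "complete_loglik_grouped",
]

#: linear predictors are clipped to this magnitude before exponentiation
ETA_CLIP = 30.0

#: outcomes below this threshold are coerced to exact zeros on ingestion
ZERO_TOL = 1e-12


@dataclass(frozen=True)
class FixedEffects:
    beta: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be finite")


@dataclass
class RandomEffectsBlock:
    """Per-subject effects b (n x r) and their covariance Sigma (r x r, SPD)."""

    b: np.ndarray
    Sigma: np.ndarray

    def __post_init__(self) -> None:
        self.b = np.atleast_2d(np.asarray(self.b, dtype=float))
        self.Sigma = np.atleast_2d(np.asarray(self.Sigma, dtype=float))
        if self.Sigma.shape[0] != self.Sigma.shape[1]:
            raise ValueError("Sigma must be square")
        if not np.allclose(self.Sigma, self.Sigma.T):
            raise ValueError("Sigma must be symmetric")
        if np.any(np.linalg.eigvalsh(self.Sigma) <= 0.0):
            raise ValueError("Sigma must be positive definite")
        if self.b.shape[1] != self.Sigma.shape[0]:
            raise ValueError("b and Sigma dimensions disagree")


@dataclass(frozen=True)
class DispersionBlock:
    phi: float
    p: float

    def __post_init__(self) -> None:
        if not (self.phi > 0.0):
            raise ValueError("phi must be positive")
        if not (1.0 < self.p < 2.0):
            raise ValueError("p must lie in (1, 2)")


@dataclass
class LongitudinalData:
    """Long-format longitudinal data in flat arrays, one entry per visit.

    Rows must be grouped by subject and ordered by visit within subject
    (:meth:`validate` enforces this).  ``y`` and ``X`` hold complete values --
    either the truth (simulation), current imputations (during sampling), or
    arbitrary placeholders behind the masks.  ``y_missing`` / ``x_missing``
    flag which entries were unobserved; the first ``n_missing_covariates``
    columns of ``X`` are the missing-prone ones, in their declared order.
    """

    subject: np.ndarray          # (N,) subject codes 0..n-1
    visit: np.ndarray            # (N,) within-subject visit index 0..n_i-1
    t: np.ndarray                # (N,) spline covariate (time)
    y: np.ndarray                # (N,) nonnegative outcomes
    X: np.ndarray                # (N, q) fixed-effect covariates
    Z: np.ndarray                # (N, r) random-effect covariates
    y_missing: np.ndarray = field(default=None)  # type: ignore[assignment]
    x_missing: np.ndarray = field(default=None)  # type: ignore[assignment]
    u: np.ndarray = field(default=None)          # type: ignore[assignment]
    n_missing_covariates: int = 0
    covariate_names: list[str] | None = None
    subject_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.subject = np.asarray(self.subject, dtype=int)
        self.visit = np.asarray(self.visit, dtype=int)
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float).copy()
        self.y[np.abs(self.y) < ZERO_TOL] = 0.0
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if self.y_missing is None:
            self.y_missing = np.zeros(self.N, dtype=bool)
        if self.x_missing is None:
            self.x_missing = np.zeros((self.N, self.n_missing_covariates), dtype=bool)
        self.y_missing = np.asarray(self.y_missing, dtype=bool)
        self.x_missing = np.atleast_2d(np.asarray(self.x_missing, dtype=bool))
        if self.u is not None:
            self.u = np.asarray(self.u, dtype=int)
        self.validate()

    # ------------------------------------------------------------------ sizes
    @property
    def N(self) -> int:
        return self.y.shape[0]

    @property
    def n_subjects(self) -> int:
        return int(self.subject.max()) + 1 if self.N else 0

    @property
    def q(self) -> int:
        return self.X.shape[1]

    @property
    def r(self) -> int:
        return self.Z.shape[1]

    @property
    def m(self) -> int:
        return self.n_missing_covariates

    def validate(self) -> None:
        N = self.N
        for name in ("subject", "visit", "t", "y_missing"):
            if getattr(self, name).shape[0] != N:
                raise ValueError(f"{name} length does not match y")
        if self.X.shape[0] != N or self.Z.shape[0] != N:
            raise ValueError("X/Z row count does not match y")
        if self.x_missing.shape != (N, self.m) and self.m > 0:
            raise ValueError("x_missing must be (N, n_missing_covariates)")
        if self.m > self.q:
            raise ValueError("n_missing_covariates exceeds number of covariates")
        obs = ~self.y_missing
        if np.any(self.y[obs] < 0.0):
            raise ValueError("observed responses must be nonnegative")
        if N and np.any(np.diff(self.subject) < 0):
            raise ValueError("rows must be grouped by subject in increasing order")
        if self.u is not None:
            zero = self.y == 0.0
            if np.any((self.u == 0) != zero):
                raise ValueError("latent counts inconsistent with outcomes (y=0 <=> u=0)")

    # --------------------------------------------------------------- helpers
    def prev_index(self) -> np.ndarray:
        """Index of the previous visit of the same subject, or -1 at baseline."""
        idx = np.arange(self.N) - 1
        idx[np.r_[True, self.subject[1:] != self.subject[:-1]] if self.N else []] = -1
        return idx

    def next_index(self) -> np.ndarray:
        """Index of the next visit of the same subject, or -1 at the last visit."""
        idx = np.arange(self.N) + 1
        last = np.r_[self.subject[1:] != self.subject[:-1], True] if self.N else []
        idx[last] = -1
        return idx


def linear_predictor(x_ij, z_ij, b_i, t_ij, beta: FixedEffects,
                     state: SplineState, config: SplineConfig) -> float:
    """Scalar eta = x'beta + z'b + g(t), clipped to +-30 with a warning."""
    basis_row = build_basis([t_ij], config)[0]
    eta = (
        float(np.dot(np.atleast_1d(x_ij), beta.beta))
        + float(np.dot(np.atleast_1d(z_ij), np.atleast_1d(b_i)))
        + float(basis_row @ state.xi)
    )
    if abs(eta) > ETA_CLIP:
        warnings.warn("linear predictor clipped to +-30", RuntimeWarning)
        eta = float(np.clip(eta, -ETA_CLIP, ETA_CLIP))
    return eta


def eta_vector(data: LongitudinalData, beta, b, xi, basis: np.ndarray) -> np.ndarray:
    """Vectorized linear predictor for all cells, clipped to +-30."""
    beta = np.asarray(beta, dtype=float)
    b = np.atleast_2d(np.asarray(b, dtype=float))
    eta = data.X @ beta + np.sum(data.Z * b[data.subject], axis=1) + basis @ np.asarray(xi)
    return np.clip(eta, -ETA_CLIP, ETA_CLIP)


def _mvn_logpdf_rows(b: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    b = np.atleast_2d(b)
    Sigma = np.atleast_2d(Sigma)
    r = Sigma.shape[0]
    chol = np.linalg.cholesky(Sigma)
    sol = np.linalg.solve(chol, b.T)
    quad = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (r * np.log(2.0 * np.pi) + logdet + quad)


def complete_loglik(data: LongitudinalData, beta, b_block: RandomEffectsBlock,
                    dispersion: DispersionBlock, spline: SplineState,
                    config: SplineConfig, basis: np.ndarray | None = None) -> float:
    """Joint log-likelihood of (Y, U, b): augmented Tweedie terms plus the
    multivariate-normal random-effect terms.

    All missing y/x entries must already hold their current imputations and
    ``data.u`` must be consistent with ``data.y`` (else -inf).
    """
    if data.u is None:
        raise ValueError("complete_loglik requires latent counts data.u")
    beta = np.asarray(getattr(beta, "beta", beta), dtype=float)
    if basis is None:
        basis = build_basis(data.t, config)
    eta = eta_vector(data, beta, b_block.b, spline.xi, basis)
    mu = np.exp(eta)
    cells = tweedie.augmented_loglik(data.y, data.u, mu, dispersion.phi, dispersion.p)
    if np.any(np.isneginf(cells)):
        return -np.inf
    return float(np.sum(cells) + np.sum(_mvn_logpdf_rows(b_block.b, b_block.Sigma)))


def complete_loglik_grouped(data: LongitudinalData, beta, b_block: RandomEffectsBlock,
                            dispersion: DispersionBlock, spline: SplineState,
                            config: SplineConfig) -> float:
    """The same complete-data log-likelihood with its terms regrouped the way
    the model is usually displayed: a -sum mu^{2-p}/(phi(2-p)) deviance-like
    term over all cells, corrections over the positive cells, and the
    random-effect terms.  Kept as an independent code path; a regression test
    asserts equality with :func:`complete_loglik`.
    """
    if data.u is None:
        raise ValueError("requires latent counts data.u")
    phi, p = dispersion.phi, dispersion.p
    beta = np.asarray(getattr(beta, "beta", beta), dtype=float)
    basis = build_basis(data.t, config)
    eta = eta_vector(data, beta, b_block.b, spline.xi, basis)
    mu = np.exp(eta)
    y, u = data.y, data.u
    pos = y > 0.0
    if np.any(pos != (u > 0)):
        return -np.inf
    a = (2.0 - p) / (p - 1.0)
    ll = -np.sum(mu ** (2.0 - p)) / (phi * (2.0 - p))
    yp, up, mup = y[pos], u[pos], mu[pos]
    ll -= np.sum(
        yp / (phi * (p - 1.0) * mup ** (p - 1.0))
        + gammaln(up * a)
        + gammaln(up + 1.0)
        + np.log(yp)
    )
    ll += np.sum(
        up * a * (np.log(yp) - np.log(phi) - np.log(p - 1.0))
        - up * (np.log(phi) + np.log(2.0 - p))
    )
    ll += float(np.sum(_mvn_logpdf_rows(b_block.b, b_block.Sigma)))
    return float(ll)
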
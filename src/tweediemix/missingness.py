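"""Nonignorable (MNAR) selection models for responses and covariates, and the
sequential normal models for missing continuous covariates.

Two logistic selection variants are supported.  With r-indicators equal to 1
when a value is missing:

* variant ``A`` -- the response logit depends on the current and previous
  outcome, ``phi_y0 + phi_y1 y_ij + phi_y2 y_{i,j-1}``; the k-th covariate
  logit depends on covariates 1..k and on the preceding covariates' missing
  indicators.
* variant ``B`` -- the response logit depends on the current outcome and the
  missing-prone covariates, ``phi_y0 + phi_y1 y_ij + sum_k phi_{y,k+1} x_ijk``;
  the k-th covariate logit depends on covariates 1..k and on the outcome.

Because the logits involve possibly unobserved quantities (evaluated at their
current imputations during sampling), both mechanisms are nonignorable.

The joint law of the m missing-prone continuous covariates is factorized into
a sequence of one-dimensional normals: x_k given its predecessors x_1..x_{k-1}
and the fully observed tail x0 is N(alpha_k' w, sigma_k^2) with
w = (1, x_1, ..., x_{k-1}, x0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit as _expit

from .model import LongitudinalData

__all__ = [
    "MechanismSpec",
    "CovariateModel",
    "response_missing_logit",
    "covariate_missing_logit",
    "response_logits",
    "covariate_logits",
    "missing_loglik",
    "bernoulli_loglik",
    "covariate_logpdf",
    "sample_covariates",
    "generate_indicators",
]


@dataclass
class MechanismSpec:
    """Selection-model coefficients for one of the two mechanism variants.

    ``phi_y`` has length 3 under variant A and 2 + m under variant B;
    ``phi_x[k-1]`` has length 2k under variant A (intercept, x_1..x_k,
    r_x1..r_x{k-1}) and k + 2 under variant B (intercept, x_1..x_k, y).
    ``lag_baseline_zero`` sets the convention for the unavailable lag
    y_{i,0} at the first visit: substitute 0 (default) or drop the term
    (equivalent here, since dropping is the same as substituting 0).
    """

    variant: str
    phi_y: np.ndarray
    phi_x: list = field(default_factory=list)
    lag_baseline_zero: bool = True

    def __post_init__(self) -> None:
        if self.variant not in ("A", "B"):
            raise ValueError(f"variant must be 'A' or 'B', got {self.variant!r}")
        self.phi_y = np.asarray(self.phi_y, dtype=float)
        self.phi_x = [np.asarray(v, dtype=float) for v in self.phi_x]
        m = len(self.phi_x)
        if self.variant == "A":
            if self.phi_y.size != 3:
                raise ValueError("variant A response block needs 3 coefficients")
            for k, v in enumerate(self.phi_x, start=1):
                if v.size != 2 * k:
                    raise ValueError(
                        f"variant A covariate block {k} needs {2 * k} coefficients, got {v.size}"
                    )
        else:
            if self.phi_y.size != 2 + m:
                raise ValueError(f"variant B response block needs {2 + m} coefficients")
            for k, v in enumerate(self.phi_x, start=1):
                if v.size != k + 2:
                    raise ValueError(
                        f"variant B covariate block {k} needs {k + 2} coefficients, got {v.size}"
                    )

    @property
    def m(self) -> int:
        return len(self.phi_x)


@dataclass
class CovariateModel:
    """Sequential conditional-normal model for the m missing-prone covariates.

    ``alpha[k-1]`` are the regression coefficients of x_k on
    (1, x_1..x_{k-1}, x0) and ``sigma2[k-1]`` the residual variance.
    """

    alpha: list
    sigma2: np.ndarray
    m: int

    def __post_init__(self) -> None:
        self.alpha = [np.asarray(a, dtype=float) for a in self.alpha]
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if len(self.alpha) != self.m or self.sigma2.size != self.m:
            raise ValueError("alpha/sigma2 blocks must match m")
        if np.any(self.sigma2 <= 0.0):
            raise ValueError("all sigma2 must be positive")

    def design(self, k: int, X: np.ndarray, m: int | None = None) -> np.ndarray:
        """Design rows (1, x_1..x_{k-1}, x0) for covariate k (1-based)."""
        m = self.m if m is None else m
        X = np.atleast_2d(X)
        cols = [np.ones((X.shape[0], 1)), X[:, : k - 1], X[:, m:]]
        return np.hstack(cols)

    def mean(self, k: int, X: np.ndarray) -> np.ndarray:
        return self.design(k, X) @ self.alpha[k - 1]


# --------------------------------------------------------------------------
# selection-model linear predictors
# --------------------------------------------------------------------------

def response_logits(y, y_prev, X, spec: MechanismSpec) -> np.ndarray:
    """Vectorized response-selection logits for all cells."""
    y = np.asarray(y, dtype=float)
    f = spec.phi_y
    if spec.variant == "A":
        if y_prev is None:
            raise ValueError("variant A requires the lagged outcome")
        return f[0] + f[1] * y + f[2] * np.asarray(y_prev, dtype=float)
    X = np.atleast_2d(X)
    if X.shape[1] < spec.m:
        raise ValueError("variant B requires the missing-prone covariate columns")
    return f[0] + f[1] * y + X[:, : spec.m] @ f[2:]


def covariate_logits(k: int, X, r_x, y, spec: MechanismSpec) -> np.ndarray:
    """Vectorized selection logits for the k-th (1-based) missing-prone covariate."""
    if not (1 <= k <= spec.m):
        raise ValueError(f"k must be in 1..{spec.m}")
    f = spec.phi_x[k - 1]
    X = np.atleast_2d(X)
    v = f[0] + X[:, :k] @ f[1 : k + 1]
    if spec.variant == "A":
        if k > 1:
            if r_x is None:
                raise ValueError("variant A needs preceding missingness indicators")
            v = v + np.atleast_2d(r_x)[:, : k - 1].astype(float) @ f[k + 1 : 2 * k]
        return v
    if y is None:
        raise ValueError("variant B needs the outcome")
    return v + f[k + 1] * np.asarray(y, dtype=float)


def response_missing_logit(y_ij: float, y_prev: float | None, x_ij, spec: MechanismSpec) -> float:
    """Scalar convenience wrapper for a single cell's response-selection logit."""
    x = None if x_ij is None else np.atleast_2d(np.asarray(x_ij, dtype=float))
    yp = None if y_prev is None else np.asarray([y_prev])
    return float(response_logits(np.asarray([y_ij]), yp, x, spec)[0])


def covariate_missing_logit(x_ij, r_prev, y_ij, spec: MechanismSpec, k: int) -> float:
    """Scalar convenience wrapper for a single cell's covariate-selection logit."""
    X = np.atleast_2d(np.asarray(x_ij, dtype=float))
    r = None if r_prev is None else np.atleast_2d(np.asarray(r_prev, dtype=float))
    y = None if y_ij is None else np.asarray([y_ij], dtype=float)
    return float(covariate_logits(k, X, r, y, spec)[0])


def bernoulli_loglik(r, logits) -> np.ndarray:
    """Per-cell Bernoulli log-likelihood r*v - log(1 + e^v), numerically stable."""
    r = np.asarray(r, dtype=float)
    v = np.asarray(logits, dtype=float)
    return r * v - np.logaddexp(0.0, v)


def _lagged_y(data: LongitudinalData, spec: MechanismSpec) -> np.ndarray:
    prev = data.prev_index()
    ylag = np.where(prev >= 0, data.y[np.maximum(prev, 0)], 0.0)
    return ylag


def missing_loglik(data: LongitudinalData, spec: MechanismSpec) -> float:
    """Total selection-model log-likelihood of the observed missingness pattern,
    evaluated at the current (imputed) values of y and X."""
    ylag = _lagged_y(data, spec) if spec.variant == "A" else None
    v = response_logits(data.y, ylag, data.X, spec)
    total = float(np.sum(bernoulli_loglik(data.y_missing, v)))
    for k in range(1, spec.m + 1):
        vk = covariate_logits(k, data.X, data.x_missing, data.y, spec)
        total += float(np.sum(bernoulli_loglik(data.x_missing[:, k - 1], vk)))
    return total


# --------------------------------------------------------------------------
# covariate model
# --------------------------------------------------------------------------

def covariate_logpdf(x_ij, model: CovariateModel) -> float:
    """Joint log-density of one cell's covariate vector under the sequential
    normal factorization (the fully observed tail conditions but is not modelled)."""
    X = np.atleast_2d(np.asarray(x_ij, dtype=float))
    total = 0.0
    for k in range(1, model.m + 1):
        mu = model.mean(k, X)[0]
        s2 = model.sigma2[k - 1]
        resid = X[0, k - 1] - mu
        total += -0.5 * (np.log(2.0 * np.pi * s2) + resid**2 / s2)
    return float(total)


def sample_covariates(x0, model: CovariateModel, rng: np.random.Generator) -> np.ndarray:
    """Draw the m missing-prone covariates sequentially given the observed tail x0."""
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    x = np.zeros(model.m + x0.size)
    x[model.m:] = x0
    for k in range(1, model.m + 1):
        mu = model.mean(k, x[None, :])[0]
        x[k - 1] = rng.normal(mu, np.sqrt(model.sigma2[k - 1]))
    return x[: model.m]


# --------------------------------------------------------------------------
# indicator generation (simulation)
# --------------------------------------------------------------------------

def generate_indicators(data: LongitudinalData, spec: MechanismSpec,
                        rng: np.random.Generator):
    """Draw missingness masks for y and the m missing-prone covariates from the
    selection mechanism, given complete data.  Returns ``(r_y, r_x)``.

    Covariate indicators are drawn in their declared order so that variant A's
    dependence of r_{x,k} on the preceding indicators is honoured.
    """
    N = data.N
    ylag = _lagged_y(data, spec) if spec.variant == "A" else None
    r_y = rng.random(N) < _expit(response_logits(data.y, ylag, data.X, spec))
    r_x = np.zeros((N, spec.m), dtype=bool)
    for k in range(1, spec.m + 1):
        v = covariate_logits(k, data.X, r_x, data.y, spec)
        r_x[:, k - 1] = rng.random(N) < _expit(v)
    return r_y, r_x
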
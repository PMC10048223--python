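"""Hybrid Gibbs / Metropolis-Hastings sampler for the Tweedie compound-Poisson
partial linear mixed model with nonignorable missing responses and covariates.

The augmented posterior is sampled by iterating over blocks:

    latent counts U  ->  missing y and x (data augmentation)  ->  random
    effects b  ->  beta, spline coefficients xi, power p, dispersion phi
    (random-walk MH)  ->  Sigma (inverse-Wishart)  ->  tau2, delta (conjugate)
    ->  selection coefficients phi_y, phi_x (MH)  ->  covariate-model alpha,
    sigma2 (conjugate).

Latent counts at positive outcomes are drawn exactly by enumerating their
unimodal discrete conditional.  Missing outcomes are proposed jointly with
their count from the Tweedie model itself (independence MH), so the Tweedie
factors cancel and the acceptance ratio reduces to the selection-model
likelihood ratio; missing covariates use random-walk MH against the product of
the Tweedie term, the sequential covariate model and the selection model.
Metropolis step sizes follow Robbins-Monro adaptation toward a 0.35 acceptance
rate during burn-in and are frozen afterwards; the beta and phi blocks
additionally use an empirical-covariance (adaptive-Metropolis) proposal shape
learned during burn-in.

A flat direction couples the level of the spline to the mean of a random
intercept; an exact extra Gibbs move resamples that level shift from its
conditional, which keeps both blocks mixing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import invwishart

from . import missingness as miss
from . import tweedie
from .model import ETA_CLIP, LongitudinalData
from .pspline import SplineConfig, build_basis, difference_penalty

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "ChainState",
    "PosteriorSummary",
    "GibbsSampler",
    "run_chain",
]


# ==========================================================================
# configuration containers
# ==========================================================================

@dataclass
class PriorSpec:
    """Hyperparameters of all prior blocks.

    Normal priors: beta ~ N(beta0, A); selection blocks phi_y ~ N(phi_y0, B),
    phi_xk ~ N(phi_x0[k], C[k]); covariate-model alpha_k ~ N(alpha0[k], D[k]).
    Sigma ~ IW(rho0, R0).  tau2 ~ IG(a_tau, b_tau), delta_h ~ Gamma(a_delta,
    b_delta), sigma_xk^2 ~ IG(a_x[k], b_x[k]).  The power and dispersion get
    N(0, var) priors on logit(p - 1) and log(phi).
    """

    beta0: np.ndarray
    A: np.ndarray
    rho0: float
    R0: np.ndarray
    a_tau: float = 1.0
    b_tau: float = 0.005
    a_delta: float = 0.5
    b_delta: float = 0.5
    phi_y0: np.ndarray = None          # type: ignore[assignment]
    B: np.ndarray = None               # type: ignore[assignment]
    phi_x0: list = field(default_factory=list)
    C: list = field(default_factory=list)
    alpha0: list = field(default_factory=list)
    D: list = field(default_factory=list)
    a_x: np.ndarray = None             # type: ignore[assignment]
    b_x: np.ndarray = None             # type: ignore[assignment]
    var_logit_p: float = 10_000.0
    var_log_phi: float = 10_000.0

    def __post_init__(self) -> None:
        self.beta0 = np.asarray(self.beta0, dtype=float)
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.R0 = np.atleast_2d(np.asarray(self.R0, dtype=float))
        if self.phi_y0 is not None:
            self.phi_y0 = np.asarray(self.phi_y0, dtype=float)
            self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        self.phi_x0 = [np.asarray(v, dtype=float) for v in self.phi_x0]
        self.C = [np.atleast_2d(np.asarray(v, dtype=float)) for v in self.C]
        self.alpha0 = [np.asarray(v, dtype=float) for v in self.alpha0]
        self.D = [np.atleast_2d(np.asarray(v, dtype=float)) for v in self.D]
        if self.a_x is not None:
            self.a_x = np.atleast_1d(np.asarray(self.a_x, dtype=float))
            self.b_x = np.atleast_1d(np.asarray(self.b_x, dtype=float))
        for name, mat in (("A", self.A), ("R0", self.R0)):
            if np.any(np.linalg.eigvalsh(mat) <= 0):
                raise ValueError(f"prior covariance {name} must be SPD")
        for val, name in ((self.a_tau, "a_tau"), (self.b_tau, "b_tau"),
                          (self.a_delta, "a_delta"), (self.b_delta, "b_delta")):
            if val <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def vague(cls, q: int, r: int, m: int, variant: str = "A",
              scale: float = 100.0) -> "PriorSpec":
        """Weakly informative priors sized for a dataset's dimensions."""
        phi_y_len = 3 if variant == "A" else 2 + m
        phi_x_len = [2 * k if variant == "A" else k + 2 for k in range(1, m + 1)]
        alpha_len = [k + q - m for k in range(1, m + 1)]
        return cls(
            beta0=np.zeros(q), A=scale * np.eye(q),
            rho0=r + 2.0, R0=np.eye(r),
            phi_y0=np.zeros(phi_y_len), B=scale * np.eye(phi_y_len),
            phi_x0=[np.zeros(l) for l in phi_x_len],
            C=[scale * np.eye(l) for l in phi_x_len],
            alpha0=[np.zeros(l) for l in alpha_len],
            D=[scale * np.eye(l) for l in alpha_len],
            a_x=np.full(m, 0.01), b_x=np.full(m, 0.01),
        )


@dataclass
class MCMCConfig:
    iterations: int = 5000        # retained draws
    burnin: int = 5000
    thin: int = 1
    seed: int = 0
    target_accept: float = 0.35
    adapt: bool = True
    u_cap: int = 20_000
    u_tail_tol: float = 1e-10


@dataclass
class ChainState:
    """Snapshot of every parameter block and latent quantity."""

    beta: np.ndarray
    p: float
    phi: float
    Sigma: np.ndarray
    xi: np.ndarray
    tau2: float
    delta: np.ndarray
    phi_y: np.ndarray
    phi_x: list
    alpha: list
    sigma2: np.ndarray
    b: np.ndarray
    u: np.ndarray
    y: np.ndarray
    X: np.ndarray
    iteration: int


class PosteriorSummary:
    """Retained draws plus posterior means/SDs (draw averages, sample SDs)."""

    def __init__(self, names, draws, xi_draws, acceptance, spline_config, config):
        self.names = list(names)
        self.draws = np.asarray(draws)
        self.xi_draws = np.asarray(xi_draws)
        self.acceptance = dict(acceptance)
        self.spline_config = spline_config
        self.config = config
        self._idx = {n: i for i, n in enumerate(self.names)}

    def draws_for(self, name: str) -> np.ndarray:
        return self.draws[:, self._idx[name]]

    def mean(self, name: str) -> float:
        return float(np.mean(self.draws_for(name)))

    def sd(self, name: str) -> float:
        return float(np.std(self.draws_for(name), ddof=1))

    def means(self) -> pd.Series:
        return pd.Series(self.draws.mean(axis=0), index=self.names)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.names,
            "mean": self.draws.mean(axis=0),
            "sd": self.draws.std(axis=0, ddof=1),
        })

    def curve(self, grid, level: float = 0.95) -> pd.DataFrame:
        """Pointwise posterior mean and central credible band of g over a grid."""
        grid = np.asarray(grid, dtype=float)
        lo, hi = self.spline_config.domain
        if np.any(grid < lo) or np.any(grid > hi):
            warnings.warn("curve grid clamped to the fitted domain", RuntimeWarning)
            grid = np.clip(grid, lo, hi)
        basis = build_basis(grid, self.spline_config)
        vals = self.xi_draws @ basis.T  # (L, G)
        a = 0.5 * (1.0 - level)
        return pd.DataFrame({
            "t": grid,
            "mean": vals.mean(axis=0),
            "lower": np.quantile(vals, a, axis=0),
            "upper": np.quantile(vals, 1.0 - a, axis=0),
        })


# ==========================================================================
# helpers
# ==========================================================================

def _chol_logpdf_factory(mean, cov):
    """Return f(x) = log N(x; mean, cov) with a precomputed factorization."""
    mean = np.asarray(mean, dtype=float)
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    L = np.linalg.cholesky(cov)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    d = mean.size
    const = -0.5 * (d * np.log(2.0 * np.pi) + logdet)

    def logpdf(x):
        z = np.linalg.solve(L, np.asarray(x, dtype=float) - mean)
        return const - 0.5 * float(z @ z)

    return logpdf


def _mvn_rows_logpdf(b, Sigma):
    b = np.atleast_2d(b)
    L = np.linalg.cholesky(np.atleast_2d(Sigma))
    sol = np.linalg.solve(L, b.T)
    quad = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (b.shape[1] * np.log(2.0 * np.pi) + logdet + quad)


class _BlockAdapter:
    """Robbins-Monro step-size + empirical-covariance proposal for one block."""

    def __init__(self, dim, target, init_log_step=-1.0):
        self.dim = dim
        self.target = target
        self.log_step = init_log_step
        self.count = 0
        self.mean = np.zeros(dim)
        self.M2 = np.zeros((dim, dim))
        self.L = np.eye(dim)

    def propose(self, rng):
        return np.exp(self.log_step) * (self.L @ rng.standard_normal(self.dim))

    def update(self, value, accepted, gamma):
        self.log_step = float(np.clip(self.log_step + gamma * (accepted - self.target), -10.0, 6.0))
        self.count += 1
        d = value - self.mean
        self.mean += d / self.count
        self.M2 += np.outer(d, value - self.mean)
        if self.count >= 100 and self.count % 100 == 0 and self.dim > 1:
            cov = self.M2 / (self.count - 1)
            try:
                self.L = np.linalg.cholesky(cov / max(np.mean(np.diag(cov)), 1e-12)
                                            + 1e-6 * np.eye(self.dim))
            except np.linalg.LinAlgError:
                pass


# ==========================================================================
# the engine
# ==========================================================================

class GibbsSampler:
    """MH-within-Gibbs engine bound to one dataset.

    The engine owns mutable copies of ``y``, ``X`` and ``u`` in which masked
    entries hold the current imputations.  Construct, then call :meth:`run`,
    or drive the individual ``update_*`` blocks directly (the unit tests do).
    """

    def __init__(self, data: LongitudinalData, priors: PriorSpec,
                 mechanism: miss.MechanismSpec | None,
                 spline_config: SplineConfig | None = None,
                 config: MCMCConfig | None = None):
        self.data = data
        self.priors = priors
        # the engine mutates the selection coefficients in place; work on a copy
        self.mech = None if mechanism is None else miss.MechanismSpec(
            variant=mechanism.variant,
            phi_y=mechanism.phi_y.copy(),
            phi_x=[v.copy() for v in mechanism.phi_x],
            lag_baseline_zero=mechanism.lag_baseline_zero,
        )
        self.spline_config = spline_config or SplineConfig()
        self.config = config or MCMCConfig()
        self.rng = np.random.default_rng(self.config.seed)

        self.N, self.q, self.r, self.m = data.N, data.q, data.r, data.m
        self.n = data.n_subjects
        self.subject = data.subject
        H = self.spline_config.num_basis
        self.H = H
        self.basis = (build_basis(data.t, self.spline_config)
                      if self.N else np.zeros((0, H)))
        self._support = [np.flatnonzero(self.basis[:, h]) for h in range(H)]
        self._prev = data.prev_index()
        self._next = data.next_index()

        self.miss_y_idx = np.flatnonzero(data.y_missing)
        self.miss_x_idx = [np.flatnonzero(data.x_missing[:, k]) for k in range(self.m)]
        # variant A couples a missing y to the next visit's selection logit
        # through the lag term, so adjacent missing cells cannot be updated
        # simultaneously; split by visit parity.
        if mechanism is not None and mechanism.variant == "A":
            par = data.visit[self.miss_y_idx] % 2
            self._y_groups = [self.miss_y_idx[par == 0], self.miss_y_idx[par == 1]]
        else:
            self._y_groups = [self.miss_y_idx]

        self._init_state()
        self._init_adaptation()
        self._prior_logpdfs()
        self.acceptance: dict[str, list] = {}
        self.iteration = 0
        self._adapting = True

    # ------------------------------------------------------------ initial state
    def _init_state(self) -> None:
        d, pri = self.data, self.priors
        self.beta = pri.beta0.astype(float).copy()
        self.theta_p = 0.0            # logit(p - 1): start at p = 1.5
        self.log_phi = 0.0            # start at phi = 1
        self.Sigma = pri.R0 / (pri.rho0 + self.r + 1.0)
        self.xi = np.zeros(self.H)
        self.tau2 = 0.1
        self.delta = np.ones(self.H - 1)
        if self.mech is not None:
            self.phi_y = pri.phi_y0.copy()
            self.phi_x = [v.copy() for v in pri.phi_x0]
        self.alpha = [v.copy() for v in pri.alpha0]
        self.sigma2 = np.ones(self.m)
        self.b = np.zeros((self.n, self.r))

        self.y = d.y.copy()
        self.X = d.X.copy()
        self.u = np.zeros(self.N, dtype=np.int64)
        # initial covariate imputations: observed column means
        for k in range(self.m):
            idx = self.miss_x_idx[k]
            if idx.size:
                obs = ~d.x_missing[:, k]
                fill = float(np.mean(self.X[obs, k])) if np.any(obs) else 0.0
                self.X[idx, k] = fill
        self._refresh_eta()
        # initial response imputations drawn from the current model
        if self.miss_y_idx.size:
            mu = self._mu(self.miss_y_idx)
            ynew, unew = tweedie.sample_arrays(mu, self.phi, self.p, self.rng)
            self.y[self.miss_y_idx] = ynew
            self.u[self.miss_y_idx] = unew
        if self.N:
            self.update_latent_u()

    def _init_adaptation(self) -> None:
        t = self.config.target_accept
        self._ad_beta = _BlockAdapter(self.q, t, init_log_step=np.log(0.1))
        self._ad_p = _BlockAdapter(1, t, init_log_step=np.log(0.1))
        self._ad_phi = _BlockAdapter(1, t, init_log_step=np.log(0.1))
        if self.mech is not None:
            self._ad_phiy = _BlockAdapter(self.phi_y.size, t, init_log_step=np.log(0.1))
            self._ad_phix = [_BlockAdapter(v.size, t, init_log_step=np.log(0.1))
                             for v in self.phi_x]
        self._ls_xi = np.full(self.H, np.log(0.5))
        self._ls_b = np.full(self.n, np.log(0.5))
        self._ls_x = [np.full(idx.size, np.log(0.5)) for idx in self.miss_x_idx]

    def _prior_logpdfs(self) -> None:
        pri = self.priors
        self._lp_beta = _chol_logpdf_factory(pri.beta0, pri.A)
        if self.mech is not None:
            self._lp_phiy = _chol_logpdf_factory(pri.phi_y0, pri.B)
            self._lp_phix = [_chol_logpdf_factory(m0, c)
                             for m0, c in zip(pri.phi_x0, pri.C)]
        self._D_inv = [np.linalg.inv(Dk) for Dk in pri.D]

    # ------------------------------------------------------------ conveniences
    @property
    def p(self) -> float:
        return 1.0 + 1.0 / (1.0 + np.exp(-self.theta_p))

    @property
    def phi(self) -> float:
        return float(np.exp(self.log_phi))

    def _refresh_eta(self) -> None:
        self.eta_x = self.X @ self.beta
        self.eta_b = np.sum(self.data.Z * self.b[self.subject], axis=1) if self.N else np.zeros(0)
        self.eta_g = self.basis @ self.xi

    def _eta(self, idx=None) -> np.ndarray:
        if idx is None:
            e = self.eta_x + self.eta_b + self.eta_g
        else:
            e = self.eta_x[idx] + self.eta_b[idx] + self.eta_g[idx]
        return np.clip(e, -ETA_CLIP, ETA_CLIP)

    def _mu(self, idx=None) -> np.ndarray:
        return np.exp(self._eta(idx))

    def _cells_ll(self, idx=None, y=None, u=None, mu=None) -> np.ndarray:
        if y is None:
            y = self.y if idx is None else self.y[idx]
        if u is None:
            u = self.u if idx is None else self.u[idx]
        if mu is None:
            mu = self._mu(idx)
        return tweedie.augmented_loglik(y, u, mu, self.phi, self.p)

    def _eta_ll(self, eta: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Per-cell log-likelihood terms that depend on eta when (y, u) are
        held fixed.  In the augmented density the count terms
        u log lam - u*shape*log scale lose their eta dependence because
        u*shape*(p-1) = u*(2-p), leaving only the deviance-like part
        -e^{(2-p)eta}/(phi(2-p)) - y e^{-(p-1)eta}/(phi(p-1))."""
        p, phi = self.p, self.phi
        out = -np.exp((2.0 - p) * eta) / (phi * (2.0 - p))
        pos = y > 0.0
        if np.any(pos):
            out[pos] -= y[pos] * np.exp(-(p - 1.0) * eta[pos]) / (phi * (p - 1.0))
        return out

    def _tweedie_total(self, mu=None, phi=None, p=None) -> float:
        phi = self.phi if phi is None else phi
        p = self.p if p is None else p
        if mu is None:
            mu = self._mu()
        return float(np.sum(tweedie.augmented_loglik(self.y, self.u, mu, phi, p)))

    def _gamma_t(self) -> float:
        return 1.0 / (10.0 + self.iteration) ** 0.6

    def _track(self, name: str, rate: float) -> None:
        if not self._adapting:
            self.acceptance.setdefault(name, []).append(rate)

    def state(self) -> ChainState:
        return ChainState(
            beta=self.beta.copy(), p=self.p, phi=self.phi, Sigma=self.Sigma.copy(),
            xi=self.xi.copy(), tau2=self.tau2, delta=self.delta.copy(),
            phi_y=(self.phi_y.copy() if self.mech is not None else None),
            phi_x=([v.copy() for v in self.phi_x] if self.mech is not None else None),
            alpha=[v.copy() for v in self.alpha], sigma2=self.sigma2.copy(),
            b=self.b.copy(), u=self.u.copy(), y=self.y.copy(), X=self.X.copy(),
            iteration=self.iteration,
        )

    # ====================================================== latent counts
    def update_latent_u(self) -> None:
        """Exact draw of each positive cell's latent count from its discrete
        conditional, by adaptive enumeration of the unimodal series."""
        pos = np.flatnonzero(self.y > 0.0)
        self.u[self.y == 0.0] = 0
        if pos.size == 0:
            return
        mu = self._mu(pos)
        lam, a, g = tweedie.natural_arrays(mu, self.phi, self.p)
        logc = np.log(lam) + a * np.log(self.y[pos] / g)
        log_mode = (np.max(logc) - a * np.log(a)) / (1.0 + a)
        cap = int(np.clip(3.0 * np.exp(min(log_mode, 15.0)) + 20.0, 20, 2000))
        while True:
            us = np.arange(1, cap + 1)
            const = gammaln(us + 1.0) + gammaln(us * a)
            M = np.outer(logc, us) - const[None, :]
            tail = np.max(M[:, -1] - np.max(M, axis=1))
            if tail < np.log(self.config.u_tail_tol) or cap >= self.config.u_cap:
                break
            cap = min(cap * 2, self.config.u_cap)
        if tail >= np.log(self.config.u_tail_tol):
            warnings.warn(
                f"latent-count enumeration truncated at {cap} with tail mass "
                f"ratio exp({tail:.1f})", RuntimeWarning)
        gum = self.rng.gumbel(size=M.shape)
        self.u[pos] = 1 + np.argmax(M + gum, axis=1)

    # ====================================================== missing values
    def _sel_terms_for_y(self, idx: np.ndarray, yvals: np.ndarray) -> np.ndarray:
        """Selection-model log-likelihood terms that involve y at cells idx,
        evaluated with those cells' outcome replaced by ``yvals``."""
        d, mech = self.data, self.mech
        f = mech.phi_y
        out = np.zeros(idx.size)
        if mech.variant == "A":
            prev = self._prev[idx]
            ylag = np.where(prev >= 0, self.y[np.maximum(prev, 0)], 0.0)
            v = f[0] + f[1] * yvals + f[2] * ylag
            out += miss.bernoulli_loglik(d.y_missing[idx], v)
            nxt = self._next[idx]
            has_next = nxt >= 0
            if np.any(has_next):
                j = nxt[has_next]
                v2 = f[0] + f[1] * self.y[j] + f[2] * yvals[has_next]
                out[has_next] += miss.bernoulli_loglik(d.y_missing[j], v2)
        else:
            Xm = self.X[idx, : self.m]
            v = f[0] + f[1] * yvals + Xm @ f[2:]
            out += miss.bernoulli_loglik(d.y_missing[idx], v)
            for k in range(1, self.m + 1):
                fk = mech.phi_x[k - 1]
                vk = fk[0] + self.X[idx, :k] @ fk[1 : k + 1] + fk[k + 1] * yvals
                out += miss.bernoulli_loglik(d.x_missing[idx, k - 1], vk)
        return out

    def update_missing_y(self) -> None:
        """Independence MH for missing outcomes: propose (y*, u*) from the
        Tweedie model at the current mean, accept on the selection-model
        likelihood ratio (the Tweedie factors cancel exactly)."""
        if self.mech is None or self.miss_y_idx.size == 0:
            return
        for idx in self._y_groups:
            if idx.size == 0:
                continue
            mu = self._mu(idx)
            ynew, unew = tweedie.sample_arrays(mu, self.phi, self.p, self.rng)
            delta = self._sel_terms_for_y(idx, ynew) - self._sel_terms_for_y(idx, self.y[idx])
            acc = np.log(self.rng.random(idx.size)) < delta
            self.y[idx[acc]] = ynew[acc]
            self.u[idx[acc]] = unew[acc]

    def _cov_model_terms_for_x(self, idx: np.ndarray, k: int, xvals: np.ndarray) -> np.ndarray:
        """Sequential covariate-model log-density terms involving x_k at cells
        idx, with that column replaced by ``xvals``."""
        out = np.zeros(idx.size)
        Xs = self.X[idx].copy()
        Xs[:, k] = xvals
        model = miss.CovariateModel(alpha=self.alpha, sigma2=self.sigma2, m=self.m)
        for l in range(k, self.m):  # own density (l = k) and successors' means
            muk = model.mean(l + 1, Xs)
            s2 = self.sigma2[l]
            out -= 0.5 * (Xs[:, l] - muk) ** 2 / s2
        return out

    def _sel_terms_for_x(self, idx: np.ndarray, k: int, xvals: np.ndarray) -> np.ndarray:
        """Selection-model terms involving covariate k (0-based) at cells idx."""
        d, mech = self.data, self.mech
        out = np.zeros(idx.size)
        Xs = self.X[idx].copy()
        Xs[:, k] = xvals
        if mech.variant == "B":
            f = mech.phi_y
            v = f[0] + f[1] * self.y[idx] + Xs[:, : self.m] @ f[2:]
            out += miss.bernoulli_loglik(d.y_missing[idx], v)
        for l in range(k, self.m):  # covariate logits l+1 involve x_{k+1} when l >= k
            fk = mech.phi_x[l]
            v = fk[0] + Xs[:, : l + 1] @ fk[1 : l + 2]
            if mech.variant == "A":
                if l > 0:
                    v = v + d.x_missing[idx, :l].astype(float) @ fk[l + 2 : 2 * l + 2]
            else:
                v = v + fk[l + 2] * self.y[idx]
            out += miss.bernoulli_loglik(d.x_missing[idx, l], v)
        return out

    def update_missing_x(self) -> None:
        """Random-walk MH for each missing covariate entry, targeting the
        Tweedie term x enters through the mean, the sequential covariate model,
        and the selection model."""
        if self.mech is None:
            return
        for k in range(self.m):
            idx = self.miss_x_idx[k]
            if idx.size == 0:
                continue
            step = np.exp(self._ls_x[k])
            xold = self.X[idx, k]
            xnew = xold + step * self.rng.standard_normal(idx.size)
            dx = xnew - xold
            eta_old = self._eta(idx)
            eta_new = np.clip(eta_old + self.beta[k] * dx, -ETA_CLIP, ETA_CLIP)
            yk = self.y[idx]
            delta = (self._eta_ll(eta_new, yk) - self._eta_ll(eta_old, yk)
                     + self._cov_model_terms_for_x(idx, k, xnew)
                     - self._cov_model_terms_for_x(idx, k, xold)
                     + self._sel_terms_for_x(idx, k, xnew)
                     - self._sel_terms_for_x(idx, k, xold))
            acc = np.log(self.rng.random(idx.size)) < delta
            if np.any(acc):
                self.X[idx[acc], k] = xnew[acc]
                self.eta_x[idx[acc]] += self.beta[k] * dx[acc]
            if self._adapting:
                self._ls_x[k] = np.clip(
                    self._ls_x[k] + self._gamma_t() * (acc.astype(float) - self.config.target_accept),
                    -10.0, 3.0)
            self._track(f"missing_x{k + 1}", float(np.mean(acc)))

    def update_missing_values(self) -> None:
        self.update_missing_y()
        self.update_missing_x()

    # ====================================================== random effects
    def update_random_effects(self) -> None:
        """Per-subject random-walk MH (subjects are conditionally independent,
        so all proposals are evaluated in one vectorized pass)."""
        if self.n == 0:
            return
        step = np.exp(self._ls_b)
        prop = self.b + step[:, None] * self.rng.standard_normal((self.n, self.r))
        eta_b_new = np.sum(self.data.Z * prop[self.subject], axis=1)
        eta_old = self._eta()
        eta_new = np.clip(self.eta_x + eta_b_new + self.eta_g, -ETA_CLIP, ETA_CLIP)
        diff = self._eta_ll(eta_new, self.y) - self._eta_ll(eta_old, self.y)
        per_subj = np.bincount(self.subject, weights=diff, minlength=self.n)
        per_subj += _mvn_rows_logpdf(prop, self.Sigma) - _mvn_rows_logpdf(self.b, self.Sigma)
        acc = np.log(self.rng.random(self.n)) < per_subj
        if np.any(acc):
            self.b[acc] = prop[acc]
            rows = acc[self.subject]
            self.eta_b[rows] = eta_b_new[rows]
        if self._adapting:
            self._ls_b = np.clip(
                self._ls_b + self._gamma_t() * (acc.astype(float) - self.config.target_accept),
                -10.0, 3.0)
        self._track("b", float(np.mean(acc)))
        self._level_swap()

    def _level_swap(self) -> None:
        """Exact Gibbs move along the flat direction (xi + c, b - c) available
        with a random intercept: c | rest ~ N(mean(b), Sigma / n)."""
        if self.n == 0 or self.r != 1 or not np.all(self.data.Z == 1.0):
            return
        s2 = float(self.Sigma[0, 0])
        c = self.rng.normal(float(np.mean(self.b)), np.sqrt(s2 / self.n))
        self.xi += c
        self.eta_g += c
        self.b -= c
        self.eta_b -= c

    # ====================================================== MH parameter blocks
    def update_beta(self) -> None:
        ad = self._ad_beta
        prop = self.beta + ad.propose(self.rng)
        eta_x_new = self.X @ prop
        eta_new = np.clip(eta_x_new + self.eta_b + self.eta_g, -ETA_CLIP, ETA_CLIP)
        delta = (float(np.sum(self._eta_ll(eta_new, self.y))
                       - np.sum(self._eta_ll(self._eta(), self.y)))
                 + self._lp_beta(prop) - self._lp_beta(self.beta))
        accepted = np.log(self.rng.random()) < delta
        if accepted:
            self.beta = prop
            self.eta_x = eta_x_new
        if self._adapting:
            ad.update(self.beta, float(accepted), self._gamma_t())
        self._track("beta", float(accepted))

    def update_xi(self) -> None:
        """Single-site random-walk sweep over the spline coefficients."""
        inv2tau = 1.0 / (2.0 * self.tau2)
        accs = np.zeros(self.H)
        for h in range(self.H):
            d = np.exp(self._ls_xi[h]) * self.rng.standard_normal()
            new = self.xi[h] + d
            pen_old = pen_new = 0.0
            if h > 0:
                pen_old += self.delta[h - 1] * (self.xi[h] - self.xi[h - 1]) ** 2
                pen_new += self.delta[h - 1] * (new - self.xi[h - 1]) ** 2
            if h < self.H - 1:
                pen_old += self.delta[h] * (self.xi[h + 1] - self.xi[h]) ** 2
                pen_new += self.delta[h] * (self.xi[h + 1] - new) ** 2
            delta_lp = -(pen_new - pen_old) * inv2tau
            rows = self._support[h]
            if rows.size:
                eta_old = self._eta(rows)
                eta_new = np.clip(eta_old + self.basis[rows, h] * d, -ETA_CLIP, ETA_CLIP)
                yr = self.y[rows]
                delta_lp += float(np.sum(self._eta_ll(eta_new, yr))
                                  - np.sum(self._eta_ll(eta_old, yr)))
            if np.log(self.rng.random()) < delta_lp:
                self.xi[h] = new
                if rows.size:
                    self.eta_g[rows] += self.basis[rows, h] * d
                accs[h] = 1.0
        if self._adapting:
            self._ls_xi = np.clip(
                self._ls_xi + self._gamma_t() * (accs - self.config.target_accept),
                -10.0, 3.0)
        self._track("xi", float(np.mean(accs)))

    def update_p(self) -> None:
        ad = self._ad_p
        prop = self.theta_p + float(ad.propose(self.rng)[0])
        p_new = 1.0 + 1.0 / (1.0 + np.exp(-prop))
        delta = (self._tweedie_total(p=p_new) - self._tweedie_total()
                 - 0.5 * prop**2 / self.priors.var_logit_p
                 + 0.5 * self.theta_p**2 / self.priors.var_logit_p)
        accepted = np.log(self.rng.random()) < delta
        if accepted:
            self.theta_p = prop
        if self._adapting:
            ad.update(np.asarray([self.theta_p]), float(accepted), self._gamma_t())
        self._track("p", float(accepted))

    def update_phi(self) -> None:
        ad = self._ad_phi
        prop = self.log_phi + float(ad.propose(self.rng)[0])
        delta = (self._tweedie_total(phi=float(np.exp(prop))) - self._tweedie_total()
                 - 0.5 * prop**2 / self.priors.var_log_phi
                 + 0.5 * self.log_phi**2 / self.priors.var_log_phi)
        accepted = np.log(self.rng.random()) < delta
        if accepted:
            self.log_phi = prop
        if self._adapting:
            ad.update(np.asarray([self.log_phi]), float(accepted), self._gamma_t())
        self._track("phi", float(accepted))

    def update_mh_blocks(self) -> None:
        self.update_beta()
        self.update_xi()
        self.update_p()
        self.update_phi()

    # ====================================================== conjugate blocks
    def update_Sigma(self) -> None:
        scale = self.priors.R0 + self.b.T @ self.b
        self.Sigma = np.atleast_2d(invwishart.rvs(
            df=self.priors.rho0 + self.n, scale=scale, random_state=self.rng))

    def update_tau_delta(self) -> None:
        pen = difference_penalty(self.xi, self.delta)
        shape = self.priors.a_tau + (self.H - 1) / 2.0
        rate = self.priors.b_tau + 0.5 * pen
        self.tau2 = 1.0 / self.rng.gamma(shape, 1.0 / rate)
        d2 = np.diff(self.xi) ** 2
        self.delta = self.rng.gamma(self.priors.a_delta + 0.5,
                                    1.0 / (self.priors.b_delta + d2 / (2.0 * self.tau2)))

    def update_alpha_sigma(self) -> None:
        """Conjugate Bayesian-linear-regression updates of the covariate-model
        blocks, evaluated on the fully imputed covariate matrix."""
        if self.m == 0:
            return
        model = miss.CovariateModel(alpha=self.alpha, sigma2=self.sigma2, m=self.m)
        for k in range(1, self.m + 1):
            W = model.design(k, self.X) if self.N else np.zeros((0, self.alpha[k - 1].size))
            target = self.X[:, k - 1] if self.N else np.zeros(0)
            s2 = self.sigma2[k - 1]
            Dinv = self._D_inv[k - 1]
            prec = W.T @ W / s2 + Dinv
            cov = np.linalg.inv(prec)
            cov = 0.5 * (cov + cov.T)
            mean = cov @ (W.T @ target / s2 + Dinv @ self.priors.alpha0[k - 1])
            L = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
            self.alpha[k - 1] = mean + L @ self.rng.standard_normal(mean.size)
            resid = target - W @ self.alpha[k - 1]
            shape = self.priors.a_x[k - 1] + 0.5 * self.N
            rate = self.priors.b_x[k - 1] + 0.5 * float(resid @ resid)
            # tiny shapes (near-improper priors with no data) can underflow to 0
            self.sigma2[k - 1] = 1.0 / max(self.rng.gamma(shape, 1.0 / rate), 1e-300)
            model.alpha[k - 1] = self.alpha[k - 1]
            model.sigma2[k - 1] = self.sigma2[k - 1]

    def update_conjugate_blocks(self) -> None:
        self.update_Sigma()
        self.update_tau_delta()
        self.update_alpha_sigma()

    # ====================================================== selection blocks
    def _phi_design_y(self):
        d = self.data
        if self.mech.variant == "A":
            prev = self._prev
            ylag = np.where(prev >= 0, self.y[np.maximum(prev, 0)], 0.0)
            return np.column_stack([np.ones(self.N), self.y, ylag])
        return np.column_stack([np.ones(self.N), self.y, self.X[:, : self.m]])

    def _phi_design_x(self, k: int):
        d = self.data
        cols = [np.ones(self.N), self.X[:, : k + 1]]
        if self.mech.variant == "A":
            if k > 0:
                cols.append(d.x_missing[:, :k].astype(float))
        else:
            cols.append(self.y)
        return np.column_stack(cols)

    def _mh_logistic(self, value, W, r, prior_lp, adapter, name):
        prop = value + adapter.propose(self.rng)
        ll_old = float(np.sum(miss.bernoulli_loglik(r, W @ value))) if self.N else 0.0
        ll_new = float(np.sum(miss.bernoulli_loglik(r, W @ prop))) if self.N else 0.0
        delta = ll_new - ll_old + prior_lp(prop) - prior_lp(value)
        accepted = np.log(self.rng.random()) < delta
        out = prop if accepted else value
        if self._adapting:
            adapter.update(out, float(accepted), self._gamma_t())
        self._track(name, float(accepted))
        return out

    def update_selection_blocks(self) -> None:
        if self.mech is None:
            return
        d = self.data
        W = self._phi_design_y() if self.N else np.zeros((0, self.phi_y.size))
        self.phi_y = self._mh_logistic(self.phi_y, W, d.y_missing.astype(float),
                                       self._lp_phiy, self._ad_phiy, "phi_y")
        self.mech.phi_y = self.phi_y
        for k in range(self.m):
            W = self._phi_design_x(k) if self.N else np.zeros((0, self.phi_x[k].size))
            self.phi_x[k] = self._mh_logistic(
                self.phi_x[k], W, d.x_missing[:, k].astype(float),
                self._lp_phix[k], self._ad_phix[k], f"phi_x{k + 1}")
            self.mech.phi_x[k] = self.phi_x[k]

    # ====================================================== main loop
    def _param_names(self) -> list[str]:
        names = [f"beta{i + 1}" for i in range(self.q)] + ["p", "phi"]
        if self.r == 1:
            names.append("Sigma")
        else:
            names += [f"Sigma_{i + 1}{j + 1}" for i in range(self.r) for j in range(i, self.r)]
        for k in range(self.m):
            names += [f"alpha{k + 1}{j}" for j in range(self.alpha[k].size)]
        if self.mech is not None:
            names += [f"phiy{j}" for j in range(self.phi_y.size)]
            for k in range(self.m):
                names += [f"phix{k + 1}{j}" for j in range(self.phi_x[k].size)]
        names += [f"sigma2_x{k + 1}" for k in range(self.m)]
        return names

    def _param_vector(self) -> np.ndarray:
        parts = [self.beta, [self.p, self.phi]]
        if self.r == 1:
            parts.append([self.Sigma[0, 0]])
        else:
            parts.append([self.Sigma[i, j] for i in range(self.r) for j in range(i, self.r)])
        parts += [a for a in self.alpha]
        if self.mech is not None:
            parts.append(self.phi_y)
            parts += [v for v in self.phi_x]
        parts.append(self.sigma2)
        return np.concatenate([np.atleast_1d(np.asarray(x, dtype=float)) for x in parts])

    def _check_finite(self) -> None:
        vec = self._param_vector()
        if not np.all(np.isfinite(vec)):
            bad = [n for n, v in zip(self._param_names(), vec) if not np.isfinite(v)]
            raise FloatingPointError(
                f"non-finite state at iteration {self.iteration} in blocks {bad}")
        if self.N and not np.all(np.isfinite(self.y)):
            raise FloatingPointError(f"non-finite imputed y at iteration {self.iteration}")

    def step(self) -> None:
        """One full sweep of the block schedule."""
        self.update_latent_u()
        self.update_missing_values()
        self.update_random_effects()
        self.update_mh_blocks()
        self.update_Sigma()
        self.update_tau_delta()
        self.update_selection_blocks()
        self.update_alpha_sigma()
        self.iteration += 1

    def run(self) -> PosteriorSummary:
        cfg = self.config
        names = self._param_names()
        L = cfg.iterations
        draws = np.empty((L, len(names)))
        xi_draws = np.empty((L, self.H))
        self._adapting = cfg.adapt
        for _ in range(cfg.burnin):
            self.step()
            if self.iteration % 100 == 0:
                self._check_finite()
        self._adapting = False
        kept = 0
        while kept < L:
            for _ in range(cfg.thin):
                self.step()
            draws[kept] = self._param_vector()
            xi_draws[kept] = self.xi
            kept += 1
            if self.iteration % 100 == 0:
                self._check_finite()
        acc = {k: float(np.mean(v)) for k, v in self.acceptance.items()}
        return PosteriorSummary(names, draws, xi_draws, acc, self.spline_config, cfg)


def run_chain(data: LongitudinalData, priors: PriorSpec,
              mechanism: miss.MechanismSpec | None = None,
              spline_config: SplineConfig | None = None,
              config: MCMCConfig | None = None) -> PosteriorSummary:
    """Fit the model by MCMC and return the posterior summary.

    ``mechanism`` may be None for complete data (no selection model is then
    fitted).  Draw-for-draw reproducible for a fixed ``config.seed``.
    """
    engine = GibbsSampler(data, priors, mechanism, spline_config, config)
    return engine.run()
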
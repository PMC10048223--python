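"""MCMC correctness: exact conditionals against oracles, prior recovery,
joint-distribution (successive-conditional) checks, and imputation laws."""

import numpy as np
import pytest
from scipy import stats

import tweediemix as tm
from tweediemix import tweedie
from tweediemix.sampler import GibbsSampler, MCMCConfig, PriorSpec


def _complete_engine(rng, n=6, ni=3, mech=None, seed=0):
    """Engine on a small complete dataset (no missing entries)."""
    N = n * ni
    subject = np.repeat(np.arange(n), ni)
    X = rng.standard_normal((N, 3))
    b = rng.normal(0, 0.8, n)
    eta = np.clip(X @ [1.0, 1.0, -1.0] + b[subject] + 0.3, -30, 30)
    y, u = tweedie.sample_arrays(np.exp(eta), 0.5, 1.5, rng)
    data = tm.LongitudinalData(subject=subject, visit=np.tile(np.arange(ni), n),
                               t=rng.uniform(0, 1, N), y=y, X=X, Z=np.ones((N, 1)),
                               u=u, n_missing_covariates=2)
    priors = PriorSpec.vague(q=3, r=1, m=2, variant="A", scale=1.0)
    priors.rho0, priors.R0 = 8.0, 2.0 * np.eye(1)
    cfg = MCMCConfig(seed=seed)
    return GibbsSampler(data, priors, mech, config=cfg)


class TestLatentCounts:
    def test_zero_outcomes_get_zero_counts(self, rng):
        eng = _complete_engine(rng)
        eng.update_latent_u()
        assert np.all((eng.y == 0) == (eng.u == 0))

    def test_matches_exhaustive_conditional(self, rng):
        eng = _complete_engine(rng, seed=3)
        cell = int(np.flatnonzero(eng.y > 0)[0])
        mu = float(eng._mu(np.array([cell]))[0])
        nat = tm.to_natural(tm.TweedieParams(mu, eng.phi, eng.p))
        logp = np.array([tm.joint_logpdf(tm.AugmentedObservation(eng.y[cell], u), nat)
                         for u in range(1, 200)])
        pmf = np.exp(logp - logp.max())
        pmf /= pmf.sum()
        draws = np.empty(4000, dtype=int)
        for i in range(draws.size):
            eng.update_latent_u()
            draws[i] = eng.u[cell]
        emp = np.bincount(draws, minlength=200)[1:200] / draws.size
        assert 0.5 * np.abs(emp - pmf).sum() < 0.03  # total variation distance


class TestConjugateBlocks:
    def test_tau2_conditional_is_inverse_gamma(self, rng):
        eng = _complete_engine(rng)
        xi0 = rng.standard_normal(eng.H)
        delta0 = np.ones(eng.H - 1)
        pen = float(np.sum(np.diff(xi0) ** 2))
        draws = np.empty(3000)
        for i in range(draws.size):
            eng.xi = xi0.copy()
            eng.delta = delta0.copy()
            eng.update_tau_delta()
            draws[i] = eng.tau2
        dist = stats.invgamma(a=eng.priors.a_tau + (eng.H - 1) / 2,
                              scale=eng.priors.b_tau + pen / 2)
        assert stats.kstest(draws, dist.cdf).pvalue > 0.01

    def test_tau2_with_constant_xi(self, rng):
        # a flat coefficient vector contributes no penalty: pure prior shape lift
        eng = _complete_engine(rng)
        draws = np.empty(3000)
        for i in range(draws.size):
            eng.xi = np.full(eng.H, 1.3)
            eng.delta = np.ones(eng.H - 1)
            eng.update_tau_delta()
            draws[i] = eng.tau2
        dist = stats.invgamma(a=eng.priors.a_tau + (eng.H - 1) / 2, scale=eng.priors.b_tau)
        assert stats.kstest(draws, dist.cdf).pvalue > 0.01

    def test_sigma_update_matches_grid_posterior(self, rng):
        # one subject, r = 1, known b: conditional must match the numerically
        # normalized prior x likelihood on a grid, and draws must follow it
        n = 1
        data = tm.LongitudinalData(subject=[0, 0], visit=[0, 1], t=[0.2, 0.8],
                                   y=[0.0, 1.0], X=np.zeros((2, 3)), Z=np.ones((2, 1)),
                                   u=[0, 1], n_missing_covariates=0)
        priors = PriorSpec.vague(q=3, r=1, m=0, variant="A")
        priors.rho0, priors.R0 = 8.0, 2.0 * np.eye(1)
        eng = GibbsSampler(data, priors, None, config=MCMCConfig(seed=1))
        b1 = 0.7
        eng.b = np.array([[b1]])
        from scipy.integrate import cumulative_trapezoid
        grid = np.linspace(1e-3, 60.0, 80_000)
        log_post = (stats.invgamma(a=4.0, scale=1.0).logpdf(grid)   # IW_1(8, 2) prior
                    + stats.norm(0.0, np.sqrt(grid)).logpdf(b1))
        w = np.exp(log_post - log_post.max())
        cdf_grid = cumulative_trapezoid(w, grid, initial=0.0)
        cdf_grid /= cdf_grid[-1]
        analytic = stats.invgamma(a=(8.0 + n) / 2, scale=(2.0 + b1**2) / 2)
        assert np.max(np.abs(cdf_grid - analytic.cdf(grid))) < 1e-3
        draws = np.empty(3000)
        for i in range(draws.size):
            eng.b = np.array([[b1]])
            eng.update_Sigma()
            draws[i] = eng.Sigma[0, 0]
        assert stats.kstest(draws, analytic.cdf).pvalue > 0.01

    def test_alpha_matches_closed_form_regression(self):
        # 20-cell synthetic covariate set, sigma2 pinned: the alpha_1 draw must
        # follow the conjugate Bayesian linear regression posterior
        rng = np.random.default_rng(8)
        eng = _complete_engine(rng, n=10, ni=2)
        s2 = 0.3
        W = np.column_stack([np.ones(eng.N), eng.X[:, 2]])
        target = eng.X[:, 0]
        Dinv = eng._D_inv[0]
        V = np.linalg.inv(W.T @ W / s2 + Dinv)
        mean = V @ (W.T @ target / s2 + Dinv @ eng.priors.alpha0[0])
        draws = np.empty((3000, 2))
        for i in range(draws.shape[0]):
            eng.sigma2[:] = [s2, 0.36]
            eng.update_alpha_sigma()
            draws[i] = eng.alpha[0]
        mc_se = np.sqrt(np.diag(V) / draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0) - mean) < 4 * mc_se)
        assert stats.kstest(draws[:, 1], stats.norm(mean[1], np.sqrt(V[1, 1])).cdf).pvalue > 0.01


class TestPriorRecovery:
    def test_zero_data_reproduces_priors(self):
        """With no observations every block's marginal chain must match its
        prior (the proper blocks; the spline prior is partially improper and
        has no stationary marginal to compare against)."""
        empty = tm.LongitudinalData(
            subject=np.zeros(0, dtype=int), visit=np.zeros(0, dtype=int),
            t=np.zeros(0), y=np.zeros(0), X=np.zeros((0, 3)), Z=np.zeros((0, 1)),
            u=np.zeros(0, dtype=int), n_missing_covariates=2)
        priors = PriorSpec.vague(q=3, r=1, m=2, variant="A", scale=1.0)
        priors.rho0, priors.R0 = 8.0, 2.0 * np.eye(1)
        priors.var_logit_p = priors.var_log_phi = 1.0
        mech = tm.MechanismSpec(variant="A", phi_y=np.zeros(3),
                                phi_x=[np.zeros(2), np.zeros(4)])
        cfg = MCMCConfig(iterations=1500, burnin=1000, thin=10, seed=4)
        summary = tm.run_chain(empty, priors, mech, config=cfg)
        checks = {
            "beta1": stats.norm(0, 1).cdf,
            "phiy0": stats.norm(0, 1).cdf,
            "alpha10": stats.norm(0, 1).cdf,
            "Sigma": stats.invgamma(a=4.0, scale=1.0).cdf,       # IW_1(8, 2)
            "sigma2_x1": stats.invgamma(a=0.01, scale=0.01).cdf,
        }
        for name, cdf in checks.items():
            p = stats.kstest(summary.draws_for(name), cdf).pvalue
            assert p > 0.01, f"{name}: KS p = {p:.4f}"
        theta = np.log(summary.draws_for("p") - 1.0) - np.log(2.0 - summary.draws_for("p"))
        assert stats.kstest(theta, stats.norm(0, 1).cdf).pvalue > 0.01
        assert stats.kstest(np.log(summary.draws_for("phi")), stats.norm(0, 1).cdf).pvalue > 0.01


class TestMHBlocks:
    def test_vanishing_step_accepts_everything(self, rng):
        eng = _complete_engine(rng)
        eng._adapting = False
        eng._ad_beta.log_step = -12.0
        for _ in range(100):
            eng.update_beta()
        assert np.mean(eng.acceptance["beta"]) > 0.95

    def test_successive_conditional_preserves_prior(self):
        """Geweke-style check of the Tweedie beta block: alternating the MH
        parameter update with a fresh data draw from the model must leave the
        marginal of beta equal to its prior."""
        rng = np.random.default_rng(12)
        eng = _complete_engine(rng, n=2, ni=1, seed=21)
        eng.Sigma = np.array([[0.64]])
        draws = []
        for it in range(30_000):
            eng.update_beta()
            # refresh (b, Y, U) from the model at the current parameters
            eng.b = eng.rng.normal(0, 0.8, (eng.n, 1))
            eng._refresh_eta()
            y, u = tweedie.sample_arrays(eng._mu(), eng.phi, eng.p, eng.rng)
            eng.y, eng.u = y, u
            if it == 1000:
                eng._adapting = False
            if it > 1000 and it % 20 == 0:
                draws.append(eng.beta[0])
        p = stats.kstest(np.asarray(draws), stats.norm(0.0, 1.0).cdf).pvalue
        assert p > 0.01

    def test_acceptance_rates_reasonable_after_adaptation(self):
        d = tm.sim1(n=60)
        data = tm.generate_dataset(d, 13)
        cfg = MCMCConfig(iterations=150, burnin=400, seed=2)
        s = tm.run_chain(data, tm.prior_spec(d, "I"), d.mechanism(), config=cfg)
        for name, rate in s.acceptance.items():
            assert 0.1 <= rate <= 0.7, f"{name}: {rate:.2f}"


class TestMissingValueUpdates:
    def _engine_with_missing(self, phi_y, seed=5):
        """One shared dataset (ignorable generation), fitted with the given
        selection coefficients pinned through the prior centers."""
        base = tm.sim1(n=40, phi_y=np.array([-1.0, 0.0, 0.0]),
                       phi_x=[np.array([-2.0, 0.0]), np.array([-2.0, 0.0, 0.0, 0.0])])
        data = tm.generate_dataset(base, 31)
        fit = tm.sim1(n=40, phi_y=np.asarray(phi_y, dtype=float),
                      phi_x=base.phi_x)
        eng = GibbsSampler(data, tm.prior_spec(fit, "I"), fit.mechanism(),
                           config=MCMCConfig(seed=seed))
        return eng

    def test_ignorable_case_is_exact_model_draw(self):
        # phi_y1 = phi_y2 = 0: the selection factor cancels, every proposal is
        # accepted, and the imputations are iid Tweedie draws at the cell mean
        eng = self._engine_with_missing([-1.0, 0.0, 0.0])
        cell = int(eng.miss_y_idx[0])
        n = 3000
        imput = np.empty(n)
        for i in range(n):
            eng.update_missing_y()
            imput[i] = eng.y[cell]
        mu = float(eng._mu(np.array([cell]))[0])
        ref, _ = tweedie.sample_arrays(np.full(n, mu), eng.phi, eng.p,
                                       np.random.default_rng(99))
        p_pos = stats.ks_2samp(imput[imput > 0], ref[ref > 0]).pvalue
        assert p_pos > 0.01
        z0 = stats.norm.sf(abs(imput.mean() - ref.mean())
                           / np.sqrt(imput.var() / n + ref.var() / n)) * 2
        assert z0 > 0.01

    def test_mnar_imputations_shift_upward(self):
        # a positive outcome coefficient in the selection model must tilt the
        # imputed missing outcomes upward relative to the ignorable case
        base = self._engine_with_missing([-1.0, 0.0, 0.0], seed=6)
        tilt = self._engine_with_missing([-1.0, 1.5, 0.0], seed=6)
        cells = base.miss_y_idx
        means = {}
        for tag, eng in (("base", base), ("tilt", tilt)):
            tot = np.zeros(cells.size)
            for _ in range(800):
                eng.update_missing_y()
                tot += eng.y[eng.miss_y_idx]
            means[tag] = tot.mean() / 800
        assert means["tilt"] > means["base"]


class TestRunChain:
    def test_deterministic_and_summary_identity(self, rng):
        d = tm.sim1(n=15)
        data = tm.generate_dataset(d, 17)
        cfg = MCMCConfig(iterations=60, burnin=60, seed=11)
        s1 = tm.run_chain(data, tm.prior_spec(d, "I"), d.mechanism(), config=cfg)
        s2 = tm.run_chain(data, tm.prior_spec(d, "I"), d.mechanism(), config=cfg)
        np.testing.assert_array_equal(s1.draws, s2.draws)
        # the reported posterior mean is the arithmetic mean of the draws
        name = "beta1"
        assert s1.mean(name) == pytest.approx(float(np.mean(s1.draws_for(name))))
        assert s1.sd(name) == pytest.approx(float(np.std(s1.draws_for(name), ddof=1)))

    def test_single_dataset_recovery_within_three_sd(self):
        # one mid-length chain on one simulated dataset: every posterior mean
        # within 3 posterior SDs of the generating truth
        d = tm.sim1()
        data = tm.generate_dataset(d, 23)
        cfg = MCMCConfig(iterations=1500, burnin=1500, seed=29)
        s = tm.run_chain(data, tm.prior_spec(d, "I"), d.mechanism(), config=cfg)
        truth = d.true_values()
        for name, tv in truth.items():
            z = abs(s.mean(name) - tv) / s.sd(name)
            assert z < 3.5, f"{name}: mean {s.mean(name):.3f} truth {tv} z {z:.2f}"
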
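"""Selection mechanisms and the sequential covariate model."""

import numpy as np
import pytest
from scipy.special import expit

import tweediemix as tm
from tweediemix.missingness import (CovariateModel, MechanismSpec, bernoulli_loglik,
                                    covariate_logits, response_logits)


def mech_a():
    return MechanismSpec(variant="A", phi_y=[-2.4, 0.1, 0.1],
                         phi_x=[[-2.5, 0.1], [-1.9, 0.05, 0.05, 0.3]])


def mech_b():
    return MechanismSpec(variant="B", phi_y=[-2.2, 0.1, 0.1, 0.1],
                         phi_x=[[-2.5, 0.2, 0.1], [-1.9, 0.05, 0.05, -0.3]])


class TestLogits:
    def test_response_variant_a_at_zero(self):
        v = tm.response_missing_logit(0.0, 0.0, None, mech_a())
        assert v == pytest.approx(-2.4)
        assert expit(v) == pytest.approx(0.0832, abs=2e-4)

    def test_covariate_k1_at_zero(self):
        v = tm.covariate_missing_logit([0.0, 0.0, 0.0], None, None, mech_a(), k=1)
        assert v == pytest.approx(-2.5)
        assert expit(v) == pytest.approx(0.0759, abs=2e-4)

    def test_variant_b_uses_outcome(self):
        v = tm.covariate_missing_logit([1.0, 0.0, 0.0], None, 2.0, mech_b(), k=1)
        assert v == pytest.approx(-2.5 + 0.2 * 1.0 + 0.1 * 2.0)

    def test_mcar_degenerate(self, rng):
        spec = MechanismSpec(variant="A", phi_y=[-1.0, 0.0, 0.0],
                             phi_x=[[-2.5, 0.1], [-1.9, 0.05, 0.05, 0.3]])
        y = rng.gamma(2, 1, 50)
        v = response_logits(y, np.zeros(50), None, spec)
        assert np.ptp(v) == 0.0  # probability independent of the outcome

    def test_layout_validation(self):
        with pytest.raises(ValueError):
            MechanismSpec(variant="A", phi_y=[-2.4, 0.1], phi_x=[])
        with pytest.raises(ValueError):
            MechanismSpec(variant="B", phi_y=[-2.2, 0.1, 0.1, 0.1],
                          phi_x=[[-2.5, 0.2], [-1.9, 0.05, 0.05, -0.3]])


class TestMissingLoglik:
    def test_limits(self):
        spec = MechanismSpec(variant="A", phi_y=[-1e3, 0.0, 0.0],
                             phi_x=[[-1e3, 0.0], [-1e3, 0.0, 0.0, 0.0]])
        data = _small_data(np.random.default_rng(0), masks=False)
        # indicators all 0, probabilities ~0: log-likelihood tends to 0-
        assert tm.missing_loglik(data, spec) == pytest.approx(0.0, abs=1e-6)

    def test_single_cell_logit_zero(self):
        assert bernoulli_loglik(1.0, 0.0) == pytest.approx(np.log(0.5))
        assert bernoulli_loglik(0.0, 0.0) == pytest.approx(np.log(0.5))

    @pytest.mark.parametrize("make_mech", [mech_a, mech_b])
    def test_matches_per_cell_oracle(self, rng, make_mech):
        spec = make_mech()
        data = _small_data(rng, masks=True)
        got = tm.missing_loglik(data, spec)
        # brute force: walk every cell, each indicator's Bernoulli log-likelihood
        want = 0.0
        prev = data.prev_index()
        for i in range(data.N):
            ylag = data.y[prev[i]] if prev[i] >= 0 else 0.0
            if spec.variant == "A":
                v = spec.phi_y[0] + spec.phi_y[1] * data.y[i] + spec.phi_y[2] * ylag
            else:
                v = (spec.phi_y[0] + spec.phi_y[1] * data.y[i]
                     + spec.phi_y[2] * data.X[i, 0] + spec.phi_y[3] * data.X[i, 1])
            pr = expit(v)
            want += np.log(pr if data.y_missing[i] else 1 - pr)
            for k in (1, 2):
                f = spec.phi_x[k - 1]
                vk = f[0] + f[1:k + 1] @ data.X[i, :k]
                if spec.variant == "A":
                    if k == 2:
                        vk += f[3] * data.x_missing[i, 0]
                else:
                    vk += f[k + 1] * data.y[i]
                pk = expit(vk)
                want += np.log(pk if data.x_missing[i, k - 1] else 1 - pk)
        assert got == pytest.approx(want, rel=1e-10)


def _small_data(rng, masks):
    n, ni = 8, 3
    N = n * ni
    subject = np.repeat(np.arange(n), ni)
    X = rng.standard_normal((N, 3))
    y = rng.gamma(1.0, 1.0, N) * (rng.random(N) > 0.2)
    data = tm.LongitudinalData(subject=subject, visit=np.tile(np.arange(ni), n),
                               t=rng.uniform(0, 1, N), y=y, X=X, Z=np.ones((N, 1)),
                               n_missing_covariates=2)
    if masks:
        data.y_missing = rng.random(N) < 0.3
        data.x_missing = rng.random((N, 2)) < 0.3
    return data


class TestCovariateModel:
    MODEL = CovariateModel(alpha=[np.array([0.05, 0.5]), np.array([-0.9, 0.05, 0.9])],
                           sigma2=np.array([0.25, 0.36]), m=2)

    def test_stated_conditionals(self):
        # x1 | x3=0 ~ N(0.05, 0.25); x2 | x1=0, x3=0 ~ N(-0.9, 0.36)
        assert self.MODEL.mean(1, np.array([[0.0, 0.0, 0.0]]))[0] == pytest.approx(0.05)
        assert self.MODEL.mean(2, np.array([[0.0, 0.0, 0.0]]))[0] == pytest.approx(-0.9)
        lp = tm.covariate_logpdf(np.array([0.05, -0.9, 0.0]), self.MODEL)
        # x2's conditional mean at x1 = 0.05 is -0.9 + 0.05 * 0.05 = -0.8975
        want = (-0.5 * np.log(2 * np.pi * 0.25)
                - 0.5 * np.log(2 * np.pi * 0.36) - 0.5 * 0.0025**2 / 0.36)
        assert lp == pytest.approx(want)

    def test_sampler_matches_entropy(self, rng):
        # mean log-density of sequential draws equals minus the sum of the
        # conditional Gaussian entropies
        n = 20_000
        lps = np.empty(n)
        for i in range(n):
            x0 = rng.standard_normal(1)
            xm = tm.sample_covariates(x0, self.MODEL, rng)
            lps[i] = tm.covariate_logpdf(np.r_[xm, x0], self.MODEL)
        entropy = sum(0.5 * np.log(2 * np.pi * np.e * s2) for s2 in (0.25, 0.36))
        se = np.std(lps) / np.sqrt(n)
        assert np.mean(lps) == pytest.approx(-entropy, abs=4 * se)

    def test_rejects_bad_variance(self):
        with pytest.raises(ValueError):
            CovariateModel(alpha=[np.array([0.0, 0.0])], sigma2=np.array([-1.0]), m=1)


class TestGenerateIndicators:
    def test_extremes(self, rng):
        data = _small_data(rng, masks=False)
        none = MechanismSpec(variant="A", phi_y=[-1e3, 0, 0],
                             phi_x=[[-1e3, 0], [-1e3, 0, 0, 0]])
        ry, rx = tm.generate_indicators(data, none, rng)
        assert not ry.any() and not rx.any()
        all_y = MechanismSpec(variant="A", phi_y=[1e3, 0, 0],
                              phi_x=[[-1e3, 0], [-1e3, 0, 0, 0]])
        ry, _ = tm.generate_indicators(data, all_y, rng)
        assert ry.all()

    def test_law_of_large_numbers(self):
        # empirical missing fractions converge to the mean logistic probability
        rng = np.random.default_rng(7)
        d = tm.sim1(n=5000)
        data = tm.generate_dataset(d, 11)
        spec = d.mechanism()
        prev = data.prev_index()
        ylag = np.where(prev >= 0, data.y[np.maximum(prev, 0)], 0.0)
        p_y = expit(response_logits(data.y, ylag, None, spec))
        assert data.y_missing.mean() == pytest.approx(p_y.mean(), abs=4 * p_y.std() / np.sqrt(data.N))
        p_x1 = expit(covariate_logits(1, data.X, None, None, spec))
        assert data.x_missing[:, 0].mean() == pytest.approx(p_x1.mean(), abs=0.006)

    def test_indicator_chain_dependence(self, rng):
        # variant A: x2's missingness depends on r_x1 exactly when phi_x23 != 0
        data = _small_data(np.random.default_rng(3), masks=False)
        data = tm.generate_dataset(tm.sim1(n=4000), 5)
        strong = MechanismSpec(variant="A", phi_y=[-1e3, 0, 0],
                               phi_x=[[0.0, 0.0], [-1.9, 0.05, 0.05, 3.0]])
        rng1 = np.random.default_rng(17)
        _, rx = tm.generate_indicators(data, strong, rng1)
        rate_given_r1 = rx[rx[:, 0], 1].mean()
        rate_given_not = rx[~rx[:, 0], 1].mean()
        assert rate_given_r1 > rate_given_not + 0.2
        null = MechanismSpec(variant="A", phi_y=[-1e3, 0, 0],
                             phi_x=[[0.0, 0.0], [-1.9, 0.05, 0.05, 0.0]])
        _, rx0 = tm.generate_indicators(data, null, np.random.default_rng(18))
        diff = abs(rx0[rx0[:, 0], 1].mean() - rx0[~rx0[:, 0], 1].mean())
        assert diff < 0.03
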
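import numpy as np
import pytest

import tweediemix as tm


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sim1_design():
    return tm.sim1()


@pytest.fixture(scope="session")
def sim1_data(sim1_design):
    return tm.generate_dataset(sim1_design, seed=7)


@pytest.fixture
def tiny_data(rng):
    """3 subjects x 2 visits, complete, with latent counts."""
    n, ni = 3, 2
    N = n * ni
    subject = np.repeat(np.arange(n), ni)
    visit = np.tile(np.arange(ni), n)
    t = rng.uniform(0, 1, N)
    X = rng.standard_normal((N, 3))
    b = rng.normal(0, 0.8, n)
    eta = X @ np.array([1.0, 1.0, -1.0]) + b[subject] + np.sin(2 * np.pi * t)
    y, u = tm.tweedie.sample_arrays(np.exp(np.clip(eta, -30, 30)), 0.5, 1.5, rng)
    return tm.LongitudinalData(subject=subject, visit=visit, t=t, y=y, X=X,
                               Z=np.ones((N, 1)), u=u, n_missing_covariates=2)
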
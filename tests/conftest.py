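import numpy as np
import pytest

from ubxii import distribution as dist
from ubxii.links import link_bundle
from ubxii.regression import RegressionModel, reg_fit


def simulate_regression_model(beta, c, n, seed, tau=0.5, link="logit",
                              extra_cov=0):
    """Logit-linked UBXII regression data with standard-normal covariates."""
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    k = beta.size
    X = np.column_stack(
        [np.ones(n)] + [rng.standard_normal(n) for _ in range(k - 1 + extra_cov)]
    )
    lnk = link_bundle(link)
    q = lnk.g_inv(X[:, :k] @ beta)
    y = np.array([
        float(dist.qf(u, dist.QuantileParams(c, qi, tau)))
        for u, qi in zip(rng.uniform(size=n), q)
    ])
    y = np.clip(y, 5e-324, np.nextafter(1.0, 0.0))
    return RegressionModel(y, X, lnk, tau)


@pytest.fixture(scope="session")
def scenario1_sample():
    """n=200 draws from UBXII(c=1.5, q=0.3, tau=0.5)."""
    return dist.sample(200, dist.QuantileParams(1.5, 0.3, 0.5), seed=20240901)


@pytest.fixture(scope="session")
def reg_model_s1():
    """Simulated scenario-1 regression data (beta=(1.3, 1.4), c=2), n=150."""
    return simulate_regression_model((1.3, 1.4), 2.0, 150, seed=77)


@pytest.fixture(scope="session")
def reg_fit_s1(reg_model_s1):
    return reg_fit(reg_model_s1)


@pytest.fixture(scope="session")
def dropout_model():
    from ubxii.datasets import load_dropout

    return load_dropout().to_model()


@pytest.fixture(scope="session")
def dropout_fit(dropout_model):
    return reg_fit(dropout_model)
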
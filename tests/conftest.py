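import numpy as np
import pytest

from bsd import Band, FrequencyGrid, ModelSpec, PriorSpec
from bsd.inversion import Posterior


@pytest.fixture
def grid():
    return FrequencyGrid.from_range(1.0, 32.0, 0.5)


@pytest.fixture
def alpha_band():
    return Band("alpha", 8.0, 12.0)


@pytest.fixture
def beta_band():
    return Band("beta", 12.0, 30.0)


@pytest.fixture
def two_band_spec(alpha_band, beta_band):
    return ModelSpec(bands=[alpha_band, beta_band])


def make_posterior(mean, cov, F=0.0, prior=None):
    """Hand-built Gaussian posterior for second-level and BMR tests."""
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    return Posterior(
        mean=mean,
        cov=cov,
        lambda_mean=0.0,
        lambda_var=0.0,
        free_energy=F,
        accuracy=F,
        complexity_theta=0.0,
        complexity_lambda=0.0,
        n_iter=1,
        converged=True,
        prior=prior,
    )


@pytest.fixture
def posterior_factory():
    return make_posterior
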
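import numpy as np
import pytest

from designrisk.models import GaussianPredictive, NonlinearGaussianModel


def gauss1d(mean: float, var: float = 1.0) -> GaussianPredictive:
    return GaussianPredictive(np.array([float(mean)]), np.array([[float(var)]]))


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def reduced_scale():
    """Problem sizes used for simulation-heavy tests: 2-minute sessions on a
    0.2 s microtime grid, sampled every 2 s."""
    return dict(session_length=120.0, dt=0.2, tr=2.0)


def linear_model(X, eta=None, prior_cov=1.0, noise_cov=1.0, name="lin"):
    X = np.asarray(X, float)
    p = X.shape[1]
    eta = np.zeros(p) if eta is None else np.asarray(eta, float)
    return NonlinearGaussianModel(
        name=name,
        observation_mapping=lambda th, d: X @ th,
        batch_mapping=lambda ts, d: X @ ts,
        prior_mean=eta,
        prior_cov=prior_cov,
        noise_cov=noise_cov,
        n_y=X.shape[0],
    )
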
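import numpy as np
import pytest

from brainstates import StudyConfig, make_ground_truth
from brainstates.synthetic_data import draw_parameters


@pytest.fixture(scope="session")
def small_study():
    """Compact planted study shared by recovery-style tests."""
    cfg = StudyConfig(n_participants=4, T=200)
    return make_ground_truth(cfg, seed=7)


@pytest.fixture(scope="session")
def quiet_study():
    """Near-noise-free study: decode should recover the planted states."""
    cfg = StudyConfig(n_participants=2, T=200, emission_snr=1e5,
                      dynamics_noise=1e-6)
    return make_ground_truth(cfg, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_params(rng, K=2, D=2, N=6, M=4, **kw):
    """Random stable parameter set with PD covariances."""
    cfg = StudyConfig(K=K, D=D, N=N, M=M, **kw)
    p = draw_parameters(cfg, rng)
    p.Sigma_v = np.diag(rng.uniform(0.05, 0.2, size=N))
    return p
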
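import numpy as np
import pytest

from mvbdecode import (SimConfig, ar1_covariance, default_confounds,
                       simulate_dataset)
from mvbdecode.mvb import MVBOperator


@pytest.fixture(scope="session")
def small_dataset():
    """Small noise-light dataset shared by classifier tests."""
    cfg = SimConfig(n_voxels=24, n_trials_per_class=8, snr=4.0,
                    drift_amplitude=0.2, seed=5)
    trials, bold, truth = simulate_dataset(cfg)
    return cfg, trials, bold, truth


@pytest.fixture(scope="session")
def small_context(small_dataset):
    """Confounds, noise model and cached operator for the small dataset."""
    cfg, trials, bold, truth = small_dataset
    conf = default_confounds(bold.n_scans, bold.TR)
    noise = ar1_covariance(bold.n_scans, 0.2)
    op = MVBOperator(bold.data, conf.R, noise.V)
    return conf, noise, op


def random_mvb_problem(seed, M=50, N=12, rho=0.2, noise_sd=0.5):
    """Seeded random operating space + target with planted weights."""
    rng = np.random.default_rng(seed)
    Y = rng.normal(size=(M, N))
    conf = default_confounds(M, 2.0)
    noise = ar1_covariance(M, rho)
    op = MVBOperator(Y, conf.R, noise.V)
    beta = rng.normal(size=N)
    v = op.L @ beta + noise_sd * rng.normal(size=op.w)
    return op, v, beta, conf, noise
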
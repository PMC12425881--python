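import numpy as np
import pytest
from hypothesis import settings

import myokf as mk

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def protocol():
    return mk.TrialProtocol()


@pytest.fixture
def fast_protocol():
    """Short protocol for unit tests that only need the structure."""
    return mk.TrialProtocol(reps=2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_config():
    """Noiseless, lag-free, crosstalk-free generator settings."""
    return mk.SynthConfig(
        crosstalk=0.0, noise_sd=0.0, baseline=0.0, lag_ms=0.0, session_gain_sd=0.0, seed=7
    )


@pytest.fixture(scope="session")
def cohort_run():
    """One full default-cohort experiment, shared across tests.

    Returns (config, result, wall_seconds).
    """
    import time

    cfg = mk.default_cohort(7, master_seed=0)
    t0 = time.time()
    result = mk.run_experiment(cfg)
    return cfg, result, time.time() - t0
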
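import numpy as np
import pytest

from fcreliab import SyntheticCohortConfig, generate_cohort
from fcreliab.synthetic import MotionModel

QUIET = MotionModel(burst_prob=0.0, signal_spike_scale=0.0)


@pytest.fixture(scope="session")
def quiet_motion():
    """Motion model with no bursts and no signal contamination."""
    return QUIET


@pytest.fixture(scope="session")
def small_cohort():
    """Default-motion cohort at desk scale: 4 subjects, 30 nodes."""
    cfg = SyntheticCohortConfig(n_pairs=2, n_nodes=30, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def quiet_cohort():
    """Low-noise, burst-free cohort for recovery tests: 4 subjects, 60 nodes."""
    cfg = SyntheticCohortConfig(
        n_pairs=2,
        n_nodes=60,
        seed=3,
        observation_noise_scale=0.2,
        adult_motion=QUIET,
        child_low_motion=QUIET,
        child_high_motion=QUIET,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
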
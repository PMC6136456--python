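import numpy as np
import pytest

import rewardshift as rs


@pytest.fixture(scope="session")
def config():
    return rs.TaskConfig()


@pytest.fixture(scope="session")
def short_config():
    """Shorter blocks for fast unit tests; same task structure."""
    return rs.TaskConfig(
        first_block_len_mean=20,
        first_block_len_sd=3,
        later_block_len_mean=26,
        later_block_len_sd=4,
    )


@pytest.fixture(scope="session")
def behavior_params():
    return rs.BehaviorParams()


@pytest.fixture(scope="session")
def session(config, behavior_params):
    """One default-length simulated session, shared across tests."""
    schedule = rs.build_block_schedule(config, 11)
    return rs.simulate_behavior(schedule, behavior_params, config, 12)


@pytest.fixture(scope="session")
def short_session(short_config, behavior_params):
    schedule = rs.build_block_schedule(short_config, 21)
    return rs.simulate_behavior(schedule, behavior_params, short_config, 22)


@pytest.fixture(scope="session")
def attentive_params():
    return rs.BehaviorParams(flavor_attention_prob=1.0)


@pytest.fixture(scope="session")
def inattentive_params():
    return rs.BehaviorParams(flavor_attention_prob=0.0)


def poisson_train(rate_hz, t_end, seed):
    """Homogeneous Poisson spike times on [0, t_end) — test-side oracle."""
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate_hz * t_end)
    return np.sort(rng.uniform(0.0, t_end, size=n))
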
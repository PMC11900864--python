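import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from thermolearn import (
    AgentSpec,
    TaskConfig,
    generate_schedule,
    realize_trials,
    simulate_agent,
)


@pytest.fixture(scope="session")
def config():
    return TaskConfig()


@pytest.fixture(scope="session")
def sequence(config):
    sched = generate_schedule(config, seed=1)
    return realize_trials(sched, config, seed=2)


@pytest.fixture(scope="session")
def hgf_dataset(sequence):
    """One clean simulated HGF agent (no missing responses)."""
    agent = AgentSpec(model="hgf2", params={"omega": -3.0}, zeta=4.0,
                      missing_rate=0.0)
    return simulate_agent(sequence, agent, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
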
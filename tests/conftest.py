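import numpy as np
import pytest

from satkit.agent import AgentParams
from satkit.config import SessionConfig
from satkit.controller import run_session


@pytest.fixture
def default_cfg():
    return SessionConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def null_agent():
    """Non-learner: flat licking, no novelty effect, steady initiation."""
    return AgentParams(
        learning_rate=0.0,
        novelty_suppression=0.0,
        init_rate_per_hr=40.0,
        diurnal_amplitude=0.0,
    )


@pytest.fixture
def learner_agent():
    return AgentParams()


@pytest.fixture(scope="session")
def learner_log():
    """One 48-h default-paradigm session from a learning agent."""
    return run_session(SessionConfig(), AgentParams(), seed=2024)


@pytest.fixture(scope="session")
def short_null_log():
    cfg = SessionConfig(session_duration_hr=4.0)
    agent = AgentParams(
        learning_rate=0.0,
        novelty_suppression=0.0,
        init_rate_per_hr=40.0,
        diurnal_amplitude=0.0,
    )
    return run_session(cfg, agent, seed=77)
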
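import pytest

from jitai.config import SimulationConfig
from jitai.features import build_model_tables
from jitai.simulate import run_deployment


def small_config(n_participants: int = 6, weeks: int = 2) -> SimulationConfig:
    cfg = SimulationConfig()
    cfg.cohort.n_participants = n_participants
    cfg.weeks = weeks
    return cfg


@pytest.fixture(scope="session")
def small_events():
    """A small (10-participant, 2-week) simulated deployment, shared across
    tests that only need a structurally valid event log."""
    return run_deployment(seed=11, config=small_config(10, 2))


@pytest.fixture(scope="session")
def small_tables(small_events):
    return build_model_tables(small_events)
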
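import numpy as np
import pytest

from edran.core import FieldPartition, build_interval_scheme
from edran.event_data import MatchEvent, MatchRecord
from edran.simulate import SimulationConfig, simulate_dataset


def make_event(
    match_id="m1",
    team="A",
    period=1,
    time_s=10.0,
    duration_s=2.0,
    x=10.0,
    y=10.0,
    event_type="pass",
):
    return MatchEvent(match_id, team, period, time_s, duration_s, x, y, event_type)


@pytest.fixture
def toy_match():
    """Hand-built 2-event match: both events in known regions of period 1."""
    events = [
        make_event(time_s=5.0, duration_s=3.0, x=5.0, y=5.0),  # region (0, 0)
        make_event(team="B", time_s=100.0, duration_s=4.0, x=25.0, y=5.0),  # (0, 1)
    ]
    return MatchRecord(
        match_id="m1", events=events, result=1, period_end_s={1: 2700.0, 2: 2700.0}
    )


@pytest.fixture
def partition():
    return FieldPartition()


@pytest.fixture(scope="session")
def small_sim():
    """60-match breadth-planted simulation shared across tests."""
    cfg = SimulationConfig(n_matches=60, seed=11)
    records, truth = simulate_dataset(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def scheme(toy_match):
    return build_interval_scheme(toy_match)
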
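import numpy as np
import pytest

from cftrgate.gating_model import (
    Protocol,
    RateSet,
    StatePath,
    build_topology,
)


@pytest.fixture(scope="session")
def wt_rates() -> RateSet:
    return RateSet.wt_calibrated()


@pytest.fixture(scope="session")
def wt_graph(wt_rates):
    return build_topology("WT", rates=wt_rates)


@pytest.fixture(scope="session")
def wt_path_2000s(wt_graph):
    """One long seeded trajectory at saturating ATP, shared across tests."""
    from cftrgate.gating_model import simulate_ssa

    return simulate_ssa(wt_graph, Protocol(duration_s=2000.0), seed=20230322)


def make_path(segments, state_names, protocol=None, seed=0) -> StatePath:
    """Hand-built StatePath from (state_index, dwell_s) pairs."""
    states, entries, dwells = [], [], []
    t = 0.0
    for s, d in segments:
        states.append(s)
        entries.append(t)
        dwells.append(d)
        t += d
    protocol = protocol or Protocol(duration_s=t)
    return StatePath(
        states=np.array(states, dtype=int),
        entry_s=np.array(entries),
        dwell_s=np.array(dwells),
        protocol=protocol,
        hydrolysis_events=np.array([]),
        seed=seed,
        state_names=tuple(state_names),
    )


@pytest.fixture
def two_level_path():
    """Alternating low/high path with 1 s dwells (10 s total)."""
    return make_path([(i % 2, 1.0) for i in range(10)], ("LOW", "HIGH"))
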
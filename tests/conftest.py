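import numpy as np
import pytest

from ctfusion import CountProfile, SimulationConfig, default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture
def config():
    return SimulationConfig(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_profile(panel):
    """Profile factory: every panel probe gets a benign default count
    (HK 200, MET wt 300, skip 30, everything else 5), overridable per probe."""

    def _make(sample_id="S1", fluid="plasma", **overrides):
        counts = {}
        for probe in panel:
            if probe.probe_class == "housekeeping":
                counts[probe.probe_id] = 200
            elif probe.probe_class == "met_wt":
                counts[probe.probe_id] = 300
            elif probe.probe_class == "met_skip":
                counts[probe.probe_id] = 30
            else:
                counts[probe.probe_id] = 5
        counts.update(overrides)
        return CountProfile(sample_id=sample_id, counts=counts, fluid=fluid)

    return _make
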
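import numpy as np
import pytest

from tremorkit import SimConfig, analyze_session, simulate_session


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180713)


@pytest.fixture(scope="session")
def et_session():
    """One simulated essential-tremor-like session (default amplitudes, 5 Hz)."""
    cfg = SimConfig(seed=1)
    recordings, ground_truth = simulate_session(cfg)
    return cfg, recordings, ground_truth


@pytest.fixture(scope="session")
def et_result(et_session):
    """Full pipeline result for the shared ET session."""
    _, recordings, _ = et_session
    return analyze_session(recordings)
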
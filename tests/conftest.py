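import numpy as np
import pytest

import tactypes as tt


@pytest.fixture(scope="session")
def window_set():
    """One (neuron, pattern) cell with four well-separated planted types."""
    return tt.simulate_window_set(k_types=4, reps_per_type=80,
                                  ungrouped_fraction=0.2, seed=11)


@pytest.fixture(scope="session")
def clustered(window_set):
    return tt.cluster_responses(window_set.windows)


@pytest.fixture(scope="session")
def small_session():
    """A short full-signal session (2 patterns x 10 reps)."""
    cfg = tt.SessionConfig(n_patterns=2, reps_per_pattern=10,
                           single_pulse_chunks_per_channel=2, seed=3)
    rec, truth = tt.simulate_session(cfg)
    return cfg, rec, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
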
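import numpy as np
import pytest

from channelsynth import make_windows, sample_trajectory, two_state_model


@pytest.fixture(scope="session")
def demo_model():
    """Two-state C<->O scheme: opening 50/s, closing 100/s, -5 pA, 1 pA noise."""
    return two_state_model()


@pytest.fixture(scope="session")
def demo_record(demo_model):
    """20 s of simulated recording at 5 kHz (100k samples)."""
    return sample_trajectory(demo_model, 20.0, seed=11)


@pytest.fixture(scope="session")
def demo_windows(demo_record):
    """Non-overlapping scaled 2 x 64 windows of the demo record."""
    return make_windows(demo_record, 64, 64)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
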
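import numpy as np
import pytest

from mupulse.events import make_event_sequence
from mupulse.params import SubjectParams
from mupulse.simulate import simulate_eeg


@pytest.fixture(scope="session")
def small_events():
    """A two-block paradigm small enough for per-test simulation."""
    return make_event_sequence(24, 24, 4, 2, 2.0, 0.3, seed=3)


@pytest.fixture(scope="session")
def clean_params():
    """Noise-free parameters isolating the oscillatory sources."""
    return SubjectParams(noise_sd=0.0, p60_amp=0.0, blink_rate=0.0,
                        occ_alpha_amp=0.0, env_wander=0.0)


@pytest.fixture(scope="session")
def small_recording(small_events):
    """One noisy 32-channel recording shared across preprocessing tests."""
    return simulate_eeg(small_events, SubjectParams(noise_sd=2.0), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
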
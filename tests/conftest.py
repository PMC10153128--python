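import logging
import warnings

import numpy as np
import pytest

from laminar_oddball.core import EventTable, ProbeGeometry, Recording
from laminar_oddball.synth import (
    SequenceSpec,
    default_oddball_truth,
    generate_session,
    generate_stimulus_sequence,
    simulate_recording,
)

logging.getLogger("laminar_oddball").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", message="Epsilon values might be innaccurate")


@pytest.fixture(scope="session")
def geometry():
    return ProbeGeometry()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_events():
    """A miniature full session (control + flip-flop oddballs) at 10 kHz."""
    return generate_session(n_control=24, n_oddball=16, seed=7)


@pytest.fixture(scope="session")
def small_recording(small_events):
    """A miniature synthetic recording with the default effect catalogue."""
    truth = default_oddball_truth()
    truth.mua.preferred_deg = 45
    return simulate_recording(small_events, truth, seed=11)


def random_recording(rng, n_contacts=16, n_samples=10000, fs=10000.0):
    sig = rng.standard_normal((n_contacts, n_samples)).astype(np.float32)
    return Recording(signal=sig, fs=fs, geometry=ProbeGeometry(n_contacts=n_contacts))
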
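import numpy as np
import pytest

from aviasomn import simulate_recording
from aviasomn.protocol import Protocol
from aviasomn.synth import SimSignalParams


@pytest.fixture(scope="session")
def short_protocol() -> Protocol:
    """Single 4-h 'day' (2 h light, 2 h dark) for fast end-to-end tests."""
    return Protocol(day_labels=("baseline",), day_hours=4.0)


@pytest.fixture(scope="session")
def short_recording(short_protocol):
    """A clean 4-h recording with ground-truth hypnogram."""
    return simulate_recording(short_protocol, seed=11)


@pytest.fixture(scope="session")
def artifact_recording(short_protocol):
    """A 4-h recording with injected artifacts at 10/h."""
    return simulate_recording(
        short_protocol,
        signal_params=SimSignalParams(artifact_rate_per_h=10.0),
        seed=13,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240229)
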
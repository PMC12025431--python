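import numpy as np
import pytest

from microstates.recording_io import Recording
from microstates.synthetic import disk_montage, make_canonical_templates


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def montage16():
    return disk_montage(16)


@pytest.fixture(scope="session")
def templates16(montage16):
    """Canonical 4-class maps on a 16-channel layout."""
    return make_canonical_templates(montage16, K=4, seed=0)


@pytest.fixture
def random_recording(rng):
    """8-channel, 2-second noise recording at 500 Hz."""
    data = rng.normal(0, 5, size=(8, 1000))
    return Recording(data=data, srate=500.0,
                     channels=[f"C{i}" for i in range(8)])
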
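import numpy as np
import pytest

from vocalmod import synth


@pytest.fixture(scope="session")
def usv_stream():
    """A medium-length ground-truth call stream shared across tests."""
    return synth.gen_usv_stream(duration=600.0, seed=11)


@pytest.fixture(scope="session")
def long_usv_stream():
    """A long stream with ~100 first calls for power/calibration checks."""
    return synth.gen_usv_stream(duration=1000.0, seed=11)


@pytest.fixture(scope="session")
def profiles():
    return synth.default_profiles()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
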
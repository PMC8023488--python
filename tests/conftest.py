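import numpy as np
import pytest

from wtexpd import WTexpdParams, load_dataset


@pytest.fixture(scope="session")
def bearings():
    return load_dataset("ball_bearings")


@pytest.fixture(scope="session")
def vinyl():
    return load_dataset("vinyl_chloride")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def params():
    """A generic strictly-interior parameter point."""
    return WTexpdParams(tau=1.0, alpha=2.4, theta=1.2, beta=1.7)
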
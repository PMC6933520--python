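import numpy as np
import pytest

from neuroseg import phantom


@pytest.fixture(scope="session")
def small_phantom() -> phantom.PhantomCase:
    """One deterministic 48-cube phantom with tumor + WMH."""
    spec = phantom.PhantomSpec(grid_shape=(48, 48, 48), seed=7)
    return phantom.generate_phantom(spec)


@pytest.fixture(scope="session")
def noiseless_phantom() -> phantom.PhantomCase:
    spec = phantom.PhantomSpec(grid_shape=(48, 48, 48), seed=7, noise_sd=0.0)
    return phantom.generate_phantom(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
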
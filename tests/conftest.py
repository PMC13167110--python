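import numpy as np
import pytest

from fluomux.spectral import build_grid, default_library


@pytest.fixture(scope="session")
def grid():
    return build_grid()


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def injected(library):
    """The nine retrograde labels (library minus the calcium indicator)."""
    return [n for n in library.names if n != "GCaMP6s"]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
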
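import numpy as np
import pytest

from sl0ct import ScanGeometry, build_projection_operator


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_system():
    """A 16x16 grid scanned from 12 angles with 24 detector bins."""
    geometry = ScanGeometry.uniform(12, 24)
    A = build_projection_operator(geometry, 16)
    return A


@pytest.fixture(scope="session")
def tiny_system():
    """An 8x8 grid with 6 angles and 12 detector bins (72 rays)."""
    geometry = ScanGeometry.uniform(6, 12)
    return build_projection_operator(geometry, 8)
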
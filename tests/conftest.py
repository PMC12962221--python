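import numpy as np
import pytest

from qmtrecon.encoding import CoilSensitivities, SamplingMask, make_vd_gaussian_mask
from qmtrecon.signal import (
    FixedPoolConstants,
    TissueParams,
    phantom_protocol,
    measurement_constants,
)


@pytest.fixture(scope="session")
def consts():
    return FixedPoolConstants()


@pytest.fixture(scope="session")
def protocol():
    return phantom_protocol()


@pytest.fixture(scope="session")
def mc(protocol, consts):
    return measurement_constants(protocol, consts)


@pytest.fixture(scope="session")
def wm_params():
    """White-matter-like reference tissue."""
    return TissueParams(i0=1.0, t1f=1.1, f=0.12, kf=2.5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_operator(rng):
    """Random coils + mask + image series on a small grid, for operator tests."""
    nx, ny, nz, nc, nm = 16, 12, 2, 3, 4
    maps = rng.normal(size=(nc, nx, ny, nz)) + 1j * rng.normal(size=(nc, nx, ny, nz))
    maps /= np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    C = CoilSensitivities(maps, np.ones((nx, ny, nz), bool))
    mask = make_vd_gaussian_mask((nx, ny), 2, 4, seed=3)
    return C, mask, (nm, nx, ny, nz)
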
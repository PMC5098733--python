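import numpy as np
import pytest

from pdtmri import (
    AcquisitionProtocol,
    VoxelGrid,
    build_phantom,
    default_aif,
)


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def aif(protocol):
    return default_aif(onset_s=protocol.injection_time_s)


@pytest.fixture(scope="session")
def small_grid():
    """Small in-plane grid for fast unit tests."""
    return VoxelGrid(12, 12, 4, dx_mm=40 / 12, dy_mm=40 / 12)


@pytest.fixture(scope="session")
def small_phantom(small_grid):
    return build_phantom(small_grid, seed=11)


@pytest.fixture(scope="session")
def study_grid():
    """The 32x32x8 grid used for recovery studies."""
    return VoxelGrid(32, 32, 8, dx_mm=40 / 32, dy_mm=40 / 32)


@pytest.fixture(scope="session")
def study_phantom(study_grid):
    return build_phantom(study_grid, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
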
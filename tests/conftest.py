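
import pytest

from boldcvr import (
    NoiseModel,
    ResponseProfile,
    WindowDesign,
    make_demo_atlas,
)

# small grids used throughout: same brain-to-grid proportions as the full
# reference geometry, scaled down so suites stay fast
SMALL_SHAPE = (32, 32, 10)
SMALL_FRAC = (0.45, 0.30, 0.46)


@pytest.fixture(scope="session")
def tiny_atlas():
    """4 leaf regions in 2 composites on a 16x16x6 grid."""
    return make_demo_atlas(
        shape=(16, 16, 6),
        voxel_size=(0.3125, 0.3125, 1.0),
        composites={"ctx": 2, "sub": 2},
        semiaxis_frac=(0.45, 0.35, 0.45),
    )


@pytest.fixture(scope="session")
def small_atlas():
    """Full 171-region hierarchy on a cropped 32x32x10 grid (~2600 voxels)."""
    return make_demo_atlas(
        shape=SMALL_SHAPE,
        voxel_size=(0.3125, 0.3125, 1.0),
        semiaxis_frac=SMALL_FRAC,
    )


@pytest.fixture
def short_window():
    """Window design scaled to 30-volume series (10 volumes per block)."""
    return WindowDesign(baseline=(1, 10), challenge=(11, 20), recovery=(21, 30))


@pytest.fixture
def quiet_noise():
    """Noise-free model (drift off too) for exactness tests."""
    return NoiseModel(sigma=0.0, rho=0.0, drift_per_volume=0.0)


@pytest.fixture
def flat_profile():
    return ResponseProfile(amplitude=0.0)
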
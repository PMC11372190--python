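import numpy as np
import pytest

from pvat.phantom import AneurysmSpec, FatProfile, PhantomConfig, generate_phantom


def cylinder_mask(shape=(40, 40, 60), radius=5.0, center=(20, 20), z_range=None):
    """Binary z-aligned cylinder in voxel units (spacing applied by caller)."""
    ii, jj = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    disk = (ii - center[0]) ** 2 + (jj - center[1]) ** 2 <= radius**2
    mask = np.zeros(shape, dtype=bool)
    zlo, zhi = z_range if z_range is not None else (0, shape[2])
    mask[:, :, zlo:zhi] = disk[:, :, None]
    return mask


@pytest.fixture(scope="session")
def aaa_phantom():
    """Noise-free AAA phantom with distinct close/distant fat bands."""
    config = PhantomConfig(
        aneurysm=AneurysmSpec(center_s_mm=30.0, length_mm=24.0, max_radius_mm=12.0),
        fat_profile=FatProfile(inner=-75, close=-75, gap=-80, distant=-85, outer=-85),
    )
    volume, truth = generate_phantom(config)
    return config, volume, truth


@pytest.fixture(scope="session")
def control_phantom():
    config = PhantomConfig(
        fat_profile=FatProfile(inner=-75, close=-75, gap=-80, distant=-85, outer=-85)
    )
    volume, truth = generate_phantom(config)
    return config, volume, truth
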
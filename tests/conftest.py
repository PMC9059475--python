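import numpy as np
import pytest


@pytest.fixture(scope="session")
def digital_sphere():
    """Digital ball, radius 50 voxels, centered between voxels."""
    g = np.arange(120) - 59.5
    x, y, z = np.meshgrid(g, g, g, indexing="ij")
    return x**2 + y**2 + z**2 <= 50.0**2


@pytest.fixture(scope="session")
def digital_cylinder():
    """Digital rod along z, radius 15 voxels, spanning the array."""
    g = np.arange(60) - 29.5
    x, y = np.meshgrid(g, g, indexing="ij")
    mask = np.zeros((60, 60, 60), dtype=bool)
    mask[(x**2 + y**2) <= 15.0**2, :] = True
    return mask


@pytest.fixture(scope="session")
def digital_plate():
    """Plate 20 voxels thick spanning the array in x and y."""
    mask = np.zeros((80, 80, 60), dtype=bool)
    mask[:, :, 20:40] = True
    return mask


@pytest.fixture(scope="session")
def wt_femur():
    from osteomech import phantoms

    return phantoms.make_femur_phantom(
        phantoms.wt_params(seed=1, voxel_spacing_um=20.0)
    )


@pytest.fixture(scope="session")
def ko_femur():
    from osteomech import phantoms

    return phantoms.make_femur_phantom(
        phantoms.ko_params(seed=1, voxel_spacing_um=20.0)
    )
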
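import numpy as np
import pytest

from pats import BinaryMask, PhantomSpec, VolumeImage, generate_thorax_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_volume(rng):
    """A 12x32x32 8-bit volume of uniform random intensities."""
    data = rng.integers(0, 256, size=(12, 32, 32), dtype=np.uint8)
    return VolumeImage(data, voxel_size_um=35.0, source="test")


def make_mask(data, voxel_size_um=35.0):
    return BinaryMask(np.asarray(data, dtype=bool), voxel_size_um)


@pytest.fixture(scope="session")
def tiny_thorax():
    """A small (60x96x96) noisy thorax phantom shared across tests."""
    return generate_thorax_phantom(
        PhantomSpec(shape=(60, 96, 96), noise_sd=6.0, seed=11)
    )
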
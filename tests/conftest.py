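import numpy as np
import pytest

from tomotex.phantom import default_materials, generate_phantom, insert_lesion
from tomotex.projector import AcquisitionGeometry, Spectrum
from tomotex.recon import SlabImage
from tomotex.texture import QuantizedROI


@pytest.fixture(scope="session")
def small_phantom():
    """Desk-scale phantom shared across tests (64x64x50 at 1 mm voxels)."""
    return generate_phantom(0.25, (64, 64, 50), seed=7, voxel_size_mm=1.0)


@pytest.fixture(scope="session")
def lesioned_phantom(small_phantom):
    return insert_lesion(small_phantom, 8.0, 25.0, seed=11)


@pytest.fixture(scope="session")
def materials():
    return default_materials()


@pytest.fixture(scope="session")
def mono_spectrum():
    return Spectrum.monoenergetic(20.0)


@pytest.fixture
def small_geometry():
    return AcquisitionGeometry(
        n_projections=5,
        pixel_pitch_mm=1.0,
        detector_shape=(72, 72),
        detector_origin_mm=(-4.0, -4.0),
    )


def make_roi(pixels, levels):
    return QuantizedROI(pixels=np.asarray(pixels, dtype=np.int32), levels=levels)


def make_slab(pixels, mask=None, **kwargs):
    pixels = np.asarray(pixels, dtype=float)
    if mask is None:
        mask = np.ones(pixels.shape, dtype=bool)
    return SlabImage(pixels=pixels, pixel_size_mm=0.27, breast_mask=mask, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
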
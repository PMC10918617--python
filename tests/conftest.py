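import numpy as np
import pytest

from ionrep.msi_data import IonImage, IonImageCube, preprocess_cube


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_cube(rng):
    """Small random raw-intensity cube with a partial pixel mask."""
    intens = rng.gamma(2.0, 1.0, size=(12, 14, 6))
    mz = np.sort(rng.uniform(100, 2000, size=6))
    mask = np.ones((12, 14), dtype=bool)
    mask[0, :3] = False
    return IonImageCube(intensities=intens, mz_values=mz, pixel_mask=mask)


@pytest.fixture
def normalized_cube(random_cube):
    return preprocess_cube(random_cube)


@pytest.fixture
def smooth_image(rng):
    """A normalized smooth blob image, the unit of augmentation."""
    yy, xx = np.mgrid[0:32, 0:32]
    blob = np.exp(-(((yy - 16) ** 2 + (xx - 16) ** 2) / 60.0))
    blob = (blob - blob.min()) / (blob.max() - blob.min())
    return IonImage(pixels=blob, mz=500.0, normalized=True)
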
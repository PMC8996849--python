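import numpy as np
import pytest

from salrad.volume_io import Modality, TumorMask, VolumeImage


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_volume(rng):
    """A 12x10x6 derived volume with mild texture, 1 mm isotropic."""
    return VolumeImage(rng.uniform(0, 10, (12, 10, 6)), (1.0, 1.0, 1.0))


@pytest.fixture
def ellipsoid_mask():
    """Ellipsoid mask centred in a 12x10x6 grid."""
    ii, jj, kk = np.indices((12, 10, 6))
    m = ((ii - 6) / 4.5) ** 2 + ((jj - 5) / 3.5) ** 2 + ((kk - 3) / 2.2) ** 2 <= 1
    return TumorMask(m, (1.0, 1.0, 1.0))


def sphere_mask(shape, center, radius, spacing=(1.0, 1.0, 1.0)):
    grids = np.indices(shape).astype(float)
    acc = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, center, spacing))
    return TumorMask(acc <= radius ** 2, spacing)
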
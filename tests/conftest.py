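import numpy as np
import pytest

from fivol import ImageVolume, RoiMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume():
    """8x6x4 volume with intensities spanning all four tissue classes."""
    rng = np.random.default_rng(7)
    data = rng.uniform(500, 5000, size=(8, 6, 4))
    return ImageVolume(data=data, spacing=(0.5, 0.5, 2.0))


@pytest.fixture
def full_roi(small_volume):
    return RoiMask(mask=np.ones(small_volume.shape, dtype=bool))


def random_volume_and_roi(rng, shape=(20, 20, 10), lo=0.0, hi=10000.0):
    """A random-intensity volume with a random (nonempty) ROI."""
    data = rng.uniform(lo, hi, size=shape)
    roi = rng.random(shape) < 0.6
    if not roi.any():
        roi[tuple(s // 2 for s in shape)] = True
    return (
        ImageVolume(data=data, spacing=tuple(rng.uniform(0.1, 3.0, 3))),
        RoiMask(mask=roi),
    )
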
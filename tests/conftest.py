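import numpy as np
import pytest

from c2fseg import ImageVolume, LabelVolume, PhantomConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_phantom_config():
    return PhantomConfig(shape=(16, 32, 32), seed=5)


@pytest.fixture
def random_volume(rng):
    return ImageVolume(data=rng.normal(500.0, 300.0, size=(6, 10, 8)),
                       spacing=(0.5, 0.4, 0.3))


def random_mask_pair(rng, shape=(12, 12, 12), spacing=(1.0, 1.0, 1.0)):
    """Two random blobby nonempty masks with shared geometry."""
    def blob():
        while True:
            m = rng.random(shape) < 0.08
            # dilate once to get connected-ish blobs
            from scipy import ndimage
            m = ndimage.binary_dilation(m)
            if m.any():
                return m.astype(np.uint8)
    return (LabelVolume(data=blob(), spacing=spacing),
            LabelVolume(data=blob(), spacing=spacing))
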
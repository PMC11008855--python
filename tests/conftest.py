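import numpy as np
import pytest

from hybridpath import PhantomSpec, make_phantom


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def disk_mask():
    """Centered digital disk of radius 30 in a 128×128 frame."""
    rr, cc = np.mgrid[0:128, 0:128]
    return (((rr - 64) ** 2 + (cc - 64) ** 2) <= 30 ** 2).astype(np.uint8)


@pytest.fixture(scope="session")
def disk_image(disk_mask):
    """Two-level image: bright disk (190) on dark background (60)."""
    return np.where(disk_mask > 0, 190, 60).astype(np.uint8)


@pytest.fixture(scope="session")
def phantom():
    """One benign phantom tile with its ground-truth nuclei mask."""
    img, mask, label = make_phantom(PhantomSpec(seed=42))
    return img, mask, label
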
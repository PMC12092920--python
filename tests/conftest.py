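import numpy as np
import pytest

from mammodiff.images import BreastMask, GrayImage


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def small_breast_image():
    """A tiny bright breast-like half-disc on black background (8-bit)."""
    h, w = 120, 100
    rr, cc = np.mgrid[0:h, 0:w]
    mask = ((rr - h / 2) ** 2 / (0.45 * h) ** 2 + cc**2 / (0.8 * w) ** 2) < 1.0
    pixels = np.zeros((h, w), dtype=np.uint8)
    pixels[mask] = 180
    img = GrayImage(pixels=pixels, view="CC", laterality="L", bits_stored=8)
    return img, BreastMask(pixels=mask)


def random_mask(rng, h, w, p=0.6):
    """A random blobby binary mask used by the ROI oracles."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.standard_normal((h, w)), 3.0)
    mask = field > np.quantile(field, 1 - p)
    if not mask.any():
        mask[h // 2, w // 2] = True
    return mask
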
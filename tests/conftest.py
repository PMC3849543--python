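"""Shared fixtures: small geometric masks and scenes built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from angiopath import BinaryMask, RasterImage


def draw_disc(shape, centre, radius):
    """Boolean disc: pixel centres within ``radius`` of ``centre`` (x, y)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(xx - centre[0], yy - centre[1]) <= radius


def draw_annulus(shape, centre, r_in, r_out, arc=None):
    """Boolean annulus; ``arc=(start_deg, extent_deg)`` erases a gap."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dist = np.hypot(xx - centre[0], yy - centre[1])
    ring = (dist <= r_out) & (dist > r_in)
    if arc is not None:
        ang = np.degrees(np.arctan2(yy - centre[1], xx - centre[0])) % 360.0
        ring &= ~(((ang - arc[0]) % 360.0) < arc[1])
    return ring


def random_blob_mask(rng, shape=(40, 40), density=0.28) -> BinaryMask:
    """Random blobby binary mask (closing removes salt noise)."""
    from scipy import ndimage as ndi

    m = rng.random(shape) < density
    return BinaryMask.from_bool(ndi.binary_closing(m))


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def annulus_mask():
    """One thick closed ring, 120x120."""
    return BinaryMask.from_bool(draw_annulus((120, 120), (60, 60), 22, 34))


@pytest.fixture
def brown_annulus_image():
    """RGB image: one 60-px brown annulus with bright lumen on pale ground."""
    img = np.empty((128, 128, 3), dtype=np.uint8)
    img[:] = (242, 228, 232)
    ring = draw_annulus((128, 128), (64, 64), 20, 30)
    lumen = draw_disc((128, 128), (64, 64), 20)
    img[ring] = (150, 90, 40)
    img[lumen] = (250, 250, 250)
    return RasterImage(img, "RGB")
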
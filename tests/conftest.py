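import numpy as np
import pytest

from hrdquant.geometry import FieldGeometry


@pytest.fixture
def geo_small() -> FieldGeometry:
    """128 x 128 px field at 3 um/px (384 x 384 um)."""
    side_deg = 128 * 3.0 / 288.0
    return FieldGeometry(width_deg=side_deg, height_deg=side_deg, um_per_deg=288.0, um_per_px=3.0)


def make_disc_mask(geometry: FieldGeometry, centres_um, radius_um):
    """Binary mask with discs at the given (x_um, y_um) centres: a pixel is
    set iff its centre lies within the radius."""
    p = geometry.um_per_px
    nrows, ncols = geometry.shape
    ii, jj = np.mgrid[0:nrows, 0:ncols]
    x = (jj + 0.5) * p
    y = (ii + 0.5) * p
    mask = np.zeros((nrows, ncols), dtype=bool)
    radii = np.broadcast_to(np.asarray(radius_um, dtype=float), (len(centres_um),))
    for (cx, cy), r in zip(centres_um, radii):
        mask |= (x - cx) ** 2 + (y - cy) ** 2 <= r**2
    return mask


@pytest.fixture
def disc_mask_factory():
    return make_disc_mask
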
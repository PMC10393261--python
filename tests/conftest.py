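import numpy as np
import pytest

from synapsekit import ChannelImage, make_rough_mask, mask_to_cell


@pytest.fixture(scope="session")
def disk_cell():
    """Digitised disk of radius 50 px as a CellMask."""
    return mask_to_cell(make_rough_mask((50.0, 50.0)))


@pytest.fixture()
def stripe_image():
    """Factory for stripe patterns at a given axial angle (radians).

    The stripes run along the direction (sin theta, cos theta) in
    (row, col); theta = 0 gives horizontal stripes.
    """

    def make(theta: float, size: int = 96, period_px: float = 9.0) -> ChannelImage:
        rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
        k = 2 * np.pi / period_px
        intensity = 100 + 50 * np.sin(k * (rr * np.cos(theta) - cc * np.sin(theta)))
        return ChannelImage(intensity, 0.1)

    return make


@pytest.fixture()
def square_cell():
    """Square mask covering most of a 96x96 raster."""
    mask = np.zeros((96, 96), dtype=bool)
    mask[8:88, 8:88] = True
    return mask_to_cell(mask)
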
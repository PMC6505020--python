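import numpy as np
import pytest

from susiq.anatomy import StriatalGeometry, make_roi_set
from susiq.grids import TEMPLATE_GRID, VoxelGrid

#: Compact grid + half-scale geometry for fast unit tests.
SMALL_GRID = VoxelGrid((48, 56, 48), (2.0, 2.0, 2.0))
SMALL_GEOMETRY = StriatalGeometry().scaled(0.5)


@pytest.fixture(scope="session")
def small_rois():
    return make_roi_set(SMALL_GRID, SMALL_GEOMETRY)


@pytest.fixture(scope="session")
def template_rois():
    """Full default template-grid ROI set (91 x 109 x 91 at 2 mm)."""
    return make_roi_set(TEMPLATE_GRID)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
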
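import numpy as np
import pytest
from hypothesis import settings

import memphys as m

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def control():
    return m.make_preset("control")


@pytest.fixture(scope="session")
def gaucher():
    return m.make_preset("gaucher")


@pytest.fixture(scope="session")
def control_cell_field(control):
    """One simulated 100-cell field plus its truth (shared across tests)."""
    return m.simulate_cell_field(control, seed=1)


@pytest.fixture(scope="session")
def control_segmentation(control_cell_field):
    img, _truth = control_cell_field
    nuclei = m.detect_nuclei(img.dapi)
    return m.segment_cells(img.membrane, nuclei, thicken_px=5)


def paint_disk_pools(shape, centers, radii, pools, total=1.0e6):
    """Paint per-cell intensity pools (list of (inner, outer, share) radial
    bands, radii relative so negative values count from the cell radius)."""
    img = np.zeros(shape)
    for c, R in zip(centers, radii):
        cy, cx = c
        b = int(np.ceil(R)) + 6
        y0, y1, x0, x1 = int(cy) - b, int(cy) + b + 1, int(cx) - b, int(cx) + b + 1
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dist = np.hypot(yy - cy, xx - cx)
        box = (slice(y0, y1), slice(x0, x1))
        for inner, outer, share in pools:
            lo = inner if inner >= 0 else R + inner
            hi = outer if outer >= 0 else R + outer
            mask = (dist >= lo) & (dist <= hi)
            img[box][mask] += share * total / mask.sum()
    return img
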
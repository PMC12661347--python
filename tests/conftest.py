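import numpy as np
import pytest

from catrack import synthetic as syn
from catrack.masks import CellMask


@pytest.fixture
def small_field():
    """A compact single-plane field with 1 μm pixels for fast rendering."""
    return syn.generate_field(
        12, seed=11, fov_um=(128.0, 128.0), pixel_size_um=(1.0, 1.0),
        n_planes=1, min_separation_um=20.0, z_jitter_um=2.0,
        structural_fraction=0.6,
    )


@pytest.fixture
def rendered_session(small_field):
    truth = syn.make_session_truth(small_field, 600, seed=12,
                                   spike_rate_hz=0.2)
    session, true_traces = syn.render_session(small_field, truth, 600)
    return small_field, truth, session, true_traces


def masks_from_field(field, radius_px=4, shape=None):
    """Ground-truth disk masks centered on each cell's centroid."""
    shape = shape or field.shape_px
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    masks = []
    for cell, (r, c) in zip(field.cells, field.centroids_px()):
        disk = (rr - r) ** 2 + (cc - c) ** 2 <= radius_px ** 2
        masks.append(CellMask(pixels=np.argwhere(disk),
                              plane_index=cell.plane_index))
    return masks
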
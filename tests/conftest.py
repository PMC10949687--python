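import numpy as np
import pytest

from nichespan import AnnotationMatrix, MultiSliceSet, SpatialSlice


def make_slice(coords, labels, slice_id="s1", cell_types=None, resolution="single_cell"):
    coords = np.asarray(coords, dtype=float)
    ann = AnnotationMatrix.from_labels(labels, cell_types)
    obs_ids = tuple(f"{slice_id}_o{i}" for i in range(len(labels)))
    return SpatialSlice(slice_id, obs_ids, coords, ann, resolution)


def make_spot_slice(coords, proportions, cell_types, slice_id="s1"):
    coords = np.asarray(coords, dtype=float)
    ann = AnnotationMatrix(np.asarray(proportions, float), tuple(cell_types))
    obs_ids = tuple(f"{slice_id}_o{i}" for i in range(coords.shape[0]))
    return SpatialSlice(slice_id, obs_ids, coords, ann, "spot")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def grid_slice():
    """5x5 unit-spaced square grid of spots with mixed proportions."""
    xs, ys = np.meshgrid(np.arange(5.0), np.arange(5.0))
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    props = np.tile([0.5, 0.5], (25, 1))
    return make_spot_slice(coords, props, ["A", "B"], slice_id="grid")


def random_simplex(rng, n, t):
    x = rng.gamma(1.0, size=(n, t))
    return x / x.sum(axis=1, keepdims=True)
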
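import numpy as np
import pytest

from arborview.pointcloud_io import PointCloud


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cloud(rng):
    """A 500-point cloud shaped vaguely like a tree (taller than wide)."""
    pts = np.column_stack(
        (
            rng.normal(0, 1.0, 500),
            rng.normal(0, 1.0, 500),
            rng.uniform(0, 15.0, 500),
        )
    )
    return PointCloud(points=pts, tree_id="fixture_tree")
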
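import numpy as np
import pytest

from atlastrace import synthetic
from atlastrace.atlas import Atlas, AtlasVolume, RegionNode, RegionTable


@pytest.fixture(scope="session")
def toy_atlas():
    """Seeded toy atlas + its ground-truth manifest (shared, read-only)."""
    atlas, manifest = synthetic.make_toy_atlas(seed=1)
    return atlas, manifest


@pytest.fixture(scope="session")
def synth_dataset(tmp_path_factory):
    """Full synthetic dataset on disk + ground truth (shared, read-only)."""
    out = tmp_path_factory.mktemp("synth")
    truth = synthetic.simulate_all(out, seed=1)
    return out, truth


@pytest.fixture
def tiny_atlas():
    """Hand-constructed 12x12x12 atlas: one parent with two disjoint child blocks."""
    labels = np.zeros((12, 12, 12), dtype=np.int32)
    labels[1:3, 1:3, 1:3] = 11   # child A: 8 voxels
    labels[5:9, 5:9, 5:9] = 12   # child B: 64 voxels
    table = RegionTable([
        RegionNode(1, "root", "root", None),
        RegionNode(10, "P", "parent", 1),
        RegionNode(11, "A", "child A", 10),
        RegionNode(12, "B", "child B", 10),
    ])
    return Atlas(AtlasVolume(labels, 100.0), table)
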
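import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from mfnorm import VolumeGrid


def make_blob_volume(
    shape=(32, 32, 16),
    blobs=(
        ((8, 8, 8), 2.5),
        ((24, 10, 6), 2.5),
        ((16, 24, 10), 3.0),
        ((10, 20, 12), 2.2),
        ((24, 24, 5), 2.5),
    ),
    affine=None,
) -> VolumeGrid:
    """Smooth multi-blob test image with texture spread across the grid."""
    coords = np.indices(shape, dtype=float)
    vol = np.zeros(shape)
    for centre, width in blobs:
        d2 = sum((coords[a] - centre[a]) ** 2 for a in range(3))
        vol += np.exp(-d2 / (2 * width**2))
    return VolumeGrid(vol, affine if affine is not None else np.eye(4))


@pytest.fixture(scope="session")
def blob_volume() -> VolumeGrid:
    return make_blob_volume()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
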
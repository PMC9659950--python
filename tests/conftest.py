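import numpy as np
import pytest

from rehoflow.grid import Volume4D


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_volume(data, tr: float = 2.0, mask=None, voxel_mm: float = 3.0) -> Volume4D:
    """Wrap a 4D array as a Volume4D with a diagonal affine."""
    data = np.asarray(data)
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    affine = np.diag([voxel_mm] * 3 + [1.0])
    return Volume4D(data=data, affine=affine, tr=tr, mask=np.asarray(mask, bool))


@pytest.fixture
def noise_volume(rng):
    """A small independent-noise volume (float64 for exact oracles)."""
    return make_volume(rng.standard_normal((6, 6, 6, 40)))
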
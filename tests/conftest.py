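import numpy as np
import pytest

from cogplast.volgrid import Mask, Timeseries4D, VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def small_grid(rng):
    return VolumeGrid(values=rng.normal(size=(8, 8, 8)), voxel_size=(2.0, 2.0, 2.0))


@pytest.fixture
def full_mask():
    return Mask(np.ones((8, 8, 8), dtype=bool))


@pytest.fixture
def random_timeseries(rng):
    """64-voxel, 120-frame noise timeseries (no structure)."""
    return Timeseries4D(values=rng.normal(size=(4, 4, 4, 120)), frame_interval=1.4)


def pearson_matrix(data):
    """Explicit correlation matrix of (N, T) rows — shared oracle helper."""
    z = (data - data.mean(axis=1, keepdims=True)) / data.std(axis=1, keepdims=True)
    return z @ z.T / (data.shape[1] - 1)
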
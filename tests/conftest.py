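import numpy as np
import pytest

from vegdyn.grid import Grid, GridTransform


@pytest.fixture
def unit_transform():
    """1 m cells, origin at (0, 10) so a 10-row grid spans y in (0, 10)."""
    return GridTransform(0.0, 10.0, 1.0, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def make_grid(values, transform=None, mask=None, cell=1.0):
    values = np.asarray(values, dtype=float)
    if transform is None:
        transform = GridTransform(0.0, values.shape[0] * cell, cell, cell)
    return Grid(values, transform, mask)


@pytest.fixture
def grid_factory():
    return make_grid
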
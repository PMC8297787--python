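import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from cromics.grid import GridSpec, build_grid


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def grid_2d():
    """A 10x10 CN / 20x20 IbM monolayer grid."""
    return build_grid(GridSpec(nx=10, ny=10, nz=1, dx=0.05, dz=0.009,
                               coarse_factor=2, dims=2))


@pytest.fixture
def grid_3d():
    """A 4x4x8 CN / 8x8x16 IbM cubic grid."""
    return build_grid(GridSpec(nx=4, ny=4, nz=8, dx=0.0114, coarse_factor=2,
                               dims=3))
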
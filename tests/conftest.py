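import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from svzprox.mask_io import MaskVolume
from svzprox.synthetic import SyntheticCohortSpec, make_ventricle_phantom


ANISO = np.diag([0.6, 0.6, 5.0, 1.0])


@pytest.fixture(scope="session")
def phantom():
    """Default labeled ventricle phantom, shared across tests."""
    return make_ventricle_phantom(SyntheticCohortSpec())


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def voxel_mask(indices, shape=(10, 10, 6), affine=ANISO, labels=None):
    """MaskVolume with foreground at the given voxel indices."""
    data = np.zeros(shape, dtype=np.int16)
    for n, ijk in enumerate(indices):
        data[tuple(ijk)] = 1 if labels is None else labels[n]
    return MaskVolume(data, affine)
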
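import numpy as np
import pytest

from petrad.features import DiscretizationSpec, DiscretizedVOI
from petrad.volumes import PETVolume, VOIMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_discretized(levels_3d, n_bins=None):
    """Wrap a hand-built integer level array (-1 = out of mask) as a
    DiscretizedVOI on a 1 mm grid."""
    levels = np.asarray(levels_3d, dtype=np.int64)
    if levels.ndim != 3:
        raise ValueError("need a 3D level array")
    n_bins = n_bins or max(2, int(levels.max()))
    spec = DiscretizationSpec(n_bins=n_bins, lower_bound=0.0, upper_bound=float(n_bins))
    mask = VOIMask(levels >= 0, (1.0, 1.0, 1.0))
    return DiscretizedVOI(levels, spec, mask, (1.0, 1.0, 1.0))


def random_discretized(rng, shape=(5, 5, 5), n_levels=6, p_mask=0.7):
    """Random small discretized VOI for oracle-equivalence sweeps."""
    levels = rng.integers(0, n_levels, size=shape).astype(np.int64)
    mask = rng.uniform(size=shape) < p_mask
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    levels[~mask] = -1
    return make_discretized(levels, n_bins=n_levels)


@pytest.fixture
def constant_volume():
    vol = PETVolume(np.full((6, 6, 6), 10.0), (1.0, 1.0, 1.0))
    mask = VOIMask(np.ones((6, 6, 6), dtype=bool), (1.0, 1.0, 1.0))
    return vol, mask
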
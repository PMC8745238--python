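import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from crclm_fm.phantoms import PhantomConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20211231)


@pytest.fixture
def small_config():
    """A fast phantom configuration for unit tests (not the study shape)."""
    return PhantomConfig(
        n_controls=3,
        n_cases=2,
        slices_per_patient=(4, 6),
        image_shape=(32, 32),
        roi_radius_px=10,
        seed=7,
    )


def random_roi(rng, shape=(6, 6), n_levels=4, mask_density=0.8):
    """A random quantised ROI: levels in 1..n_levels, 0 outside the mask."""
    mask = rng.uniform(size=shape) < mask_density
    if not mask.any():
        mask[shape[0] // 2, shape[1] // 2] = True
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    return levels, mask
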
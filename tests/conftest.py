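import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_roi_factory():
    """Random small discretized ROIs for oracle-equivalence checks."""
    from radpath.radiomics.types import DiscretizedROI

    def make(seed: int, max_side: int = 5, n_levels: int = 5):
        r = np.random.default_rng(seed)
        shape = tuple(int(s) for s in r.integers(2, max_side + 1, 3))
        levels = r.integers(1, n_levels + 1, shape)
        mask = r.random(shape) < 0.8
        if not mask.any():
            mask[0, 0, 0] = True
        levels = np.where(mask, levels, 0)
        return DiscretizedROI(levels, mask, n_levels, np.arange(n_levels + 1.0))

    return make
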
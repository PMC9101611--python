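import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from lesiontex.imaging_io import ROI
from lesiontex.preprocess import QuantizedROI


@pytest.fixture
def rng():
    return np.random.default_rng(20220429)


@pytest.fixture
def random_roi(rng):
    """A 64x64 ROI of clipped Gaussian texture."""
    px = np.clip(rng.normal(128, 30, (64, 64)), 0, 255).astype(np.uint8)
    return ROI(px)


def make_quantized(levels: np.ndarray, ng: int) -> QuantizedROI:
    """Wrap an explicit level array (values in [1, ng]) as a QuantizedROI."""
    levels = np.asarray(levels, dtype=np.int64)
    return QuantizedROI(levels, ng=ng, mu=0.0, sigma=1.0)


@pytest.fixture
def quantized_factory():
    return make_quantized
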
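import numpy as np
import pytest

from crystalsight.features import default_registry
from crystalsight.frames import GrayFrame
from crystalsight.synth import ExperimentConfig


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def random_frame(rng):
    """A small random frame for oracle comparisons."""
    def make(rows=9, cols=9):
        return GrayFrame(rng.integers(0, 256, size=(rows, cols), dtype=np.uint8))
    return make


@pytest.fixture
def constant_frame():
    def make(value=128, rows=16, cols=16):
        return GrayFrame(np.full((rows, cols), value, dtype=np.uint8))
    return make


@pytest.fixture(scope="session")
def small_cfg():
    """Small-geometry experiment configuration for rendering tests."""
    return ExperimentConfig(profile=(), image_shape=(96, 128), seed=11)
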
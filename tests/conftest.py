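import warnings

import numpy as np
import pytest

# the fill-and-flag rule for sub-256 ROIs warns on every extraction; tests
# exercise it explicitly where it matters
warnings.filterwarnings(
    "ignore", message="image supports only", category=RuntimeWarning
)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_int_image(seed: int, shape=(8, 8), levels: int = 256) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, levels, shape).astype(np.float64)


def random_float_image(seed: int, shape=(8, 8)) -> np.ndarray:
    return np.random.default_rng(seed).random(shape) * 100.0
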
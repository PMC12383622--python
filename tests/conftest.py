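import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_boxes(rng, n, span=100.0, min_side=2.0, max_side=30.0):
    """n random valid (x1, y1, x2, y2) boxes inside [0, span]^2."""
    x1 = rng.uniform(0, span - max_side, n)
    y1 = rng.uniform(0, span - max_side, n)
    w = rng.uniform(min_side, max_side, n)
    h = rng.uniform(min_side, max_side, n)
    return np.stack([x1, y1, x1 + w, y1 + h], axis=1)
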
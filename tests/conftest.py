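import numpy as np
import pytest

from iterstereo.params import MatchParams
from iterstereo.types import StereoPair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """Matcher parameters scaled to the tiny test scenes."""
    return MatchParams(
        er=3, br=3, median_radius=3, sigma_g=3.0, d_min_global=0, d_max_global=24
    )


def random_pair(rng, h=12, w=16, frame_index=0):
    left = rng.random((h, w, 3))
    right = rng.random((h, w, 3))
    return StereoPair(left, right, frame_index)


def shifted_pair(rng, h=16, w=32, d=4):
    """Left image random, right image an exact horizontal shift by d."""
    canvas = rng.random((h, w + d, 3))
    left = canvas[:, :w]
    right = canvas[:, d : d + w]
    return StereoPair(left, right)
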
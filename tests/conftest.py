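import numpy as np
import pytest

from prehear.movie import DFFMovie, MovieStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def constant_movie():
    return MovieStack(np.full((50, 8, 8), 100.0), frame_rate=2.0, um_per_px=1.0)


def make_dff(dff_values, frame_rate=10.0, um_per_px=1.0):
    """Wrap a raw dF/F array in a DFFMovie without normalization."""
    dff_values = np.asarray(dff_values, dtype=float)
    return DFFMovie(dff_values, np.ones(dff_values.shape[1:]), frame_rate, um_per_px)
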
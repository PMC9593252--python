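import numpy as np
import pytest

from ncd import PointPattern, Window


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_window():
    return Window.square(2000.0)  # 2 x 2 um


@pytest.fixture
def random_pattern(rng, small_window):
    pts = rng.uniform(0, 2000, size=(30, 2))
    return PointPattern(pts, small_window)
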
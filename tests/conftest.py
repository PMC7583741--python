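import numpy as np
import pytest

from copsense.pressure_video import PressureVideo


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_video(rng):
    """3-frame 7x20-ish random video with a few empty frames possible."""
    frames = rng.uniform(0.0, 50.0, size=(3, 20, 7))
    return PressureVideo(frames)


def make_video(frames, **kw):
    return PressureVideo(np.asarray(frames, dtype=float), **kw)
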
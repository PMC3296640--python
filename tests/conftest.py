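import numpy as np
import pytest

from wcetex.config import PipelineConfig
from wcetex.image_io import HSVFrame, RawFrame
from wcetex.synthetic_data import SynthConfig, generate_frame


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_frame(rng):
    """One 64x64 synthetic normal frame."""
    frame, _ = generate_frame(SynthConfig(size=64, seed=5), "normal", rng)
    return frame


@pytest.fixture
def abnormal_frame(rng):
    frame, _ = generate_frame(SynthConfig(size=64, seed=5), "abnormal", rng)
    return frame


@pytest.fixture
def hsv_frame(rng):
    """A random full-mask HSV frame for descriptor-level tests."""
    channels = rng.random((3, 32, 32))
    return HSVFrame(channels=channels, mask=np.ones((32, 32), dtype=bool))


@pytest.fixture
def default_cfg():
    return PipelineConfig()


def random_raw_frame(rng, size=32):
    return RawFrame(pixels=rng.integers(0, 256, size=(size, size, 3), dtype=np.uint8))
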
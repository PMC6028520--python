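import numpy as np
import pytest

from dropfreq import SyntheticVideoConfig, generate_video

#: Small-geometry keyword arguments shared by fast fixtures.
SMALL_GEOMETRY = dict(
    resolution=(32, 128),
    channel_width=20,
    droplet_diameter=10.0,
    spacing_px=22.0,
)


def make_clip(frequency_hz, frame_rate, n_frames, seed, **overrides):
    """Generate a small stable synthetic clip and its ground truth."""
    kwargs = {**SMALL_GEOMETRY, **overrides}
    cfg = SyntheticVideoConfig.stable(
        frequency_hz, frame_rate, n_frames, seed=seed, **kwargs
    )
    return generate_video(cfg)


@pytest.fixture(scope="session")
def stable_clip():
    """A 200 Hz clip sampled at 1500 fps for 600 frames (period 7.5 frames)."""
    stack, truth = make_clip(200.0, 1500.0, 600, seed=3)
    return stack, truth


@pytest.fixture(scope="session")
def exact_period_clip():
    """Noise- and jitter-free 150 Hz at 1500 fps: period exactly 10 frames."""
    stack, truth = make_clip(
        150.0, 1500.0, 400, seed=11, noise_sigma=0.0, jitter=0.0
    )
    return stack, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
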
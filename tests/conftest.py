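import numpy as np
import pytest

from eegfiction.io import Montage, Recording
from eegfiction.simulate import (
    DesignSpec,
    NoiseSpec,
    scaled_group_sizes,
    small_montage,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tone_recording(
    freq_hz: float,
    duration_s: float = 20.0,
    fs: float = 500.0,
    n_channels: int = 4,
    amplitude: float = 1.0,
) -> Recording:
    """A recording whose every channel is one pure sinusoid."""
    t = np.arange(int(duration_s * fs)) / fs
    x = amplitude * np.sin(2 * np.pi * freq_hz * t)
    montage = Montage(tuple(f"CH{i}" for i in range(n_channels)))
    return Recording("tone", montage, fs, np.tile(x, (n_channels, 1)))


def small_design(
    n_participants: int = 2,
    n_trials: int = 2,
    montage_size: int = 8,
    duration=(4.0, 6.0),
    **kwargs,
) -> DesignSpec:
    """A reduced design for fast tests: fewer participants/trials, shorter
    stimuli, smaller montage; group sizes keep the study's proportions."""
    kwargs.setdefault("noise", NoiseSpec(
        pink_scale_uv=3.0, sensor_white_uv=1.5,
        blink_rate_hz=0.1, muscle_burst_rate_hz=0.05,
    ))
    kwargs.setdefault("seed", 7)
    return DesignSpec(
        n_participants=n_participants,
        n_trials=n_trials,
        stimulus_duration_s=duration,
        montage=small_montage(montage_size),
        group_sizes=scaled_group_sizes(n_participants),
        **kwargs,
    )
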
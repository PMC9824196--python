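import numpy as np
import pytest

from gutsound import AudioClip, SceneConfig, generate_scene


@pytest.fixture(scope="session")
def tone_clip() -> AudioClip:
    """1 s of a 440 Hz tone at 48 kHz, half amplitude."""
    t = np.arange(48_000) / 48_000
    return AudioClip(samples=0.5 * np.sin(2 * np.pi * 440.0 * t), sample_rate_hz=48_000)


@pytest.fixture(scope="session")
def small_scene():
    """A 10 s synthetic scene with ground truth (quiet noise floor)."""
    config = SceneConfig(duration_s=10.0, ssi_mean_s=1.0, ssi_sd_s=0.5, seed=42)
    clip, truth = generate_scene(config)
    return config, clip, truth
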
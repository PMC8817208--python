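"""Shared fixtures: synthetic tones, voices, and AU tables."""

import numpy as np
import pytest

from facevox.signal import AudioSignal
from facevox.synth import VoiceSynthesisParams, synth_voiced_audio

FS = 16000


def make_tone(freq: float, duration: float = 1.0, amplitude: float = 0.8,
              fs: int = FS) -> AudioSignal:
    t = np.arange(int(duration * fs)) / fs
    return AudioSignal(amplitude * np.sin(2 * np.pi * freq * t), fs)


@pytest.fixture(scope="session")
def silence() -> AudioSignal:
    return AudioSignal(np.zeros(FS), FS)


@pytest.fixture(scope="session")
def white_noise() -> AudioSignal:
    rng = np.random.default_rng(1234)
    return AudioSignal(0.1 * rng.standard_normal(2 * FS), FS)


@pytest.fixture(scope="session")
def clean_voice():
    """Steady 150 Hz voice, fully voiced, negligible noise."""
    params = VoiceSynthesisParams(
        f0=150.0, jitter_target=0.0, hnr_target=40.0, voiced_fraction=1.0,
        duration=2.0, seed=3,
    )
    return synth_voiced_audio(params)
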
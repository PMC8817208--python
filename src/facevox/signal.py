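"""Audio signal container, WAV I/O and framing utilities.

All acoustic analysis in this package operates on mono floating-point
waveforms at a fixed analysis rate (16 kHz by default, see
:class:`facevox.acoustics.AcousticConfig`).  Stereo input is downmixed by
channel averaging; integer PCM is rescaled to the nominal [-1, 1] range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AudioSignal:
    """A sampled mono waveform.

    Parameters
    ----------
    samples
        1-D float array, nominal amplitude range -1..1 (not enforced).
    sample_rate
        Sampling rate in Hz, positive integer.
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("AudioSignal requires a 1-D (mono) sample array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("AudioSignal samples must all be finite")
        if int(self.sample_rate) <= 0:
            raise ValueError("sample_rate must be a positive integer")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sample_rate", int(self.sample_rate))

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return len(self.samples) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)

    def resample(self, target_rate: int) -> "AudioSignal":
        """Polyphase resampling to ``target_rate`` Hz (no-op if equal)."""
        if target_rate == self.sample_rate:
            return self
        from math import gcd

        g = gcd(target_rate, self.sample_rate)
        out = resample_poly(self.samples, target_rate // g, self.sample_rate // g)
        return AudioSignal(out, target_rate)

    def scaled(self, factor: float) -> "AudioSignal":
        return AudioSignal(self.samples * factor, self.sample_rate)


@dataclass
class FrameTrack:
    """Per-analysis-frame scalar track (F0, energy, or boolean flags).

    ``strength`` optionally carries the normalized-autocorrelation peak
    height per frame (harmonic strength in [0, 1]) when produced by the
    pitch tracker; it is the substrate of the HNR marker.
    """

    frame_times: np.ndarray  # seconds, frame midpoints, strictly increasing
    values: np.ndarray
    voiced_flags: np.ndarray
    strength: np.ndarray | None = None
    frame_len: float = 0.0  # seconds
    hop: float = 0.0  # seconds

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
        self.values = np.asarray(self.values)
        self.voiced_flags = np.asarray(self.voiced_flags, dtype=bool)
        if len(self.values) != len(self.frame_times):
            raise ValueError("values and frame_times must have equal length")
        if len(self.voiced_flags) != len(self.frame_times):
            raise ValueError("voiced_flags and frame_times must have equal length")
        if len(self.frame_times) > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frame_times)

    @property
    def n_voiced(self) -> int:
        return int(np.count_nonzero(self.voiced_flags))


def read_wav(path) -> AudioSignal:
    """Read a PCM or float WAV file as a mono :class:`AudioSignal`.

    Integer PCM is rescaled to [-1, 1]; stereo is downmixed by averaging
    channels (logged as a warning).
    """
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        logger.warning("stereo WAV %s downmixed to mono by channel averaging", path)
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    return AudioSignal(data, int(rate))


def write_wav(path, signal: AudioSignal) -> None:
    """Write an :class:`AudioSignal` as 16-bit PCM WAV."""
    clipped = np.clip(signal.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(path, signal.sample_rate, pcm)


def frame_signal(signal: AudioSignal, frame_len: float, hop: float) -> np.ndarray:
    """Slice a signal into overlapping analysis frames.

    Returns an array of shape ``(n_frames, L)`` where
    ``n_frames = floor((N - L) / H) + 1``; a final partial frame is
    discarded.  A signal shorter than one frame yields zero frames.
    """
    if frame_len <= 0 or hop <= 0:
        raise ValueError("frame_len and hop must be positive")
    L = int(round(frame_len * signal.sample_rate))
    H = int(round(hop * signal.sample_rate))
    x = signal.samples
    if len(x) < L:
        return np.empty((0, L))
    n = (len(x) - L) // H + 1
    view = np.lib.stride_tricks.sliding_window_view(x, L)[:: H]
    return view[:n]


def frame_midpoints(signal: AudioSignal, frame_len: float, hop: float) -> np.ndarray:
    """Midpoint times (seconds) of the frames produced by :func:`frame_signal`."""
    L = int(round(frame_len * signal.sample_rate))
    H = int(round(hop * signal.sample_rate))
    if len(signal.samples) < L:
        return np.empty(0)
    n = (len(signal.samples) - L) // H + 1
    starts = np.arange(n) * H
    return (starts + L / 2.0) / signal.sample_rate
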
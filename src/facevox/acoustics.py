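"""Vocal acoustic markers from mono audio.

Implements the six per-recording vocal markers used in remote digital
phenotyping of schizophrenia:

* vocal intensity (dB, energy-weighted over speech frames, re 2e-5),
* fundamental frequency mean and standard deviation (Hz, voiced frames),
* local jitter (%, cycle-to-cycle period irregularity),
* harmonics-to-noise ratio (dB, from the normalized autocorrelation peak),
* speech prevalence (% of frames classified as speech).

Pitch is tracked with window-normalized autocorrelation (Boersma-style):
each frame is mean-subtracted, Hann-windowed, its autocorrelation divided
by the window autocorrelation, and the highest interpolated peak inside
the search band is accepted if it clears a voicing threshold.  Degenerate
inputs yield markers that are *missing with a reason*, never NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .enhance import logmmse_enhance
from .signal import AudioSignal, FrameTrack, frame_midpoints, frame_signal

DB_REF = 2e-5  # Praat-style intensity reference, sample-amplitude units
_ENERGY_DB_FLOOR = -200.0
_OCTAVE_TOLERANCE = 0.07  # height slack when preferring shorter-lag peaks


@dataclass(frozen=True)
class AcousticConfig:
    """Tunable parameters of the vocal marker pipeline."""

    f_min: float = 75.0  # Hz, lower pitch search bound
    f_max: float = 500.0  # Hz, upper pitch search bound
    hop: float = 0.01  # s, analysis hop
    voicing_threshold: float = 0.45  # on the normalized autocorrelation peak
    silence_threshold: float = 0.03  # fraction of global peak amplitude
    vad_margin_db: float = 9.0  # speech if energy > noise floor + margin
    noise_seconds: float = 0.3  # LogMMSE initial noise window
    enhance: bool = True  # apply LogMMSE before all marker extraction
    target_rate: int = 16000  # all analysis at this rate


@dataclass(frozen=True)
class MarkerValue:
    """A scalar marker that may be missing with a reason code."""

    value: float | None
    reason: str | None = None

    @property
    def is_missing(self) -> bool:
        return self.value is None

    @staticmethod
    def missing(reason: str) -> "MarkerValue":
        return MarkerValue(None, reason)


@dataclass(frozen=True)
class VocalMarkerSet:
    """The six vocal acoustic markers of one recording."""

    vocal_intensity: MarkerValue
    f0_mean: MarkerValue
    f0_stdev: MarkerValue
    jitter_local: MarkerValue
    hnr: MarkerValue
    speech_prevalence: MarkerValue

    def as_dict(self) -> dict[str, MarkerValue]:
        return {
            "vocal_intensity": self.vocal_intensity,
            "f0_mean": self.f0_mean,
            "f0_stdev": self.f0_stdev,
            "jitter_local": self.jitter_local,
            "hnr": self.hnr,
            "speech_prevalence": self.speech_prevalence,
        }


def _normalized_autocorr(frame: np.ndarray, win: np.ndarray, win_ac: np.ndarray,
                         nfft: int, max_lag: int) -> np.ndarray:
    """Window-normalized autocorrelation of one frame, lags 0..max_lag."""
    x = (frame - frame.mean()) * win
    spec = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(np.abs(spec) ** 2, nfft)[: max_lag + 1]
    if ac[0] <= 0:
        return np.zeros(max_lag + 1)
    return (ac / ac[0]) / win_ac[: max_lag + 1]


def _parabolic_peak(y: np.ndarray, i: int) -> tuple[float, float]:
    """Parabolic interpolation of a local maximum at index ``i``.

    Returns (interpolated position, interpolated height)."""
    if i <= 0 or i >= len(y) - 1:
        return float(i), float(y[i])
    a, b, c = y[i - 1], y[i], y[i + 1]
    denom = a - 2 * b + c
    if denom == 0:
        return float(i), float(b)
    d = 0.5 * (a - c) / denom
    d = float(np.clip(d, -0.5, 0.5))
    return i + d, b - 0.25 * (a - c) * d


def estimate_f0_track(
    signal: AudioSignal, f_min: float = 75.0, f_max: float = 500.0,
    hop: float = 0.01, voicing_threshold: float = 0.45,
    silence_threshold: float = 0.03,
) -> FrameTrack:
    """Framewise fundamental-frequency estimation.

    Frames are ``3 / f_min`` seconds long with a ``hop``-second hop.  A
    frame is voiced when its normalized-autocorrelation peak inside
    ``[f_min, f_max]`` exceeds ``voicing_threshold`` and its amplitude
    clears ``silence_threshold`` of the global peak.  The returned track
    carries F0 values (Hz; NaN where unvoiced) and the per-frame harmonic
    strength (peak height).
    """
    fs = signal.sample_rate
    if not (0 < f_min < f_max < fs / 2):
        raise ValueError("pitch search band infeasible for this sample rate")
    frame_len = 3.0 / f_min
    frames = frame_signal(signal, frame_len, hop)
    times = frame_midpoints(signal, frame_len, hop)
    n = len(frames)
    f0 = np.full(n, np.nan)
    strength = np.zeros(n)
    voiced = np.zeros(n, dtype=bool)
    if n == 0:
        return FrameTrack(times, f0, voiced, strength, frame_len, hop)

    L = frames.shape[1]
    lag_min = max(2, int(np.floor(fs / f_max)))
    lag_max = int(np.ceil(fs / f_min))
    lag_max = min(lag_max, L - 1)
    nfft = int(2 ** np.ceil(np.log2(2 * L)))
    win = np.hanning(L + 1)[:L]
    wspec = np.fft.rfft(win, nfft)
    win_ac = np.fft.irfft(np.abs(wspec) ** 2, nfft)[: lag_max + 2]
    win_ac = np.maximum(win_ac / win_ac[0], 1e-6)

    global_peak = np.max(np.abs(signal.samples))
    if global_peak == 0:
        return FrameTrack(times, f0, voiced, strength, frame_len, hop)

    for i, frame in enumerate(frames):
        if np.max(np.abs(frame)) < silence_threshold * global_peak:
            continue
        rn = _normalized_autocorr(frame, win, win_ac, nfft, lag_max)
        seg = rn[lag_min : lag_max + 1]
        if len(seg) < 3:
            continue
        # candidates = local maxima inside the search band; among peaks of
        # comparable height prefer the shortest lag, which suppresses the
        # double/triple-period (octave-error) peaks that window
        # normalization inflates at large lags
        interior = np.flatnonzero(
            (seg[1:-1] >= seg[:-2]) & (seg[1:-1] >= seg[2:])
        ) + 1
        if len(interior) == 0:
            continue
        heights = np.minimum(seg[interior], 1.0)
        best = interior[heights >= heights.max() - _OCTAVE_TOLERANCE][0]
        pos, height = _parabolic_peak(rn, lag_min + best)
        height = float(min(height, 1.0))
        strength[i] = max(height, 0.0)
        if height >= voicing_threshold and pos > 0:
            cand = fs / pos
            if f_min <= cand <= f_max:
                f0[i] = cand
                voiced[i] = True
    _suppress_octave_outliers(f0, voiced)
    return FrameTrack(times, f0, voiced, strength, frame_len, hop)


def _suppress_octave_outliers(
    f0: np.ndarray, voiced: np.ndarray, rel_tol: float = 0.25, half_window: int = 2
) -> None:
    """Un-voice frames whose F0 deviates >25% from the local voiced median.

    Frames straddling a voicing onset/offset can lock onto a resonance or a
    sub/super-harmonic; a local median test removes these octave-jump
    errors in place (the usual lightweight alternative to Praat's
    dynamic-programming path search).
    """
    ref_f0 = f0.copy()
    ref_voiced = voiced.copy()
    for i in np.flatnonzero(ref_voiced):
        lo, hi = max(0, i - half_window), min(len(f0), i + half_window + 1)
        neigh = ref_f0[lo:hi][ref_voiced[lo:hi]]
        neigh = neigh[np.isfinite(neigh)]
        if len(neigh) >= 3:
            med = np.median(neigh)
            if abs(ref_f0[i] - med) > rel_tol * med:
                voiced[i] = False
                f0[i] = np.nan
    # global octave test: short runs of resonance-locked frames at voicing
    # offsets can dominate their local window; an utterance-level median
    # bound (factor 1.5) removes them without touching plausible F0 range
    remaining = f0[voiced]
    if len(remaining) >= 5:
        med = np.median(remaining)
        bad = voiced & ((f0 > 1.5 * med) | (f0 < med / 1.5))
        voiced[bad] = False
        f0[bad] = np.nan


def f0_summary(track: FrameTrack) -> tuple[MarkerValue, MarkerValue]:
    """Mean and population SD of F0 over voiced frames."""
    v = track.values[track.voiced_flags]
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return MarkerValue.missing("unvoiced"), MarkerValue.missing("unvoiced")
    return MarkerValue(float(np.mean(v))), MarkerValue(float(np.std(v)))


def extract_periods(
    signal: AudioSignal, track: FrameTrack,
    f_min: float = 75.0, f_max: float = 500.0,
) -> np.ndarray:
    """Glottal-cycle durations (seconds) within voiced regions.

    Within each contiguous voiced run, pulses are located by peak-picking:
    starting from the strongest sample, the expected next pulse lies one
    local F0 period away and is searched for within +-1/3 period.  Periods
    outside ``[1/f_max, 1/f_min]`` are discarded.
    """
    fs = signal.sample_rate
    x = signal.samples
    voiced = track.voiced_flags
    if not voiced.any():
        return np.empty(0)
    hop_n = int(round(track.hop * fs))
    half = int(round(track.frame_len * fs / 2))
    periods: list[float] = []
    # contiguous voiced runs of frames
    edges = np.flatnonzero(np.diff(np.concatenate(([0], voiced.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        # bound the search region by the first/last voiced frame *centres*
        # so window tails reaching into silence contribute no pulses
        i0 = max(0, start * hop_n + half)
        i1 = min(len(x), (stop - 1) * hop_n + half)
        if i1 - i0 < 8:
            continue
        run_f0 = track.values[start:stop]
        run_f0 = run_f0[np.isfinite(run_f0)]
        if len(run_f0) == 0:
            continue
        T = fs / float(np.median(run_f0))  # samples per cycle
        seg = x[i0:i1]
        # coarse pulses: peaks of the amplitude envelope (one decaying bump
        # per glottal pulse, robust to resonator ringing)
        env = np.abs(sp_signal.hilbert(seg))
        pulses, _ = sp_signal.find_peaks(env, distance=max(2, int(0.7 * T)))
        if len(pulses) >= 2:
            heights = env[pulses]
            pulses = pulses[heights >= 0.2 * np.median(heights)]
        if len(pulses) < 2:
            continue
        periods.extend(_refine_periods_cc(seg, pulses, T) / fs)
    periods_arr = np.asarray(periods)
    keep = (periods_arr >= 1.0 / f_max) & (periods_arr <= 1.0 / f_min)
    return periods_arr[keep]


def _refine_periods_cc(seg: np.ndarray, pulses: np.ndarray, T: float) -> np.ndarray:
    """Sub-sample period refinement by waveform matching.

    Each period is the lag (near the coarse pulse spacing) maximizing the
    cross-correlation of one cycle-length window with the next cycle —
    insensitive to the envelope-peak bias that overlapping resonator tails
    introduce at close pulse spacings.
    """
    out = []
    h = max(2, int(round(0.8 * T)) // 2)
    span = max(5, int(round(T / 8)))
    for i in range(len(pulses) - 1):
        p = int(pulses[i])
        coarse = int(pulses[i + 1]) - p
        lo, hi = p - h, p + h
        if lo < 0 or hi + coarse + span + 1 > len(seg):
            out.append(float(coarse))
            continue
        a = seg[lo:hi]
        lags = np.arange(coarse - span, coarse + span + 1)
        cc = np.array([np.dot(a, seg[lo + l : hi + l]) for l in lags])
        j = int(np.argmax(cc))
        pos, _ = _parabolic_peak(cc, j)
        out.append(float(lags[0] + pos))
    return np.asarray(out)


def jitter_local(
    periods: np.ndarray, max_period_factor: float = 1.3
) -> MarkerValue:
    """Local jitter: mean absolute consecutive-period difference over the
    mean period, as a percentage (Praat convention).

    Consecutive pairs whose period ratio exceeds ``max_period_factor``
    (Praat's maximum period factor, default 1.3) are treated as
    pulse-detection outliers — e.g. a missed pulse doubling a period — and
    excluded from both the numerator and the denominator.
    """
    periods = np.asarray(periods, dtype=float)
    if len(periods) < 2:
        return MarkerValue.missing("fewer than two glottal periods")
    a, b = periods[:-1], periods[1:]
    valid = np.maximum(a, b) / np.minimum(a, b) <= max_period_factor
    if not valid.any():
        return MarkerValue.missing("no admissible consecutive period pairs")
    mean_abs_diff = np.mean(np.abs(b[valid] - a[valid]))
    # denominator: every period participating in at least one valid pair
    participates = np.zeros(len(periods), dtype=bool)
    participates[:-1] |= valid
    participates[1:] |= valid
    mean_period = np.mean(periods[participates])
    return MarkerValue(float(100.0 * mean_abs_diff / mean_period))


def hnr_db(signal: AudioSignal, track: FrameTrack) -> MarkerValue:
    """Harmonics-to-noise ratio in dB, averaged over voiced frames.

    Per voiced frame the harmonic energy fraction ``r`` is the height of
    the normalized autocorrelation peak at the F0 lag (as stored by the
    pitch tracker), and the frame HNR is ``10 log10(r / (1 - r))``.
    """
    if track.strength is None:
        raise ValueError("track carries no harmonic strength; run estimate_f0_track")
    r = track.strength[track.voiced_flags]
    if len(r) == 0:
        return MarkerValue.missing("unvoiced")
    r = np.clip(r, 1e-6, 1.0 - 1e-6)
    return MarkerValue(float(np.mean(10.0 * np.log10(r / (1.0 - r)))))


def frame_energy_db(signal: AudioSignal, frame_len: float, hop: float) -> np.ndarray:
    """Framewise RMS level in dB re :data:`DB_REF` (floored at -200 dB)."""
    frames = frame_signal(signal, frame_len, hop)
    if len(frames) == 0:
        return np.empty(0)
    rms = np.sqrt(np.mean(frames**2, axis=1))
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(rms / DB_REF)
    return np.maximum(db, _ENERGY_DB_FLOOR)


def detect_speech_frames(
    signal: AudioSignal, track: FrameTrack, vad_margin_db: float = 9.0
) -> FrameTrack:
    """Energy + voicing voice-activity detection.

    A frame is speech when it is voiced, or when its energy exceeds the
    estimated noise floor (10th percentile of frame energies) by
    ``vad_margin_db`` dB.  Energy uses a 20 ms window at the track hop —
    shorter than the pitch frame — so frames straddling a speech/silence
    boundary inflate the speech count by at most about one frame per edge.
    """
    db = frame_energy_db(signal, min(0.02, track.frame_len), track.hop)
    n = min(len(db), len(track))
    db = db[:n]
    if n == 0:
        return FrameTrack(track.frame_times[:0], np.empty(0, bool), np.empty(0, bool))
    noise_floor = np.percentile(db, 10)
    loud = db > noise_floor + vad_margin_db
    flags = loud | track.voiced_flags[:n]
    # a floor-level "loud" frame only means the whole file is near-silent
    if np.max(db) <= _ENERGY_DB_FLOOR:
        flags[:] = False
    return FrameTrack(
        track.frame_times[:n], flags, flags, None, track.frame_len, track.hop
    )


def speech_prevalence(flags: FrameTrack) -> MarkerValue:
    """Percentage of frames classified as speech."""
    if len(flags) == 0:
        return MarkerValue.missing("no analysis frames")
    return MarkerValue(float(100.0 * np.mean(flags.values.astype(bool))))


def intensity_db(
    signal: AudioSignal,
    speech_flags: FrameTrack | None = None,
    frame_len: float = 0.04,
    hop: float = 0.01,
) -> MarkerValue:
    """Energy-weighted mean frame intensity in dB re 2e-5 amplitude units.

    The reference is uncalibrated (no microphone SPL calibration exists for
    remote recordings), so values are comparable only within a study.  When
    ``speech_flags`` is given only speech frames contribute.
    """
    if len(signal) == 0:
        raise ValueError("empty signal")
    if speech_flags is not None:
        frame_len, hop = speech_flags.frame_len, speech_flags.hop
    frames = frame_signal(signal, frame_len, hop)
    if len(frames) == 0:
        frames = signal.samples[None, :]
    energy = np.mean(frames**2, axis=1)
    if speech_flags is not None:
        n = min(len(energy), len(speech_flags))
        mask = speech_flags.values[:n].astype(bool)
        energy = energy[:n][mask]
    energy = energy[energy > 0]
    if len(energy) == 0:
        return MarkerValue.missing("silent")
    db = 10.0 * np.log10(energy / DB_REF**2)
    return MarkerValue(float(np.sum(energy * db) / np.sum(energy)))


def extract_vocal_markers(
    signal: AudioSignal, config: AcousticConfig = AcousticConfig()
) -> VocalMarkerSet:
    """Compute all six vocal markers of one recording.

    The recording is resampled to the analysis rate, enhanced once with
    LogMMSE (unless disabled), and every marker is derived from the
    enhanced waveform.  Deterministic: repeat calls are bit-identical.
    """
    if len(signal) == 0:
        raise ValueError("empty audio")
    sig = signal.resample(config.target_rate)
    if sig.duration < 3.0 / config.f_min:
        raise ValueError("recording shorter than one pitch analysis frame")
    if config.enhance and sig.duration >= config.noise_seconds:
        sig = logmmse_enhance(sig, config.noise_seconds)
    track = estimate_f0_track(
        sig, config.f_min, config.f_max, config.hop,
        config.voicing_threshold, config.silence_threshold,
    )
    f0_mean, f0_stdev = f0_summary(track)
    periods = extract_periods(sig, track, config.f_min, config.f_max)
    jitter = jitter_local(periods)
    hnr = hnr_db(sig, track)
    flags = detect_speech_frames(sig, track, config.vad_margin_db)
    prevalence = speech_prevalence(flags)
    intensity = intensity_db(sig, flags)
    return VocalMarkerSet(
        vocal_intensity=intensity,
        f0_mean=f0_mean,
        f0_stdev=f0_stdev,
        jitter_local=jitter,
        hnr=hnr,
        speech_prevalence=prevalence,
    )
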
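"""LogMMSE speech enhancement.

Log-spectral-amplitude minimum mean-square-error estimator (Ephraim-Malah
log-MMSE gain) with decision-directed a-priori SNR tracking and a simple
likelihood-ratio noise-update rule.  The noise spectrum is initialized from
the first ``noise_seconds`` of the recording and updated during frames the
internal VAD classifies as speech-absent.  Parameters follow the standard
literature defaults: decision-directed smoothing 0.98, gain floored at
10^(-25/20) so residual noise is attenuated by at most 25 dB.
"""

from __future__ import annotations

import numpy as np
from scipy.special import exp1

from .signal import AudioSignal

_ALPHA_DD = 0.98  # decision-directed a-priori SNR smoothing
_NOISE_MU = 0.98  # noise spectrum update smoothing
_VAD_ETA = 0.15  # speech-absence threshold on the mean log-likelihood ratio
_GAIN_FLOOR = 10.0 ** (-25.0 / 20.0)
_KSI_MIN = 10.0 ** (-25.0 / 10.0)


def logmmse_enhance(signal: AudioSignal, noise_seconds: float = 0.3) -> AudioSignal:
    """Denoise a recording with the log-MMSE short-time spectral estimator.

    Parameters
    ----------
    signal
        Mono input waveform.
    noise_seconds
        Length of the initial segment used to seed the noise spectrum
        estimate.  Must be positive and no longer than the signal.

    Returns
    -------
    AudioSignal
        Enhanced waveform with the same length and sample rate.
    """
    if noise_seconds <= 0:
        raise ValueError("noise_seconds must be positive")
    if signal.duration < noise_seconds:
        raise ValueError("signal shorter than the initial noise window")
    fs = signal.sample_rate
    L = int(round(0.02 * fs))  # 20 ms analysis frames
    if L % 2 == 1:
        L += 1
    if len(signal) < L:
        raise ValueError("too short to enhance")
    H = L // 4  # 75% overlap
    nfft = int(2 ** np.ceil(np.log2(2 * L)))
    win = np.hanning(L + 1)[:L]
    win_gain = H / win.sum()  # overlap-add normalization

    x = signal.samples
    n_noise_frames = max(1, int(round(noise_seconds * fs / H)))
    noise_psd = np.zeros(nfft // 2 + 1)
    count = 0
    for j in range(n_noise_frames):
        seg = x[j * H : j * H + L]
        if len(seg) < L:
            break
        spec = np.fft.rfft(win * seg, nfft)
        noise_psd += np.abs(spec) ** 2
        count += 1
    noise_psd /= max(count, 1)
    noise_psd = np.maximum(noise_psd, 1e-20)

    n_frames = (len(x) - L) // H + 1
    out = np.zeros(len(x) + nfft)
    prev_gain2_post = None
    for k in range(n_frames):
        seg = x[k * H : k * H + L]
        spec = np.fft.rfft(win * seg, nfft)
        mag2 = np.abs(spec) ** 2
        gammak = np.minimum(mag2 / noise_psd, 40.0)  # a-posteriori SNR
        if prev_gain2_post is None:
            ksi = _ALPHA_DD + (1 - _ALPHA_DD) * np.maximum(gammak - 1, 0)
        else:
            ksi = _ALPHA_DD * prev_gain2_post + (1 - _ALPHA_DD) * np.maximum(
                gammak - 1, 0
            )
        ksi = np.maximum(_KSI_MIN, ksi)

        # speech-absence decision on the frame-mean log-likelihood ratio
        log_sigma_k = gammak * ksi / (1 + ksi) - np.log1p(ksi)
        if log_sigma_k.mean() < _VAD_ETA:
            noise_psd = _NOISE_MU * noise_psd + (1 - _NOISE_MU) * mag2
            noise_psd = np.maximum(noise_psd, 1e-20)

        a = ksi / (1 + ksi)
        vk = np.maximum(a * gammak, 1e-50)
        gain = a * np.exp(0.5 * exp1(vk))
        gain = np.clip(gain, _GAIN_FLOOR, 1.0)
        prev_gain2_post = gain**2 * gammak

        frame_out = np.fft.irfft(gain * spec, nfft)
        out[k * H : k * H + nfft] += frame_out
    # tail samples beyond the last full frame are kept unframed but attenuated
    # by the floor gain so trailing clicks cannot dominate the output
    tail_start = (n_frames - 1) * H + L if n_frames > 0 else 0
    enhanced = out[: len(x)] * win_gain
    if tail_start < len(x):
        enhanced[tail_start:] = x[tail_start:] * _GAIN_FLOOR
    return AudioSignal(enhanced, fs)
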
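"""Vocal marker estimators against synthesis ground truth and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from facevox.acoustics import (
    AcousticConfig,
    detect_speech_frames,
    estimate_f0_track,
    extract_periods,
    extract_vocal_markers,
    f0_summary,
    hnr_db,
    intensity_db,
    jitter_local,
    speech_prevalence,
)
from facevox.signal import AudioSignal, FrameTrack
from facevox.synth import VoiceSynthesisParams, synth_voiced_audio
from tests.conftest import FS, make_tone


class TestPitchTracking:
    @pytest.mark.parametrize("freq", [100.0, 150.0, 250.0, 400.0])
    def test_steady_tone_recovery(self, freq):
        track = estimate_f0_track(make_tone(freq))
        assert track.n_voiced >= 0.9 * len(track)
        mean, sd = f0_summary(track)
        assert abs(mean.value - freq) <= 0.01 * freq
        assert sd.value < 2.0

    def test_white_noise_mostly_unvoiced(self, white_noise):
        track = estimate_f0_track(white_noise)
        assert track.n_voiced < 0.1 * len(track)

    def test_silence_all_unvoiced(self, silence):
        track = estimate_f0_track(silence)
        assert track.n_voiced == 0

    def test_infeasible_band_errors(self):
        with pytest.raises(ValueError):
            estimate_f0_track(make_tone(100.0), f_min=75.0, f_max=9000.0)

    def test_glide_mean(self):
        # linear glide 100 -> 200 Hz: mean near 150
        t = np.arange(FS) / FS
        phase = 2 * np.pi * np.cumsum(100 + 100 * t) / FS
        track = estimate_f0_track(AudioSignal(0.5 * np.sin(phase), FS))
        mean, _ = f0_summary(track)
        assert abs(mean.value - 150.0) <= 5.0


class TestF0Summary:
    def test_constant_track(self):
        track = FrameTrack(
            np.arange(5) * 0.01, np.full(5, 150.0), np.ones(5, bool)
        )
        mean, sd = f0_summary(track)
        assert mean.value == 150.0 and sd.value == 0.0

    def test_unvoiced_track_missing(self):
        track = FrameTrack(np.arange(5) * 0.01, np.full(5, np.nan), np.zeros(5, bool))
        mean, sd = f0_summary(track)
        assert mean.is_missing and sd.is_missing
        assert mean.reason == "unvoiced"


class TestJitter:
    def test_hand_worked_value(self):
        # mean |dT| = 0.001, mean T = 0.010333 -> 9.677%
        res = jitter_local(np.array([0.010, 0.011, 0.010]))
        assert res.value == pytest.approx(9.677, abs=1e-3)

    def test_constant_periods_zero(self):
        assert jitter_local(np.array([0.010] * 3)).value == 0.0

    def test_single_period_missing(self):
        assert jitter_local(np.array([0.010])).is_missing

    def test_outlier_pair_excluded(self):
        # a doubled period (missed pulse) must not inflate the estimate
        clean = np.full(50, 0.010)
        clean[25] = 0.020
        assert jitter_local(clean).value < 0.5

    @pytest.mark.parametrize("seed", [3, 11])
    def test_programmed_jitter_recovery(self, seed):
        estimates = []
        for target in (0.0, 1.0, 2.0, 4.0):
            params = VoiceSynthesisParams(
                f0=150.0, jitter_target=target, hnr_target=40.0,
                voiced_fraction=1.0, duration=2.0, seed=seed,
            )
            sig, _ = synth_voiced_audio(params)
            track = estimate_f0_track(sig)
            est = jitter_local(extract_periods(sig, track)).value
            estimates.append(est)
            if target > 0:
                assert abs(est - target) <= 0.25 * target
        assert estimates == sorted(estimates)  # strictly increasing
        assert all(np.diff(estimates) > 0)


class TestPeriods:
    def test_pulse_train_periods(self):
        params = VoiceSynthesisParams(
            f0=100.0, jitter_target=0.0, hnr_target=60.0, voiced_fraction=1.0,
            duration=1.0, seed=7,
        )
        sig, _ = synth_voiced_audio(params)
        periods = extract_periods(sig, estimate_f0_track(sig))
        assert len(periods) > 80
        assert np.allclose(periods, 0.010, atol=2e-4)

    def test_perturbed_pulse_train_reproduces_programmed_periods(self):
        # each recovered period matches a programmed period within 1 sample
        params = VoiceSynthesisParams(
            f0=100.0, jitter_target=2.0, hnr_target=60.0, voiced_fraction=1.0,
            duration=1.0, seed=7,
        )
        sig, truth = synth_voiced_audio(params)
        est = extract_periods(sig, estimate_f0_track(sig))
        true = np.diff(truth["pulse_times"])
        assert len(est) >= 0.9 * len(true)
        err = np.min(np.abs(est[:, None] - true[None, :]), axis=1)
        assert np.max(err) <= 1.0 / sig.sample_rate

    def test_silence_empty(self, silence):
        track = estimate_f0_track(silence)
        assert len(extract_periods(silence, track)) == 0


class TestHNR:
    @pytest.mark.parametrize("target", [5.0, 10.0, 20.0])
    def test_injected_hnr_recovery(self, target):
        params = VoiceSynthesisParams(
            f0=150.0, jitter_target=0.0, hnr_target=target, voiced_fraction=1.0,
            duration=2.0, seed=4,
        )
        sig, _ = synth_voiced_audio(params)
        est = hnr_db(sig, estimate_f0_track(sig)).value
        assert abs(est - target) <= 2.0

    def test_monotone_in_noise(self):
        estimates = []
        for target in (5.0, 10.0, 20.0):
            params = VoiceSynthesisParams(
                f0=150.0, jitter_target=0.0, hnr_target=target,
                voiced_fraction=1.0, duration=2.0, seed=4,
            )
            sig, _ = synth_voiced_audio(params)
            estimates.append(hnr_db(sig, estimate_f0_track(sig)).value)
        assert all(np.diff(estimates) > 0)

    def test_equal_power_mixture_near_zero(self):
        params = VoiceSynthesisParams(
            f0=150.0, jitter_target=0.0, hnr_target=0.0, voiced_fraction=1.0,
            duration=2.0, seed=4,
        )
        sig, _ = synth_voiced_audio(params)
        est = hnr_db(sig, estimate_f0_track(sig)).value
        assert abs(est) <= 1.5

    def test_clean_voice_high(self, clean_voice):
        sig, _ = clean_voice
        assert hnr_db(sig, estimate_f0_track(sig)).value >= 25.0

    def test_unvoiced_missing(self, silence):
        assert hnr_db(silence, estimate_f0_track(silence)).is_missing


class TestIntensity:
    def test_full_scale_sine_closed_form(self):
        # RMS 1/sqrt(2): 20 log10(0.7071/2e-5) = 90.97 dB
        sine = make_tone(150.0, amplitude=1.0)
        assert intensity_db(sine).value == pytest.approx(90.97, abs=0.01)

    def test_halving_amplitude_drops_6db(self):
        a = intensity_db(make_tone(150.0, amplitude=1.0)).value
        b = intensity_db(make_tone(150.0, amplitude=0.5)).value
        assert a - b == pytest.approx(6.02, abs=0.1)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.01, max_value=1.0))
    def test_scaling_linearity(self, k):
        base = make_tone(150.0, amplitude=0.9)
        scaled = base.scaled(k)
        delta = intensity_db(scaled).value - intensity_db(base).value
        assert abs(delta - 20 * np.log10(k)) <= 0.1

    def test_silence_missing(self, silence):
        res = intensity_db(silence)
        assert res.is_missing and res.reason == "silent"

    def test_empty_signal_errors(self):
        with pytest.raises(ValueError):
            intensity_db(AudioSignal(np.empty(0), 16000))


class TestSpeechDetection:
    def test_voiced_segment_flanked_by_silence(self):
        params = VoiceSynthesisParams(
            f0=150.0, jitter_target=0.5, hnr_target=25.0, voiced_fraction=0.5,
            duration=4.0, seed=8,
        )
        sig, truth = synth_voiced_audio(params)
        track = estimate_f0_track(sig)
        flags = detect_speech_frames(sig, track)
        voiced_dur = sum(b - a for a, b in truth["voiced_segments"])
        expected = 100.0 * voiced_dur / sig.duration
        assert speech_prevalence(flags).value == pytest.approx(expected, abs=5.0)

    def test_all_silence_no_speech(self, silence):
        track = estimate_f0_track(silence)
        flags = detect_speech_frames(silence, track)
        assert speech_prevalence(flags).value == 0.0

    def test_fully_voiced_all_speech(self, clean_voice):
        sig, _ = clean_voice
        flags = detect_speech_frames(sig, estimate_f0_track(sig))
        assert speech_prevalence(flags).value > 95.0

    def test_prevalence_definition(self):
        flags = FrameTrack(
            np.arange(100) * 0.01,
            np.r_[np.ones(60), np.zeros(40)].astype(bool),
            np.zeros(100, bool),
        )
        assert speech_prevalence(flags).value == 60.0

    def test_prevalence_conservation(self):
        """Prevalence of a concatenation equals the frame-weighted mean of
        per-segment prevalences, up to one-frame edge effects."""
        p1 = VoiceSynthesisParams(f0=150, jitter_target=0.5, hnr_target=25,
                                  voiced_fraction=0.8, duration=2.0, seed=1)
        p2 = VoiceSynthesisParams(f0=150, jitter_target=0.5, hnr_target=25,
                                  voiced_fraction=0.3, duration=2.0, seed=2)
        s1, _ = synth_voiced_audio(p1)
        s2, _ = synth_voiced_audio(p2)
        cat = AudioSignal(np.concatenate([s1.samples, s2.samples]), FS)

        def prev_and_n(sig):
            track = estimate_f0_track(sig)
            flags = detect_speech_frames(sig, track)
            return speech_prevalence(flags).value, len(flags)

        v1, n1 = prev_and_n(s1)
        v2, n2 = prev_and_n(s2)
        vc, nc = prev_and_n(cat)
        weighted = (v1 * n1 + v2 * n2) / (n1 + n2)
        assert abs(vc - weighted) <= 100.0 * 8 / nc  # few frames at the seam


class TestExtractVocalMarkers:
    def test_round_trip(self):
        params = VoiceSynthesisParams(
            f0=150.0, jitter_target=1.0, hnr_target=15.0, voiced_fraction=0.7,
            duration=4.0, seed=9,
        )
        sig, _ = synth_voiced_audio(params)
        vms = extract_vocal_markers(sig)
        assert vms.f0_mean.value == pytest.approx(150.0, abs=1.5)
        assert vms.f0_stdev.value < 2.0
        assert vms.jitter_local.value == pytest.approx(1.0, rel=0.25)
        # injected noise ratio is an upper bound on harmonicity here: 1%
        # cycle jitter itself converts harmonic energy into aperiodicity
        assert 11.0 <= vms.hnr.value <= 17.0
        # voiced fraction 0.7 -> 70%, +-5 points plus one-frame edge
        # effects at each of the 8 segment boundaries (~2 points)
        assert vms.speech_prevalence.value == pytest.approx(70.0, abs=7.0)

    def test_pure_silence(self, silence):
        vms = extract_vocal_markers(silence, AcousticConfig(enhance=False))
        assert vms.speech_prevalence.value == 0.0
        assert vms.f0_mean.is_missing
        assert vms.jitter_local.is_missing
        assert vms.hnr.is_missing
        assert vms.vocal_intensity.is_missing

    def test_deterministic(self, clean_voice):
        sig, _ = clean_voice
        a = extract_vocal_markers(sig)
        b = extract_vocal_markers(sig)
        assert a == b

    def test_empty_audio_errors(self):
        with pytest.raises(ValueError):
            extract_vocal_markers(AudioSignal(np.empty(0), 16000))

    def test_resampling_invariance(self):
        """Feeding a 44.1 kHz copy of the same recording changes no marker
        beyond its stated tolerance (analysis resamples to 16 kHz)."""
        params = VoiceSynthesisParams(
            f0=150.0, jitter_target=1.0, hnr_target=15.0, voiced_fraction=0.7,
            duration=4.0, seed=9,
        )
        sig, _ = synth_voiced_audio(params)
        up = sig.resample(44100)
        a = extract_vocal_markers(sig)
        b = extract_vocal_markers(up)
        assert b.f0_mean.value == pytest.approx(a.f0_mean.value, abs=1.5)
        assert b.jitter_local.value == pytest.approx(a.jitter_local.value, rel=0.25)
        assert b.hnr.value == pytest.approx(a.hnr.value, abs=2.0)
        assert b.vocal_intensity.value == pytest.approx(
            a.vocal_intensity.value, abs=0.5
        )
        assert b.speech_prevalence.value == pytest.approx(
            a.speech_prevalence.value, abs=5.0
        )
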
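"""Synthetic audio, AU-table, and cohort generation with known ground truth.

No participant data accompany the study design this package implements, so
every pipeline stage is validated against synthetic inputs whose generating
parameters are stored alongside the output:

* :func:`synth_voiced_audio` renders a glottal pulse train (with calibrated
  cycle-to-cycle jitter and optional slow F0 drift) through two fixed
  second-order resonators, mixes in white noise at a prescribed
  harmonics-to-noise ratio, and interleaves voiced segments with silence to
  hit a target voiced fraction.
* :func:`synth_au_table` emits OpenFace-style baseline and response action
  unit frame tables with a programmable expressivity multiplier and
  confidence dropout.
* :func:`simulate_cohort` draws a latent symptom-severity variable per
  participant and lets it drive both PANSS item scores (one-factor ordinal
  model) and digital marker values (linear loadings), emitting the exact
  input bundle the pipeline consumes.

All randomness flows from one seeded generator per call; outputs are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import lfilter

from .facial import AU_COLUMNS, AUFrameTable
from .signal import AudioSignal, write_wav

# formant-like resonators (centre Hz, bandwidth Hz): a crude /a/-ish spectrum
_RESONATORS = ((500.0, 80.0), (1500.0, 160.0))


@dataclass(frozen=True)
class VoiceSynthesisParams:
    """Generating parameters for one synthetic voiced recording."""

    f0: float = 150.0  # Hz
    f0_drift_sd: float = 0.0  # Hz, SD of slow AR(1) drift of F0
    jitter_target: float = 1.0  # %, local jitter of the pulse sequence
    hnr_target: float = 15.0  # dB, harmonic-to-noise power ratio (voiced part)
    intensity_scale: float = 1.0  # linear amplitude factor
    voiced_fraction: float = 1.0  # fraction of the file that is voiced
    duration: float = 3.0  # s
    sample_rate: int = 16000  # Hz
    ambient_db: float = -55.0  # ambient noise level re voiced RMS (dB)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.voiced_fraction <= 1:
            raise ValueError("voiced_fraction must lie in [0, 1]")
        if self.jitter_target < 0:
            raise ValueError("jitter_target must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.f0 >= self.sample_rate / 2:
            raise ValueError("f0 at or above Nyquist is infeasible")


def _resonator_coeffs(fs: int) -> list[tuple[np.ndarray, np.ndarray]]:
    coeffs = []
    for fc, bw in _RESONATORS:
        r = np.exp(-np.pi * bw / fs)
        theta = 2 * np.pi * fc / fs
        a = np.array([1.0, -2 * r * np.cos(theta), r**2])
        coeffs.append((np.array([1.0 - r]), a))
    return coeffs


def _jittered_periods(
    rng: np.random.Generator, n: int, f0: float, jitter_target: float,
    f0_drift_sd: float,
) -> np.ndarray:
    """Period sequence whose empirical local jitter matches the target.

    Multiplicative i.i.d. Gaussian perturbations are drawn and rescaled so
    the realized jitter of the sequence equals ``jitter_target`` (the
    rescale leaves the sequence seed-deterministic).  Slow drift is an
    AR(1) walk on F0, normalized to ``f0_drift_sd``.
    """
    base_f0 = np.full(n, f0)
    if f0_drift_sd > 0 and n > 1:
        e = rng.standard_normal(n)
        drift = np.empty(n)
        drift[0] = e[0]
        phi = 0.99
        for i in range(1, n):
            drift[i] = phi * drift[i - 1] + np.sqrt(1 - phi**2) * e[i]
        drift = drift - drift.mean()
        sd = drift.std()
        if sd > 0:
            base_f0 = f0 + f0_drift_sd * drift / sd
    periods = 1.0 / base_f0
    if jitter_target > 0 and n > 1:
        eps = rng.standard_normal(n)
        eps -= eps.mean()
        for _ in range(3):  # fixed-point rescale to the exact target
            cand = periods * (1.0 + eps)
            realized = 100.0 * np.mean(np.abs(np.diff(cand))) / np.mean(cand)
            if realized <= 0:
                break
            eps *= jitter_target / realized
        periods = periods * (1.0 + eps)
    return np.maximum(periods, 1e-4)


def synth_voiced_audio(
    params: VoiceSynthesisParams,
) -> tuple[AudioSignal, dict]:
    """Render a synthetic voiced recording; return it with its ground truth.

    The ground-truth record stores true pulse times (s), voiced segment
    boundaries (s), the realized local jitter of the pulse sequence, and
    every generating parameter.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.sample_rate
    n_total = int(round(params.duration * fs))
    x_harm = np.zeros(n_total)

    # segment plan: 1-second cycles of [silence, voiced]; leading silence
    # gives the enhancer a noise-profile window
    v = params.voiced_fraction
    segments: list[tuple[int, int]] = []  # voiced (start, stop) in samples
    if v > 0:
        cycle = min(1.0, params.duration)
        n_cycle = int(round(cycle * fs))
        pos = 0
        while pos < n_total:
            sil = int(round(n_cycle * (1 - v)))
            start = min(pos + sil, n_total)
            stop = min(pos + n_cycle, n_total)
            if stop - start > int(0.05 * fs):
                segments.append((start, stop))
            pos += n_cycle

    pulse_times: list[float] = []
    coeffs = _resonator_coeffs(fs)
    all_periods: list[float] = []
    for start, stop in segments:
        seg_dur = (stop - start) / fs
        n_pulses = int(np.ceil(seg_dur * params.f0)) + 2
        periods = _jittered_periods(
            rng, n_pulses, params.f0, params.jitter_target, params.f0_drift_sd
        )
        t = np.cumsum(np.concatenate(([0.0], periods)))
        t = t[t < seg_dur - 1.0 / params.f0 * 0.5]
        # band-limited pulses at fractional sample positions: a windowed
        # sinc keeps the programmed periods exact (no quantization jitter)
        half = 32
        kernel_n = np.arange(-half, half + 1)
        taper = np.kaiser(2 * half + 1, 6.0)
        kept_times = []
        for tt in t:
            pos = start + tt * fs
            base = int(np.floor(pos))
            frac = pos - base
            lo, hi = base - half, base + half + 1
            if lo < 0 or hi > n_total:
                continue
            x_harm[lo:hi] += np.sinc(kernel_n - frac) * taper
            kept_times.append(tt)
        pulse_times.extend((start / fs) + tt for tt in kept_times)
        if len(kept_times) >= 2:
            all_periods.extend(np.diff(kept_times))

    for b, a in coeffs:
        x_harm = lfilter(b, a, x_harm)

    voiced_mask = np.zeros(n_total, dtype=bool)
    for start, stop in segments:
        voiced_mask[start:stop] = True

    p_harm = float(np.mean(x_harm[voiced_mask] ** 2)) if voiced_mask.any() else 0.0
    noise = rng.standard_normal(n_total)
    x = x_harm.copy()
    if p_harm > 0:
        target_noise_power = p_harm / (10.0 ** (params.hnr_target / 10.0))
        gated = noise * np.sqrt(target_noise_power)
        x = x + np.where(voiced_mask, gated, 0.0)
        ambient_power = p_harm * 10.0 ** (params.ambient_db / 10.0)
        x = x + np.where(voiced_mask, 0.0, noise * np.sqrt(ambient_power))
    # normalize voiced RMS to a nominal 0.1, then apply intensity scaling
    ref_rms = np.sqrt(np.mean(x[voiced_mask] ** 2)) if voiced_mask.any() else 0.0
    if ref_rms > 0:
        x = x * (0.1 / ref_rms)
    x = x * params.intensity_scale

    realized_jitter = (
        100.0 * np.mean(np.abs(np.diff(all_periods))) / np.mean(all_periods)
        if len(all_periods) >= 2
        else 0.0
    )
    truth = {
        "f0": params.f0,
        "jitter_target": params.jitter_target,
        "realized_jitter": float(realized_jitter),
        "hnr_target": params.hnr_target,
        "voiced_fraction": params.voiced_fraction,
        "intensity_scale": params.intensity_scale,
        "duration": params.duration,
        "sample_rate": fs,
        "seed": params.seed,
        "pulse_times": [float(t) for t in pulse_times],
        "voiced_segments": [(s / fs, e / fs) for s, e in segments],
    }
    return AudioSignal(x, fs), truth


def synth_au_table(
    expressivity_multiplier: float = 1.0,
    baseline_level: float = 0.5,
    n_frames: int = 300,
    dropout_fraction: float = 0.0,
    seed: int = 0,
    n_baseline_frames: int = 90,
    fps: float = 30.0,
    noise_sd: float = 0.03,
) -> tuple[AUFrameTable, AUFrameTable]:
    """Baseline and response AU frame tables with known expressivity.

    Baseline frames have per-AU mean ``baseline_level``; response frames
    have mean ``expressivity_multiplier * baseline_level``.  A
    ``dropout_fraction`` of frames in each table is assigned a face-
    detection confidence below 0.80.
    """
    if expressivity_multiplier < 0:
        raise ValueError("expressivity multiplier must be non-negative")
    if not 0 <= dropout_fraction < 1:
        raise ValueError("dropout_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n_aus = len(AU_COLUMNS)

    def build(n: int, level: float, t0: float, frame0: int) -> AUFrameTable:
        vals = np.maximum(level + noise_sd * rng.standard_normal((n, n_aus)), 0.0)
        conf = rng.uniform(0.85, 1.0, n)
        drop = rng.random(n) < dropout_fraction
        conf[drop] = rng.uniform(0.30, 0.79, int(drop.sum()))
        df = pd.DataFrame(vals, columns=AU_COLUMNS)
        df.insert(0, "frame", np.arange(frame0, frame0 + n))
        df.insert(1, "timestamp", t0 + np.arange(n) / fps)
        df.insert(2, "confidence", conf)
        df.insert(3, "success", np.ones(n, dtype=int))
        return AUFrameTable(df)

    baseline = build(n_baseline_frames, baseline_level, 0.0, 0)
    response = build(
        n_frames,
        expressivity_multiplier * baseline_level,
        n_baseline_frames / fps,
        n_baseline_frames,
    )
    return baseline, response


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerSpec:
    """Population distribution and severity loading of one digital marker."""

    mean: float
    sd: float
    target_r: float  # population correlation between marker and severity
    lo: float = -np.inf  # feasibility clip for audio/AU rendering
    hi: float = np.inf


# defaults emulate the study: correlation signs follow the reported
# direction of each marker's association with negative symptom severity
DEFAULT_MARKERS: dict[str, MarkerSpec] = {
    "vocal_intensity": MarkerSpec(70.0, 4.0, -0.10, 55.0, 85.0),
    "f0_mean": MarkerSpec(160.0, 25.0, -0.60, 90.0, 350.0),
    "f0_stdev": MarkerSpec(8.0, 3.0, -0.40, 0.5, 25.0),
    "jitter_local": MarkerSpec(1.5, 0.5, 0.55, 0.2, 4.5),
    "hnr": MarkerSpec(15.0, 4.0, -0.60, 4.0, 28.0),
    "speech_prevalence": MarkerSpec(65.0, 12.0, -0.50, 15.0, 95.0),
    "facial_expressivity": MarkerSpec(2.0, 0.5, -0.50, 0.3, 4.0),
}

CONTEXT_MARKERS: dict[str, tuple[str, ...]] = {
    "free_behavior": (
        "facial_expressivity", "vocal_intensity", "f0_mean", "f0_stdev",
        "jitter_local", "hnr", "speech_prevalence",
    ),
    "evoked_facial": ("facial_expressivity",),
    "evoked_vocal": (
        "vocal_intensity", "f0_mean", "f0_stdev", "jitter_local", "hnr",
        "speech_prevalence",
    ),
}

CONTEXT_DAYS: dict[str, tuple[int, ...]] = {
    "free_behavior": (2, 7, 14),
    "evoked_facial": (1, 7, 14),
    "evoked_vocal": (1, 7, 14),
}

_PANSS_CUTS = np.array([-1.5, -0.9, -0.3, 0.3, 0.9, 1.5])


@dataclass(frozen=True)
class CohortSimParams:
    """Study-design parameters of a simulated cohort.

    Defaults mirror the emulated study: 20 participants, two PANSS visits
    (days 1 and 14), three remote assessment days per task context, and
    severity loadings with the reported correlation signs.
    """

    n_participants: int = 20
    markers: dict[str, MarkerSpec] = field(
        default_factory=lambda: dict(DEFAULT_MARKERS)
    )
    within_noise_frac: float = 0.1  # assessment-to-assessment SD, x marker SD
    item_noise_sd: float = 0.3  # PANSS item-specific noise on the latent scale
    missingness: float = 0.05  # per-assessment missing probability
    audio_duration: float = 5.0  # s, rendered recordings
    au_frames: int = 300  # rendered response frames per facial assessment
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 3:
            raise ValueError("need at least 3 participants")
        if not 0 <= self.missingness < 1:
            raise ValueError("missingness must lie in [0, 1)")


def _panss_items(rng: np.random.Generator, z: np.ndarray, item_noise_sd: float,
                 n_items: int) -> np.ndarray:
    """Ordinal item scores 1..7 from a one-factor model with cut points."""
    n = len(z)
    x = z[:, None] + item_noise_sd * rng.standard_normal((n, n_items))
    x = x / np.sqrt(1.0 + item_noise_sd**2)
    return 1 + (x[:, :, None] > _PANSS_CUTS).sum(axis=2)


def simulate_cohort(
    params: CohortSimParams, out_dir: str | Path, render: bool = False
) -> Path:
    """Generate a full input bundle for the pipeline; return the bundle dir.

    Writes ``panss.csv``, ``manifest.yaml``, ``ground_truth.json`` and
    either a precomputed ``markers.csv`` (``render=False``) or WAV / AU-CSV
    files per assessment (``render=True``).  Per participant, a latent
    severity ``z ~ N(0,1)`` drives both PANSS items and marker values:
    ``marker = mean + sd * (r z + sqrt(1-r^2) u)`` with stable individual
    deviation ``u`` and small assessment-level noise.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    n = params.n_participants
    pids = [f"P{i + 1:03d}" for i in range(n)]
    z = rng.standard_normal(n)

    # participant-level marker means
    level: dict[str, np.ndarray] = {}
    for name, ms in params.markers.items():
        u = rng.standard_normal(n)
        r = float(np.clip(ms.target_r, -1.0, 1.0))
        level[name] = ms.mean + ms.sd * (r * z + np.sqrt(1 - r**2) * u)

    # PANSS: 30 items, two visits
    panss_rows = []
    item_cols = (
        [f"P{i}" for i in range(1, 8)]
        + [f"N{i}" for i in range(1, 8)]
        + [f"G{i}" for i in range(1, 17)]
    )
    for day in (1, 14):
        items = _panss_items(rng, z, params.item_noise_sd, 30)
        for i, pid in enumerate(pids):
            row = {"participant_id": pid, "visit_day": day}
            row.update({c: int(v) for c, v in zip(item_cols, items[i])})
            panss_rows.append(row)
    panss_df = pd.DataFrame(panss_rows)
    panss_df.to_csv(out / "panss.csv", index=False)

    manifest: dict = {
        "panss_csv": "panss.csv",
        "config": {"seed": params.seed},
        "participants": pids,
        "assessments": [],
    }
    marker_rows = []
    assessment_values: dict[tuple, dict[str, float]] = {}
    for pid_i, pid in enumerate(pids):
        for context, days in CONTEXT_DAYS.items():
            for day in days:
                if rng.random() < params.missingness:
                    continue
                aid = f"{pid}_{context}_d{day:02d}"
                values = {}
                for m in CONTEXT_MARKERS[context]:
                    if m not in params.markers:
                        continue
                    ms = params.markers[m]
                    val = level[m][pid_i] + (
                        params.within_noise_frac * ms.sd * rng.standard_normal()
                    )
                    values[m] = float(np.clip(val, ms.lo, ms.hi))
                assessment_values[(pid, context, day)] = values
                entry = {
                    "participant_id": pid,
                    "assessment_id": aid,
                    "day": int(day),
                    "task_context": context,
                }
                if render:
                    if context in ("free_behavior", "evoked_vocal"):
                        entry["audio_path"] = f"audio/{aid}.wav"
                    if context in ("free_behavior", "evoked_facial"):
                        entry["au_table_path"] = f"au/{aid}.csv"
                        entry["baseline_end_seconds"] = 3.0
                manifest["assessments"].append(entry)
                for m, val in values.items():
                    marker_rows.append(
                        {
                            "participant_id": pid,
                            "assessment_id": aid,
                            "day": int(day),
                            "task_context": context,
                            "marker": m,
                            "value": val,
                            "missing_reason": "",
                        }
                    )

    if render:
        (out / "audio").mkdir(exist_ok=True)
        (out / "au").mkdir(exist_ok=True)
        for entry in manifest["assessments"]:
            pid = entry["participant_id"]
            context = entry["task_context"]
            day = entry["day"]
            values = assessment_values[(pid, context, day)]
            sub_seed = int(rng.integers(0, 2**31 - 1))
            if "audio_path" in entry:
                vp = VoiceSynthesisParams(
                    f0=values["f0_mean"],
                    f0_drift_sd=values["f0_stdev"],
                    jitter_target=values["jitter_local"],
                    hnr_target=values["hnr"],
                    intensity_scale=10.0
                    ** ((values["vocal_intensity"] - 74.0) / 20.0),
                    voiced_fraction=values["speech_prevalence"] / 100.0,
                    duration=params.audio_duration,
                    seed=sub_seed,
                )
                sig, _ = synth_voiced_audio(vp)
                write_wav(out / entry["audio_path"], sig)
            if "au_table_path" in entry:
                baseline, response = synth_au_table(
                    expressivity_multiplier=values["facial_expressivity"],
                    baseline_level=0.5,
                    n_frames=params.au_frames,
                    dropout_fraction=0.05,
                    seed=sub_seed + 1,
                )
                both = pd.concat([baseline.df, response.df], ignore_index=True)
                both.to_csv(out / entry["au_table_path"], index=False)
    else:
        pd.DataFrame(marker_rows).to_csv(out / "markers.csv", index=False)
        manifest["markers_csv"] = "markers.csv"

    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    truth = {
        "seed": params.seed,
        "severity": {pid: float(z[i]) for i, pid in enumerate(pids)},
        "target_r": {m: ms.target_r for m, ms in params.markers.items()},
        "marker_levels": {
            m: {pid: float(level[m][i]) for i, pid in enumerate(pids)}
            for m in params.markers
        },
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return out
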
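# Methods

This note documents the models, estimators, parameter choices, and known
limitations of `facevox`.  It is written for a reader who wants to know
*why* the pipeline computes what it computes, and what passing its test
suite does and does not demonstrate about real patient data.

## Measurement model

The package targets a remote-assessment study design: patients with
schizophrenia complete brief smartphone tasks over a two-week window —
free description of emotionally evocative images (day 2, 7, 14), an
evoked "most expressive face" prompt, and an evoked speech prompt
(reciting the days of the week; days 1, 7, 14) — while the PANSS is
administered in person on days 1 and 14.  Because patients are clinically
stable, repeated measurements are treated as noisy replicates of a stable
trait: digital markers are averaged per participant × task context, PANSS
derived scores are averaged over the two visits, and the analysis is a
cross-sectional correlation of the two averages.

## Vocal acoustics

All audio is downmixed to mono, resampled to 16 kHz (fixing the analysis
rate makes results sample-rate-independent and deterministic), and passed
once through LogMMSE enhancement before any marker is computed.

**LogMMSE.**  Classical log-spectral-amplitude MMSE gain with
decision-directed a-priori SNR (smoothing 0.98), 20 ms Hann frames at 75%
overlap, noise PSD initialized from the first 0.3 s and updated during
frames whose mean log-likelihood ratio indicates speech absence
(threshold 0.15, smoothing 0.98).  The spectral gain is floored at
10^(−25/20) so the residual noise floor sits 25 dB down; this bounds
musical-noise artifacts and keeps the map linear enough that intensity
comparisons survive enhancement.  These are the standard literature
defaults; the algorithm itself has no published parameterization tied to
this study design.

**Pitch tracking.**  Window-normalized autocorrelation in the Boersma
style: frames of 3/f_min seconds (so the lowest searched pitch fits three
periods) at a 10 ms hop; each frame is mean-subtracted, Hann-windowed,
and its normalized autocorrelation is divided by the window's own
autocorrelation to undo the taper bias.  The default search band is
75–500 Hz, voicing threshold 0.45 on the normalized peak, and a silence
gate at 0.03 of the global peak amplitude.  Two deliberate deviations
from a full Praat-style tracker:

* no octave-cost dynamic programming over candidate paths.  Instead,
  (a) among local maxima within 0.07 of the tallest (heights capped at
  1), the shortest lag wins — this suppresses the double/triple-period
  peaks that window normalization inflates at large lags; and
  (b) a post-pass un-voices frames deviating more than 25% from the
  local 5-frame voiced median, then more than a factor 1.5 from the
  utterance median.  The second pass exists because frames at voicing
  offsets can lock onto a formant resonance (e.g. a 500 Hz ring reads as
  488 Hz "pitch" with high strength) in short runs that defeat a local
  median.  This combination is adequate for enhanced, non-pathological
  speech; severely disordered voices (diplophonia, creak) would need the
  full path search.

F0 mean and SD are computed over voiced frames only (population SD);
both are *missing with reason* when nothing is voiced.

**Jitter.**  Praat's "local jitter": 100 × mean |T_i − T_{i−1}| / mean T
over consecutive glottal periods.  Periods are found in two stages inside
each contiguous voiced run (trimmed to the first/last voiced frame
centre): coarse pulse candidates are peaks of the Hilbert amplitude
envelope (one decaying bump per glottal pulse, minimum spacing 0.7 of the
local median period, peaks under 0.2 of the median height discarded),
then each period is refined to sub-sample precision by waveform matching
— the lag near the coarse spacing that maximizes the cross-correlation of
one cycle-length window with the next, parabolically interpolated.  The
refinement matters: raw envelope peak positions are biased by the
overlapping resonator tails of neighbouring pulses, which compresses
jitter estimates by ~25% at 4% jitter; waveform matching removes this
almost entirely (recovery 0.98/1.98/4.05 for programmed 1/2/4%).
Following Praat's "maximum period factor", consecutive-period pairs whose
ratio exceeds 1.3 (a missed or spurious pulse) are excluded from both
numerator and denominator.  Periods outside [1/f_max, 1/f_min] are
discarded outright.

The marker is reported as a dimensionless percentage.  (Some descriptions
of this marker say "hertz"; the standard local-jitter statistic is a
ratio, and the ratio is what this package computes.)

**HNR.**  Per voiced frame, the normalized-autocorrelation peak height r
at the F0 lag estimates the harmonic energy fraction, and the frame HNR
is 10·log₁₀(r/(1−r)) with r clamped to (10⁻⁶, 1−10⁻⁶); the marker is the
mean over voiced frames.  On jitter-free synthetic voices this recovers
injected ratios of 0/5/10/20 dB within 0.4 dB.  Note an interaction that
is physics, not estimator error: cycle-to-cycle jitter spreads harmonic
energy off the harmonic comb, so for a jittered voice the injected
noise-power ratio is an *upper bound* on measurable harmonicity (1%
jitter at an injected 15 dB reads ≈ 12.5 dB).  Tests of pure HNR recovery
therefore use jitter-free synthesis.

**Intensity.**  Energy-weighted mean of framewise 20·log₁₀(RMS / 2×10⁻⁵)
over speech frames.  The 2×10⁻⁵ reference mimics the SPL convention but
is uncalibrated — remote smartphone recordings have unknown gain — so only
relative and correlational use is meaningful.  A full-scale sine reads
20·log₁₀(0.7071/2×10⁻⁵) = 90.97 dB, and amplitude scaling by k moves the
marker by exactly 20·log₁₀(k).

**Speech prevalence.**  A frame is speech iff it is voiced *or* its
energy exceeds the noise floor (10th percentile of frame energies) by
9 dB; prevalence is the percentage of speech frames.  Energy uses a 20 ms
window at the 10 ms hop — shorter than the pitch frame — to keep the
boundary-straddling inflation near one frame per voiced/silence edge.
With 1 s voicing cycles this still biases prevalence high by 3–5 points
at 60–70% voiced; the tests budget for edge effects explicitly.

**Missing-value semantics.**  Degenerate inputs (silence, all-unvoiced,
fewer than two periods) produce a `MarkerValue` that is missing with a
reason code; NaN never propagates into the statistics, which instead use
explicit pairwise deletion with per-cell n.

## Facial expressivity

AU tables are consumed in the OpenFace CSV dialect (frame, timestamp,
confidence, success, 17 `AU.._r` intensity columns); a 0–100 confidence
column is normalized to [0, 1] on load.  Frames with confidence < 0.80
(strictly below; "80% or higher" is kept) or success = 0 are dropped —
before *both* the baseline profile and the response computation, so the
ratio is taken between equally filtered quantities.  The manifest
declares where the pre-stimulus baseline ends (default: first 3 s).
Per-AU baseline means below 10⁻³ are floored to 10⁻³ and flagged rather
than dropped, keeping the division defined while preserving an audit
trail.  Expressivity is the grand mean of baseline-normalized intensities
over all AUs and retained response frames — identical for evoked and
spontaneous contexts.  The composite is exactly 1 for a baseline segment
normalized against itself and exactly linear in a uniform scaling of the
response intensities.

## Clinical scores

PANSS records carry 30 items (P1–P7, N1–N7, G1–G16) each in 1–7.
Subscale totals are plain sums; the negative-symptom reference is the
Marder five-factor negative composite N1+N2+N3+N4+N6+G7+G16 (motor
retardation and active social avoidance promoted from the general scale),
configurable for alternative item sets.  Visit averaging operates on
derived scores; because all scores are linear in items this is identical
to averaging items first (property-tested).  A single-visit participant
passes through with a logged warning.

## Statistics

* **Pearson correlation** with two-sided p from the exact t transform
  (t = r·√((n−2)/(1−r²)) on n−2 df), pairwise deletion, n ≥ 3 and
  non-constant inputs required (violations are flagged, not NaN).
* **Benjamini–Hochberg** step-up adjustment, applied by default within
  the family of marker-vs-scale cells of one task-context table, matching
  the per-table presentation of this kind of analysis.  Marker–marker
  intercorrelation cells carry raw p only under the default family
  (`family_spec="all"` includes them).  The implementation is
  cross-checked elementwise against statsmodels' `fdr_bh` and a naive
  O(m²) oracle.
* **Test–retest reliability** is ICC(A,1) — two-way mixed effects,
  absolute agreement, single measure — computed from the ANOVA mean
  squares and cross-checked against pingouin.  Week 1 is days ≤ 7,
  week 2 days > 7, each averaged per participant before pairing.  The
  specific ICC form is a documented choice (the analysis only needs "a"
  defensible reliability statistic); it is the most conservative common
  variant because it penalizes systematic week effects.

## Synthetic data

The generators are first-class, tested code: they define the conditions
under which every other module is validated.

**Voice synthesis.**  A glottal pulse train at period 1/f0 passes through
two fixed second-order resonators (500 Hz / 80 Hz BW, 1500 Hz / 160 Hz
BW — a crude open-vowel spectrum).  Pulses are band-limited windowed
sincs placed at fractional sample positions, so programmed periods are
exact and no quantization jitter leaks in.  Jitter is injected as
multiplicative i.i.d. Gaussian period perturbations rescaled (fixed
point, 3 iterations) so the realized local jitter of the true pulse
sequence equals the target; optional slow F0 drift is an AR(1) walk
normalized to a target SD.  White noise scaled to the target
harmonic-to-noise power ratio is added inside voiced segments (plus a
−55 dB ambient floor in silences, which feeds the enhancer's noise
profile); voiced/silence alternation follows 1 s cycles with the silence
first, hitting the target voiced fraction.  Ground truth records pulse
times, segment boundaries, realized jitter, and all parameters.

**AU tables.**  Baseline frames with per-AU mean `baseline_level` plus
Gaussian noise (SD 0.03), response frames at `multiplier ×
baseline_level`; a programmed fraction of frames receives confidence in
[0.30, 0.79] (below threshold), the rest [0.85, 1.0].

**Cohorts.**  Latent severity z ~ N(0,1) per participant.  A marker with
loading r has participant-level value mean + sd·(r·z + √(1−r²)·u) with
stable individual deviation u, plus small assessment-level noise
(SD 0.1 × marker SD) — placing nearly all variance at the participant
level matches the design assumption of stable traits and makes the
participant-mean marker correlate with z at ≈ r.  PANSS items follow a
one-factor ordinal model: per visit and item, x = z + 0.3·ε is
standardized and cut at symmetric thresholds (±0.3, ±0.9, ±1.5 SD) into
1–7.  Default marker distributions and loadings (e.g. F0 mean 160 ± 25 Hz
at r = −0.6, jitter 1.5 ± 0.5% at +0.55, HNR 15 ± 4 dB at −0.6,
prevalence 65 ± 12% at −0.5, expressivity 2.0 ± 0.5 at −0.5) are chosen
to be physiologically plausible with association signs matching the
negative-symptom literature for these markers.  Default design: 20
participants, 3 assessment days per context, 5% missing assessments,
two PANSS visits.  In `render` mode the sampled marker values become
synthesis parameters and the bundle contains actual WAV and AU-CSV files;
in marker-level mode the values are written directly, which isolates the
statistics from estimator noise.

Simulation sizes used by the tests and the acceptance script — 500
participants for correlation recovery, 20-cohort null batteries, a
50-participant rendered cohort for end-to-end determinism, 2–4 s
synthetic recordings — were chosen as the smallest sizes at which the
stochastic tolerances are statistically meaningful.

## Pipeline and determinism

The manifest (YAML) declares assessments, task contexts, input paths, and
the PANSS CSV; validation enforces the context/input compatibility map
(evoked vocal ⇒ audio, evoked facial ⇒ AU table, free behavior ⇒ either).
Per-assessment extraction failures (corrupt files, too-short audio) are
logged and skipped — remote capture data is routinely partially corrupt —
and the run fails only if nothing usable remains.  All outputs are tidy
CSVs written with a fixed float format; re-running with the same
manifest, config, and seed is byte-identical (only the log carries
timestamps).

## What the tests show — and what they do not

Passing the suite demonstrates that the estimators recover known ground
truth from *clean, synthetic* signals obeying the generator's model: a
stationary two-resonator voice, Gaussian noise, exact baselines,
one-factor PANSS structure.  Real smartphone recordings add reverberation,
codec artifacts, non-stationary noise, off-axis microphones, and voices
whose source-filter structure the generator does not attempt to imitate;
OpenFace confidence on real video correlates with pose and lighting
rather than the coin-flips simulated here.  The correlation-recovery
results validate the *statistical* pipeline, not the claim that these
markers track symptom severity in patients — that claim is exactly what a
clinical study must establish.  Known numeric edges: prevalence reads
3–5 points high at intermediate voiced fractions (boundary frames);
HNR saturates near 25–30 dB (window leakage) and is bounded above by
jitter as described; jitter has a noise floor near 0.06% from residual
peak-localization error.
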
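"""Manifest-driven end-to-end orchestration.

A study manifest (YAML) lists participants, their per-assessment inputs
(audio and/or AU tables with a task context), and the PANSS CSV.  The
pipeline extracts per-assessment digital markers, averages them to
participant level, derives the clinical scores, builds one correlation
table per task context, and computes week-1 vs week-2 test-retest ICCs.
Per-assessment failures are logged and skipped; the run is fatal only when
no usable assessment remains.  Outputs are deterministic: re-running with
the same manifest and config yields byte-identical CSVs (only the run log
carries timestamps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .acoustics import AcousticConfig, extract_vocal_markers
from .facial import expressivity_from_frames, read_au_table
from .panss import clinical_scores_frame, read_panss_csv
from .signal import read_wav
from .stats import aggregate_assessments, correlation_table, icc_test_retest
from .synth import CONTEXT_MARKERS

logger = logging.getLogger(__name__)

TASK_CONTEXTS = ("free_behavior", "evoked_facial", "evoked_vocal")
_FLOAT_FORMAT = "%.10g"


@dataclass(frozen=True)
class PipelineConfig:
    """Effective configuration of one pipeline run."""

    acoustic: AcousticConfig = AcousticConfig()
    confidence_threshold: float = 0.80
    baseline_end_seconds: float = 3.0
    family_spec: str = "scales"
    seed: int = 0


@dataclass
class StudyManifest:
    """Parsed study manifest."""

    root: Path
    panss_csv: str
    assessments: list[dict]
    participants: list[str] = field(default_factory=list)
    markers_csv: str | None = None
    config: dict = field(default_factory=dict)


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def load_manifest(path) -> StudyManifest:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("manifest must be a YAML mapping")
    return StudyManifest(
        root=path.parent,
        panss_csv=raw.get("panss_csv", ""),
        assessments=list(raw.get("assessments", [])),
        participants=list(raw.get("participants", [])),
        markers_csv=raw.get("markers_csv"),
        config=dict(raw.get("config", {})),
    )


def validate_manifest(manifest: StudyManifest) -> ValidationReport:
    """Check paths and task-context / input compatibility."""
    rep = ValidationReport()
    if not manifest.panss_csv:
        rep.errors.append("manifest declares no PANSS CSV")
    elif not (manifest.root / manifest.panss_csv).exists():
        rep.errors.append(f"PANSS CSV not found: {manifest.panss_csv}")
    if manifest.markers_csv is not None:
        if not (manifest.root / manifest.markers_csv).exists():
            rep.errors.append(f"markers CSV not found: {manifest.markers_csv}")
        return rep
    n_valid = 0
    for entry in manifest.assessments:
        aid = entry.get("assessment_id", "<unnamed>")
        ctx = entry.get("task_context")
        if ctx not in TASK_CONTEXTS:
            rep.errors.append(f"{aid}: unknown task_context {ctx!r}")
            continue
        has_audio = "audio_path" in entry
        has_au = "au_table_path" in entry
        if ctx == "evoked_vocal" and not has_audio:
            rep.errors.append(f"{aid}: evoked_vocal entry lacks an audio path")
            continue
        if ctx == "evoked_facial" and not has_au:
            rep.errors.append(f"{aid}: evoked_facial entry lacks an AU table path")
            continue
        if ctx == "free_behavior" and not (has_audio or has_au):
            rep.errors.append(f"{aid}: free_behavior entry has no inputs")
            continue
        entry_ok = True
        for key in ("audio_path", "au_table_path"):
            if key in entry and not (manifest.root / entry[key]).exists():
                rep.errors.append(f"{aid}: missing file {entry[key]}")
                entry_ok = False
        n_valid += entry_ok
    if manifest.assessments and n_valid == 0:
        rep.errors.append("no valid assessments in manifest")
    return rep


def _marker_value_rows(entry: dict, names, markers) -> list[dict]:
    rows = []
    for name in names:
        mv = markers[name]
        rows.append(
            {
                "participant_id": entry["participant_id"],
                "assessment_id": entry["assessment_id"],
                "day": int(entry["day"]),
                "task_context": entry["task_context"],
                "marker": name,
                "value": "" if mv.is_missing else mv.value,
                "missing_reason": mv.reason or "",
            }
        )
    return rows


def extract_markers(
    manifest: StudyManifest, config: PipelineConfig = PipelineConfig()
) -> pd.DataFrame:
    """Per-assessment marker extraction (tidy long format).

    Corrupt or unreadable assessments are logged and skipped.
    """
    if manifest.markers_csv is not None:
        df = pd.read_csv(
            manifest.root / manifest.markers_csv,
            keep_default_na=False,
            dtype={"missing_reason": str},
        )
        df["value"] = pd.to_numeric(df["value"], errors="coerce")
        return df
    rows: list[dict] = []
    skipped = []
    for entry in sorted(manifest.assessments, key=lambda e: e["assessment_id"]):
        ctx = entry["task_context"]
        vocal_wanted = ctx in ("free_behavior", "evoked_vocal")
        facial_wanted = ctx in ("free_behavior", "evoked_facial")
        try:
            if vocal_wanted and "audio_path" in entry:
                sig = read_wav(manifest.root / entry["audio_path"])
                vms = extract_vocal_markers(sig, config.acoustic)
                names = [m for m in CONTEXT_MARKERS[ctx] if m != "facial_expressivity"]
                rows.extend(_marker_value_rows(entry, names, vms.as_dict()))
            if facial_wanted and "au_table_path" in entry:
                table = read_au_table(manifest.root / entry["au_table_path"])
                res = expressivity_from_frames(
                    table,
                    float(entry.get("baseline_end_seconds",
                                    config.baseline_end_seconds)),
                    config.confidence_threshold,
                )
                rows.extend(
                    _marker_value_rows(
                        entry, ["facial_expressivity"],
                        {"facial_expressivity": res.facial_expressivity},
                    )
                )
        except Exception as exc:  # failure isolation: log and skip
            skipped.append(entry["assessment_id"])
            logger.warning("skipping assessment %s: %s", entry["assessment_id"], exc)
    if not rows:
        raise RuntimeError(
            f"no usable assessments (skipped: {', '.join(skipped) or 'none'})"
        )
    if skipped:
        logger.info("skipped %d assessment(s): %s", len(skipped), ", ".join(skipped))
    return pd.DataFrame(rows)


def _icc_report(markers_df: pd.DataFrame) -> pd.DataFrame:
    """Week-1 (days 1-7) vs week-2 (days 8-14) ICC(A,1) per context/marker."""
    df = markers_df.copy()
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    df["week"] = (df["day"] > 7).map({False: "week1", True: "week2"})
    rows = []
    for (ctx, marker), grp in df.groupby(["task_context", "marker"], sort=True):
        wide = grp.pivot_table(
            index="participant_id", columns="week", values="value", aggfunc="mean"
        )
        if not {"week1", "week2"}.issubset(wide.columns):
            continue
        paired = wide.dropna()
        res = icc_test_retest(paired["week1"], paired["week2"])
        rows.append(
            {
                "task_context": ctx,
                "marker": marker,
                "icc": "" if res.icc is None else res.icc,
                "n": res.n,
                "note": res.note,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    manifest: StudyManifest,
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path = "facevox_out",
) -> Path:
    """End-to-end run; writes the output bundle and returns its directory."""
    report = validate_manifest(manifest)
    if not report.ok:
        raise RuntimeError("manifest invalid:\n" + "\n".join(report.errors))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    markers_df = extract_markers(manifest, config)
    markers_df.to_csv(out / "markers.csv", index=False,
                      float_format=_FLOAT_FORMAT)

    profiles = aggregate_assessments(markers_df)
    profiles.to_csv(out / "profiles.csv", index=False, float_format=_FLOAT_FORMAT)

    records = read_panss_csv(manifest.root / manifest.panss_csv)
    clinical = clinical_scores_frame(records)
    clinical.to_csv(out / "clinical_scores.csv", index=False,
                    float_format=_FLOAT_FORMAT)

    for ctx in TASK_CONTEXTS:
        if (profiles["task_context"] == ctx).any():
            table = correlation_table(profiles, clinical, ctx, config.family_spec)
            table.to_csv(out / f"correlations_{ctx}.csv", index=False,
                         float_format=_FLOAT_FORMAT)

    icc = _icc_report(markers_df)
    icc.to_csv(out / "icc.csv", index=False, float_format=_FLOAT_FORMAT)

    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "confidence_threshold": config.confidence_threshold,
                "baseline_end_seconds": config.baseline_end_seconds,
                "family_spec": config.family_spec,
                "seed": config.seed,
                "acoustic": {
                    "f_min": config.acoustic.f_min,
                    "f_max": config.acoustic.f_max,
                    "hop": config.acoustic.hop,
                    "voicing_threshold": config.acoustic.voicing_threshold,
                    "silence_threshold": config.acoustic.silence_threshold,
                    "vad_margin_db": config.acoustic.vad_margin_db,
                    "noise_seconds": config.acoustic.noise_seconds,
                    "enhance": config.acoustic.enhance,
                    "target_rate": config.acoustic.target_rate,
                },
            },
            fh,
            sort_keys=True,
        )
    return out
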
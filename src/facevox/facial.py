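"""Facial expressivity from framewise action-unit intensity tables.

Consumes OpenFace-style CSV output (one row per video frame: frame index,
timestamp, face-detection confidence, success flag, and 17 action-unit
intensity columns ``AU01_r`` ... ``AU45_r``).  Frames below the confidence
threshold (0.80, inclusive) or with ``success == 0`` are discarded.  Each
AU intensity is divided by its mean over a pre-stimulus baseline segment
recorded at the start of the assessment, and *facial expressivity* is the
grand mean of the normalized intensities over all AUs and retained frames.
The same formula applies to evoked and spontaneous task contexts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .acoustics import MarkerValue

AU_IDS = (
    "01", "02", "04", "05", "06", "07", "09", "10", "12", "14", "15",
    "17", "20", "23", "25", "26", "45",
)
AU_COLUMNS = tuple(f"AU{i}_r" for i in AU_IDS)
BASELINE_FLOOR = 1e-3
DEFAULT_CONFIDENCE_THRESHOLD = 0.80


@dataclass
class AUFrameTable:
    """Framewise AU intensities with detection confidence.

    Wraps a DataFrame with columns ``frame, timestamp, confidence, success``
    plus the 17 AU intensity columns.  ``fraction_dropped`` is populated by
    :func:`filter_confidence`.
    """

    df: pd.DataFrame
    fraction_dropped: float = 0.0
    au_columns: tuple[str, ...] = AU_COLUMNS

    def __post_init__(self) -> None:
        required = ["frame", "timestamp", "confidence", "success", *self.au_columns]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing AU column(s): {', '.join(missing)}")
        au = self.df[list(self.au_columns)].to_numpy(dtype=float)
        if np.any(au < 0):
            raise ValueError("AU intensities must be non-negative")
        conf = self.df["confidence"].to_numpy(dtype=float)
        if np.any((conf < 0) | (conf > 1)):
            raise ValueError("confidence must lie in [0, 1]")
        frames = self.df["frame"].to_numpy()
        if len(frames) > 1 and not np.all(np.diff(frames) > 0):
            raise ValueError("frame_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.df)

    def intensities(self) -> np.ndarray:
        return self.df[list(self.au_columns)].to_numpy(dtype=float)


@dataclass(frozen=True)
class BaselineProfile:
    """Per-AU mean intensity during the pre-stimulus baseline segment."""

    means: dict[str, float]
    n_frames_used: int
    floored_aus: tuple[str, ...] = ()


@dataclass(frozen=True)
class ExpressivityResult:
    """The baseline-normalized facial expressivity composite."""

    facial_expressivity: MarkerValue
    n_frames_used: int
    fraction_dropped_low_confidence: float


def read_au_table(path, au_columns: tuple[str, ...] = AU_COLUMNS) -> AUFrameTable:
    """Load an OpenFace-dialect CSV as an :class:`AUFrameTable`.

    Confidence is normalized to [0, 1] whether the file stores a fraction
    or a 0-100 percentage.  Non-numeric cells raise with the row number.
    """
    df = pd.read_csv(path, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    required = ["frame", "timestamp", "confidence", "success", *au_columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing AU column(s) in {path}: {', '.join(missing)}")
    df = df[required].copy()
    for col in required:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"non-numeric value in column {col!r} at row {row}")
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise ValueError(f"empty cell in column {col!r} at row {row}")
        df[col] = converted
    if df["confidence"].max() > 1.5:  # percentage dialect
        df["confidence"] = df["confidence"] / 100.0
    return AUFrameTable(df)


def filter_confidence(
    table: AUFrameTable, threshold: float = DEFAULT_CONFIDENCE_THRESHOLD
) -> AUFrameTable:
    """Drop frames below the confidence threshold (inclusive keep) or with
    ``success == 0``; record the dropped fraction."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    df = table.df
    keep = (df["confidence"] >= threshold) & (df["success"] != 0)
    dropped = 1.0 - (keep.sum() / len(df)) if len(df) else 0.0
    return AUFrameTable(
        df[keep].reset_index(drop=True),
        fraction_dropped=float(dropped),
        au_columns=table.au_columns,
    )


def baseline_profile(baseline_segment: AUFrameTable) -> BaselineProfile:
    """Per-AU mean intensity over the (confidence-filtered) baseline frames.

    AUs whose baseline mean falls below 1e-3 are floored to 1e-3 and
    flagged, keeping the downstream ratio well-defined.
    """
    if len(baseline_segment) == 0:
        raise ValueError("no usable baseline")
    vals = baseline_segment.intensities().mean(axis=0)
    floored = []
    means = {}
    for au, v in zip(baseline_segment.au_columns, vals):
        if v < BASELINE_FLOOR:
            means[au] = BASELINE_FLOOR
            floored.append(au)
        else:
            means[au] = float(v)
    return BaselineProfile(means, len(baseline_segment), tuple(floored))


def normalize_aus(table: AUFrameTable, baseline: BaselineProfile) -> AUFrameTable:
    """Divide each framewise AU intensity by its baseline mean."""
    missing = [au for au in table.au_columns if au not in baseline.means]
    if missing:
        raise ValueError(f"AU(s) absent from baseline profile: {', '.join(missing)}")
    df = table.df.copy()
    for au in table.au_columns:
        df[au] = df[au] / baseline.means[au]
    return AUFrameTable(df, table.fraction_dropped, table.au_columns)


def facial_expressivity(table: AUFrameTable) -> ExpressivityResult:
    """Grand mean of the normalized AU intensities over all frames and AUs."""
    if len(table) == 0:
        return ExpressivityResult(
            MarkerValue.missing("no confident frames"), 0, table.fraction_dropped
        )
    value = float(table.intensities().mean())
    return ExpressivityResult(MarkerValue(value), len(table), table.fraction_dropped)


def expressivity_from_frames(
    table: AUFrameTable,
    baseline_end_seconds: float = 3.0,
    threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
) -> ExpressivityResult:
    """Full per-assessment computation from one raw AU table.

    Frames with ``timestamp < baseline_end_seconds`` form the pre-stimulus
    baseline; both segments are confidence-filtered before the baseline
    profile is taken and the response is normalized.
    """
    df = table.df
    is_baseline = df["timestamp"] < baseline_end_seconds
    base = AUFrameTable(
        df[is_baseline].reset_index(drop=True), au_columns=table.au_columns
    )
    resp = AUFrameTable(
        df[~is_baseline].reset_index(drop=True), au_columns=table.au_columns
    )
    base_f = filter_confidence(base, threshold)
    resp_f = filter_confidence(resp, threshold)
    if len(base_f) == 0:
        return ExpressivityResult(
            MarkerValue.missing("no usable baseline"), 0, resp_f.fraction_dropped
        )
    profile = baseline_profile(base_f)
    normalized = normalize_aus(resp_f, profile)
    return facial_expressivity(normalized)
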
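"""Marker-severity correlation analysis and test-retest reliability.

Per-assessment markers are averaged to one value per participant x task
context (clinically stable cohort; averaging reduces within-subject
noise).  Each marker is then correlated with the visit-averaged PANSS
scores using Pearson's r, with two-sided p-values from the exact t
transform, and Benjamini-Hochberg step-up adjustment applied within the
family of marker-vs-scale tests of one task-context table.  The negative
symptom column uses the Marder negative factor; positive, general and
total columns use the plain subscale totals.  Test-retest reliability
between the study's two weeks uses the two-way mixed-effects,
absolute-agreement, single-measure intraclass correlation ICC(A,1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

SCALE_COLUMNS = {
    "negative": "marder_negative",
    "positive": "p_total",
    "general": "g_total",
    "total": "panss_total",
}


@dataclass(frozen=True)
class CorrelationResult:
    """One cell of a marker-vs-scale correlation table."""

    marker: str
    scale: str
    r: float | None
    p_raw: float | None
    p_adjusted: float | None
    n: int
    note: str = ""


@dataclass(frozen=True)
class ICCResult:
    """Two-way mixed, absolute-agreement, single-measure ICC."""

    icc: float | None
    n: int
    note: str = ""


def aggregate_assessments(marker_rows: pd.DataFrame) -> pd.DataFrame:
    """Participant-level marker profiles.

    Input is the tidy per-assessment table (columns ``participant_id,
    task_context, marker, value, missing_reason``); output has one row per
    participant x context x marker with the arithmetic mean over
    non-missing assessment values and the contributing count
    ``n_assessments`` (0 when all assessments were missing).
    """
    df = marker_rows.copy()
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    grouped = df.groupby(
        ["participant_id", "task_context", "marker"], sort=True
    )["value"].agg(value="mean", n_assessments="count")
    out = grouped.reset_index()
    out["n_assessments"] = out["n_assessments"].astype(int)
    return out


def pearson_corr(x, y) -> tuple[float | None, float | None, int, str]:
    """Pearson r with a two-sided p-value after pairwise deletion.

    Returns ``(r, p, n, note)``; constant or too-short vectors yield
    ``(None, None, n, reason)`` rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        return None, None, n, "fewer than 3 complete pairs"
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None, n, "constant vector"
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), n, ""


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    ``q_(i) = min over j >= i of p_(j) * m / j`` on the ascending sort,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def correlation_table(
    profiles: pd.DataFrame,
    clinical: pd.DataFrame,
    task_context: str,
    family_spec: str = "scales",
) -> pd.DataFrame:
    """Marker-vs-scale and marker-vs-marker Pearson correlations.

    ``profiles`` is the output of :func:`aggregate_assessments`;
    ``clinical`` the visit-averaged score frame.  ``family_spec`` selects
    the multiple-comparison family for the BH adjustment: ``"scales"``
    adjusts the marker-vs-scale cells of this one context table (the
    intercorrelation cells keep raw p only) while ``"all"`` adjusts every
    cell.  Pairwise deletion per cell; per-cell n is reported.
    """
    if family_spec not in ("scales", "all"):
        raise ValueError("family_spec must be 'scales' or 'all'")
    sub = profiles[profiles["task_context"] == task_context]
    wide = sub.pivot_table(
        index="participant_id", columns="marker", values="value", aggfunc="first"
    )
    merged = wide.join(clinical.set_index("participant_id"), how="inner")
    markers = sorted(wide.columns)
    rows = []
    for marker in markers:
        for scale_name, col in SCALE_COLUMNS.items():
            r, p, n, note = pearson_corr(merged[marker], merged[col])
            rows.append(
                {
                    "task_context": task_context,
                    "marker": marker,
                    "scale": scale_name,
                    "kind": "marker_vs_scale",
                    "r": r,
                    "p_raw": p,
                    "n": n,
                    "note": note,
                }
            )
    for i, m1 in enumerate(markers):
        for m2 in markers[i + 1 :]:
            r, p, n, note = pearson_corr(merged[m1], merged[m2])
            rows.append(
                {
                    "task_context": task_context,
                    "marker": m1,
                    "scale": m2,
                    "kind": "marker_vs_marker",
                    "r": r,
                    "p_raw": p,
                    "n": n,
                    "note": note,
                }
            )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = np.nan
    in_family = (
        table.index
        if family_spec == "all"
        else table.index[table["kind"] == "marker_vs_scale"]
    )
    defined = table.loc[in_family, "p_raw"].notna()
    idx = table.loc[in_family].index[defined]
    if len(idx):
        table.loc[idx, "p_adjusted"] = bh_adjust(table.loc[idx, "p_raw"].to_numpy())
    return table


def icc_test_retest(week1, week2) -> ICCResult:
    """ICC(A,1): two-way mixed, absolute agreement, single measure.

    ``week1`` and ``week2`` are paired per-participant marker values.  From
    the two-way ANOVA mean squares (rows = participants, columns = weeks):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    x = np.asarray(week1, dtype=float)
    y = np.asarray(week2, dtype=float)
    if len(x) != len(y):
        raise ValueError("week vectors must be paired")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        return ICCResult(None, n, "fewer than 3 complete pairs")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    if np.ptp(row_means) == 0:
        return ICCResult(None, n, "zero between-participant variance")
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return ICCResult(None, n, "degenerate variance structure")
    return ICCResult(float((msr - mse) / denom), n)
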
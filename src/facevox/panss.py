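"""PANSS item scores, subscale totals, and the Marder negative factor.

The Positive and Negative Syndrome Scale has 30 clinician-rated items
(P1-P7, N1-N7, G1-G16), each scored 1-7.  Subscale totals are plain sums;
the Marder negative symptom factor augments five negative-scale items with
motor retardation (G7) and active social avoidance (G16), per the standard
five-factor solution.  When a participant is rated at two visits the
derived scores are averaged, giving the clinical reference against which
digital markers are correlated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

P_ITEMS = tuple(f"P{i}" for i in range(1, 8))
N_ITEMS = tuple(f"N{i}" for i in range(1, 8))
G_ITEMS = tuple(f"G{i}" for i in range(1, 17))
ALL_ITEMS = P_ITEMS + N_ITEMS + G_ITEMS
# Marder negative factor: N1-N4, N6 plus motor retardation (G7) and
# active social avoidance (G16)
MARDER_NEGATIVE_ITEMS = ("N1", "N2", "N3", "N4", "N6", "G7", "G16")


@dataclass(frozen=True)
class PANSSRecord:
    """One participant-visit's 30 item scores."""

    participant_id: str
    visit_day: int
    items: dict[str, int]

    def __post_init__(self) -> None:
        missing = [k for k in ALL_ITEMS if k not in self.items]
        if missing:
            raise ValueError(f"missing PANSS item(s): {', '.join(missing)}")
        extra = [k for k in self.items if k not in ALL_ITEMS]
        if extra:
            raise ValueError(f"unknown PANSS item(s): {', '.join(extra)}")
        for k, v in self.items.items():
            if not (isinstance(v, (int,)) and 1 <= v <= 7):
                raise ValueError(f"item {k} out of range 1..7: {v!r}")


@dataclass(frozen=True)
class ClinicalScores:
    """Derived PANSS scores for one participant (-visit or visit-average)."""

    participant_id: str
    p_total: float
    n_total: float
    g_total: float
    panss_total: float
    marder_negative: float
    n_visits: int = 1


def panss_totals(
    record: PANSSRecord,
    marder_items: tuple[str, ...] = MARDER_NEGATIVE_ITEMS,
) -> ClinicalScores:
    """Subscale totals, grand total, and Marder negative factor."""
    p = sum(record.items[k] for k in P_ITEMS)
    n = sum(record.items[k] for k in N_ITEMS)
    g = sum(record.items[k] for k in G_ITEMS)
    return ClinicalScores(
        participant_id=record.participant_id,
        p_total=float(p),
        n_total=float(n),
        g_total=float(g),
        panss_total=float(p + n + g),
        marder_negative=float(marder_negative_factor(record, marder_items)),
    )


def marder_negative_factor(
    record: PANSSRecord, items: tuple[str, ...] = MARDER_NEGATIVE_ITEMS
) -> int:
    """Sum of the Marder negative-factor items (default N1-N4, N6, G7, G16)."""
    unknown = [k for k in items if k not in ALL_ITEMS]
    if unknown:
        raise ValueError(f"unknown PANSS item(s): {', '.join(unknown)}")
    return sum(record.items[k] for k in items)


def average_visits(
    records: list[PANSSRecord],
    marder_items: tuple[str, ...] = MARDER_NEGATIVE_ITEMS,
) -> ClinicalScores:
    """Average the derived scores of one participant across visits.

    A single visit passes through with a logged warning (clinically stable
    cohorts are scored at two visits; one visit means no averaging noise
    reduction).
    """
    if not records:
        raise ValueError("no PANSS records to average")
    pid = records[0].participant_id
    if any(r.participant_id != pid for r in records):
        raise ValueError("records belong to different participants")
    if len(records) == 1:
        logger.warning("participant %s has a single PANSS visit; no averaging", pid)
    per_visit = [panss_totals(r, marder_items) for r in records]
    k = len(per_visit)
    return ClinicalScores(
        participant_id=pid,
        p_total=sum(s.p_total for s in per_visit) / k,
        n_total=sum(s.n_total for s in per_visit) / k,
        g_total=sum(s.g_total for s in per_visit) / k,
        panss_total=sum(s.panss_total for s in per_visit) / k,
        marder_negative=sum(s.marder_negative for s in per_visit) / k,
        n_visits=k,
    )


def read_panss_csv(path) -> list[PANSSRecord]:
    """Read participant-visit item scores from CSV.

    Expected columns: ``participant_id, visit_day, P1..P7, N1..N7, G1..G16``.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("participant_id", "visit_day", *ALL_ITEMS)
               if c not in df.columns]
    if missing:
        raise ValueError(f"PANSS CSV missing column(s): {', '.join(missing)}")
    records = []
    for _, row in df.iterrows():
        items = {k: int(row[k]) for k in ALL_ITEMS}
        records.append(
            PANSSRecord(str(row["participant_id"]), int(row["visit_day"]), items)
        )
    return records


def clinical_scores_frame(
    records: list[PANSSRecord],
    marder_items: tuple[str, ...] = MARDER_NEGATIVE_ITEMS,
) -> pd.DataFrame:
    """Visit-averaged derived scores, one row per participant."""
    by_pid: dict[str, list[PANSSRecord]] = {}
    for r in records:
        by_pid.setdefault(r.participant_id, []).append(r)
    rows = []
    for pid in sorted(by_pid):
        s = average_visits(by_pid[pid], marder_items)
        rows.append(
            {
                "participant_id": pid,
                "p_total": s.p_total,
                "n_total": s.n_total,
                "g_total": s.g_total,
                "panss_total": s.panss_total,
                "marder_negative": s.marder_negative,
                "n_visits": s.n_visits,
            }
        )
    return pd.DataFrame(rows)
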
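"""Grouping asynchronous element recordings into bedside assessments.

Vital-sign elements are charted one at a time, so a single bedside
observation appears on disk as several rows minutes apart. Recordings of one
patient falling within a 15-minute window count as a single assessment: the
first unassigned recording opens the assessment and fixes its anchor time,
every later recording with timestamp < anchor + window joins it, and the
first recording at or beyond anchor + window opens the next one. The window
is anchored, not rolling, so the grouping is deterministic and independent
of input row order, and a chain of measurements 14 minutes apart cannot
merge without bound.

If the same element recurs inside one window the latest value supersedes the
earlier ones (a repeat within minutes is a re-measurement); superseded rows
are retained on the assessment so that no recording is ever dropped from the
partition. Each assessment carries a MEWS recomputed from its elements —
never trusted from input — and a source label: AUTOMATED iff at least half
of its constituent recordings came from the automated system (ties go to
AUTOMATED).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .records_io import (
    CORE_ELEMENTS,
    Arm,
    ElementKind,
    RecordingSource,
    VitalRecording,
)
from .scoring import MewsResult, ScoringTable, build_default_table, compute_mews

__all__ = [
    "Assessment",
    "build_assessments",
    "label_source",
    "completeness_counts",
    "write_assessments",
    "DEFAULT_WINDOW_MINUTES",
]

DEFAULT_WINDOW_MINUTES = 15.0


@dataclass(frozen=True)
class Assessment:
    """One ≤window group of recordings for one patient, scored."""

    patient_id: str
    anchor_time: datetime
    elements: dict[ElementKind, VitalRecording]
    mews: MewsResult
    source_label: RecordingSource
    arm: Arm
    n_recordings: int  # all constituent recordings, superseded duplicates included
    superseded: tuple[VitalRecording, ...] = ()

    @property
    def complete(self) -> bool:
        return self.mews.complete


def build_assessments(
    recordings: Iterable[VitalRecording],
    window_minutes: float = DEFAULT_WINDOW_MINUTES,
    table: ScoringTable | None = None,
) -> list[Assessment]:
    """Partition recordings into anchored-window assessments, per patient.

    Every input recording belongs to exactly one assessment (superseded
    duplicates included in its ``n_recordings``). Empty input yields an
    empty list.
    """
    if window_minutes <= 0:
        raise ValueError("window_minutes must be positive")
    if table is None:
        table = build_default_table()
    window = timedelta(minutes=window_minutes)

    ordered = sorted(recordings, key=lambda r: (r.patient_id, r.timestamp, r.element.value))
    out: list[Assessment] = []
    group: list[VitalRecording] = []

    def flush():
        if group:
            out.append(_finalize(group, table))
            group.clear()

    for rec in ordered:
        if group and (rec.patient_id != group[0].patient_id or rec.timestamp >= group[0].timestamp + window):
            flush()
        group.append(rec)
    flush()
    return out


def _finalize(group: Sequence[VitalRecording], table: ScoringTable) -> Assessment:
    latest: dict[ElementKind, VitalRecording] = {}
    superseded: list[VitalRecording] = []
    for rec in group:  # chronological within the group
        if rec.element in latest:
            superseded.append(latest[rec.element])
        latest[rec.element] = rec
    mews = compute_mews(
        table, {e: (r.value, r.oxygen_therapy) for e, r in latest.items()}
    )
    return Assessment(
        patient_id=group[0].patient_id,
        anchor_time=group[0].timestamp,
        elements=latest,
        mews=mews,
        source_label=_majority_source(group),
        arm=group[0].period,
        n_recordings=len(group),
        superseded=tuple(superseded),
    )


def _majority_source(recordings: Sequence[VitalRecording]) -> RecordingSource:
    n_auto = sum(1 for r in recordings if r.source is RecordingSource.AUTOMATED)
    # ties resolve to AUTOMATED: the device charts whole observations, so an
    # even split still means the device was in play
    if 2 * n_auto >= len(recordings) and n_auto > 0:
        return RecordingSource.AUTOMATED
    return RecordingSource.CONVENTIONAL


def label_source(assessment: Assessment) -> RecordingSource:
    """Majority source over the assessment's constituent recordings."""
    if assessment.n_recordings < 1:
        raise ValueError("assessment has no recordings")
    return assessment.source_label


def completeness_counts(assessments: Sequence[Assessment]) -> tuple[int, int]:
    """(total, complete) — complete means all 7 core elements present."""
    n_total = len(assessments)
    n_complete = sum(1 for a in assessments if a.complete)
    return n_total, n_complete


def write_assessments(assessments: Sequence[Assessment], path: str | Path) -> Path:
    """Export one row per assessment with its score and element values."""
    path = Path(path)
    rows = []
    for a in assessments:
        row = {
            "patient_id": a.patient_id,
            "anchor_time": a.anchor_time.strftime("%Y-%m-%dT%H:%M"),
            "mews_total": a.mews.total,
            "complete": int(a.complete),
            "source_label": a.source_label.value,
            "arm": a.arm.value,
        }
        for element in ElementKind:
            rec = a.elements.get(element)
            row[element.value.lower()] = "" if rec is None else rec.value
        rows.append(row)
    df = pd.DataFrame(rows)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
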
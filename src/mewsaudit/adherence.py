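"""Protocol-adherence auditing.

The hospital response protocol dictates the maximum time until the next
bedside assessment as a function of the current MEWS:

    ====  ==========================  =====================================
    MEWS  next assessment within      escalation actions
    ====  ==========================  =====================================
    0     next shift (24 h)           —
    1     8 h                         —
    2     4 h                         —
    3     1 h                         consult responsible physician
    ≥4    1 h                         consult physician, consider RRT
    ====  ==========================  =====================================

An assessment is *adherent* when the anchor-to-anchor interval to the next
assessment of the same stay does not exceed the window for its MEWS. The
last assessment of a stay has no successor and is not evaluable; by default
it leaves the denominator ("exclude_terminal"), or it can be counted as
non-adherent ("terminal_nonadherent") to approximate accounting schemes
whose denominator is the total number of assessments. Only the
monitoring-interval component of the protocol is auditable from timestamps;
whether the physician or rapid response team was actually called is not on
the chart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .assessments import Assessment
from .records_io import RecordingSource
from .stats import median_iqr

__all__ = [
    "ResponseRule",
    "AdherenceVerdict",
    "IntervalStratum",
    "DEFAULT_RESPONSE_RULES",
    "required_interval_hours",
    "audit_stay",
    "audit_assessments",
    "adherence_rate",
    "interval_strata",
    "write_audit",
    "write_strata",
]

DenominatorPolicy = Literal["exclude_terminal", "terminal_nonadherent"]


@dataclass(frozen=True)
class ResponseRule:
    """Maximum monitoring interval and escalation actions for one MEWS value."""

    mews_value: int  # the top rule applies to all values >= its mews_value
    max_interval_hours: float
    actions: str


DEFAULT_RESPONSE_RULES: tuple[ResponseRule, ...] = (
    ResponseRule(0, 24.0, "none"),
    ResponseRule(1, 8.0, "none"),
    ResponseRule(2, 4.0, "none"),
    ResponseRule(3, 1.0, "consult physician"),
    ResponseRule(4, 1.0, "consult physician + consider RRT"),
)


def required_interval_hours(
    mews: int, rules: Sequence[ResponseRule] = DEFAULT_RESPONSE_RULES
) -> float:
    """Maximum hours until the next assessment for a given MEWS."""
    if mews < 0:
        raise ValueError(f"MEWS cannot be negative, got {mews}")
    for rule in rules:
        if mews == rule.mews_value:
            return rule.max_interval_hours
    return rules[-1].max_interval_hours  # every value above the table's top row


@dataclass(frozen=True)
class AdherenceVerdict:
    """Audit outcome for one assessment.

    ``adherent`` is None for the stay's terminal assessment (no successor to
    time); otherwise interval ≤ required window.
    """

    assessment: Assessment
    mews_total: int
    interval_to_next_hours: float | None
    required_hours: float
    adherent: bool | None


@dataclass(frozen=True)
class IntervalStratum:
    """Time-to-next-assessment summary for one MEWS stratum."""

    label: str
    n: int
    median_hours: float | None
    iqr_hours: float | None
    intervals: tuple[float, ...] = ()


def audit_stay(
    assessments: Sequence[Assessment],
    rules: Sequence[ResponseRule] = DEFAULT_RESPONSE_RULES,
    complete_only: bool = False,
) -> list[AdherenceVerdict]:
    """Audit the chronologically sorted assessments of a single stay.

    With ``complete_only`` the audit is restricted to complete assessments
    (both as clock-starters and as successors); by default incomplete
    assessments are audited on their partial — lower-bound — MEWS.
    """
    if not assessments:
        return []
    patient_ids = {a.patient_id for a in assessments}
    if len(patient_ids) > 1:
        raise ValueError(f"audit_stay got assessments of several patients: {sorted(patient_ids)}")
    times = [a.anchor_time for a in assessments]
    if times != sorted(times):
        raise ValueError("assessments must be chronologically sorted")

    pool = [a for a in assessments if a.complete] if complete_only else list(assessments)
    verdicts: list[AdherenceVerdict] = []
    for current, nxt in zip(pool, pool[1:] + [None]):
        required = required_interval_hours(current.mews.total, rules)
        if nxt is None:
            verdicts.append(
                AdherenceVerdict(current, current.mews.total, None, required, None)
            )
        else:
            hours = (nxt.anchor_time - current.anchor_time).total_seconds() / 3600.0
            verdicts.append(
                AdherenceVerdict(current, current.mews.total, hours, required, hours <= required)
            )
    return verdicts


def audit_assessments(
    assessments: Sequence[Assessment],
    rules: Sequence[ResponseRule] = DEFAULT_RESPONSE_RULES,
    complete_only: bool = False,
) -> list[AdherenceVerdict]:
    """Audit a multi-patient collection, stay by stay."""
    by_patient: dict[str, list[Assessment]] = {}
    for a in sorted(assessments, key=lambda a: (a.patient_id, a.anchor_time)):
        by_patient.setdefault(a.patient_id, []).append(a)
    verdicts: list[AdherenceVerdict] = []
    for pid in sorted(by_patient):
        verdicts.extend(audit_stay(by_patient[pid], rules, complete_only))
    return verdicts


def adherence_rate(
    verdicts: Iterable[AdherenceVerdict],
    policy: DenominatorPolicy = "exclude_terminal",
) -> float:
    """Adherent fraction under the chosen denominator policy; NaN for 0/0."""
    n_adherent = 0
    n_denom = 0
    for v in verdicts:
        if v.adherent is None:
            if policy == "terminal_nonadherent":
                n_denom += 1
            continue
        n_denom += 1
        n_adherent += v.adherent
    if n_denom == 0:
        return math.nan
    return n_adherent / n_denom


def interval_strata(
    verdicts: Iterable[AdherenceVerdict],
    levels: Sequence[int] = (0, 1, 2, 3),
    split_top: bool = False,
    quartile_rule: str = "tukey",
) -> list[IntervalStratum]:
    """Median / IQR-width of time-to-next-assessment per MEWS stratum.

    An interval belongs to the stratum of its *earlier* assessment — the
    protocol clock starts at the scored observation. The top level pools all
    higher scores (e.g. stratum "3" holds MEWS ≥ 3) unless ``split_top``,
    which adds a separate ">=top+1" stratum.
    """
    levels = sorted(levels)
    buckets: dict[str, list[float]] = {str(l): [] for l in levels}
    top = levels[-1]
    if split_top:
        buckets[f">={top + 1}"] = []
    for v in verdicts:
        if v.interval_to_next_hours is None:
            continue
        m = v.mews_total
        if split_top and m > top:
            key = f">={top + 1}"
        else:
            key = str(min(m, top)) if m >= levels[0] else None
        if key is not None:
            buckets[key].append(v.interval_to_next_hours)
    strata = []
    for label, values in buckets.items():
        if values:
            med, iqr = median_iqr(values, quartile_rule)
        else:
            med = iqr = None
        strata.append(IntervalStratum(label, len(values), med, iqr, tuple(values)))
    return strata


def write_audit(verdicts: Sequence[AdherenceVerdict], path: str | Path) -> Path:
    """Export one row per verdict."""
    path = Path(path)
    rows = [
        {
            "patient_id": v.assessment.patient_id,
            "anchor_time": v.assessment.anchor_time.strftime("%Y-%m-%dT%H:%M"),
            "mews_total": v.mews_total,
            "required_hours": v.required_hours,
            "interval_to_next_hours": "" if v.interval_to_next_hours is None else round(v.interval_to_next_hours, 4),
            "adherent": "" if v.adherent is None else int(v.adherent),
        }
        for v in verdicts
    ]
    df = pd.DataFrame(
        rows,
        columns=["patient_id", "anchor_time", "mews_total", "required_hours", "interval_to_next_hours", "adherent"],
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_strata(strata: Sequence[IntervalStratum], path: str | Path) -> Path:
    """Export the strata table (MEWS, N, median hours, IQR width)."""
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "mews": s.label,
                "n": s.n,
                "median_hours": "" if s.median_hours is None else round(s.median_hours, 2),
                "iqr_hours": "" if s.iqr_hours is None else round(s.iqr_hours, 2),
            }
            for s in strata
        ]
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
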
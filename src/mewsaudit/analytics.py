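"""Cohort-level descriptive analyses and the before/after arm comparison.

Produces the operational report of an early-warning-system evaluation:
completeness and protocol-adherence proportions with 2×2 tests, per-element
missingness tables, the 24-hour pattern of assessments, time-to-next-
assessment strata compared by rank-sum test, and clinical-outcome summaries
taken verbatim from the stay table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .adherence import (
    AdherenceVerdict,
    DenominatorPolicy,
    adherence_rate,
    audit_assessments,
    interval_strata,
)
from .assessments import Assessment, completeness_counts
from .records_io import CORE_ELEMENTS, Arm, ElementKind, PatientStay, RecordingSource
from .stats import (
    ContingencyResult,
    contingency_test,
    median_iqr,
    percent,
    rank_sum_test,
)

__all__ = [
    "ElementMissingness",
    "missingness_by_element",
    "hourly_pattern",
    "ArmComparisonReport",
    "compare_arms",
]

#: Fixed display order for element tables.
ELEMENT_ORDER = [
    ElementKind.HEART_RATE,
    ElementKind.SYSTOLIC_BP,
    ElementKind.RESP_RATE,
    ElementKind.TEMPERATURE,
    ElementKind.SPO2,
    ElementKind.AVPU,
    ElementKind.URINE_4H,
]


@dataclass(frozen=True)
class ElementMissingness:
    element: ElementKind
    n_assessments: int
    n_missing: int

    @property
    def percent_missing(self) -> float:
        if self.n_assessments == 0:
            return float("nan")
        return 100.0 * self.n_missing / self.n_assessments


def missingness_by_element(
    assessments: Sequence[Assessment],
    elements: Sequence[ElementKind] = tuple(ELEMENT_ORDER),
) -> list[ElementMissingness]:
    """Per core element, how many assessments lack it."""
    n = len(assessments)
    out = []
    for element in elements:
        n_missing = sum(1 for a in assessments if element not in a.elements)
        out.append(ElementMissingness(element, n, n_missing))
    return out


def hourly_pattern(assessments: Sequence[Assessment]) -> np.ndarray:
    """Counts of assessments by anchor hour-of-day (24 integer bins).

    Bedside observation practice shows up here as peaks at the daily
    nursing-round hours.
    """
    bins = np.zeros(24, dtype=int)
    for a in assessments:
        bins[a.anchor_time.hour] += 1
    return bins


# ---------------------------------------------------------------------------
# the before/after report


@dataclass
class ArmComparisonReport:
    """All tables of the operational comparison, as DataFrames.

    ``adherence_summary`` — per group: assessments, complete (n, %),
    adherent (n, denominator, %), with chi-square / Fisher p-values for
    control vs intervention on completeness and adherence.
    ``missingness`` — per element and group: n missing and % missing.
    ``intervals`` — three comparison panels of time-to-next-assessment by
    MEWS stratum with rank-sum p and Z.
    ``outcomes`` — clinical-outcome summaries per arm with tests.
    ``hourly`` — 24-bin assessment counts per group.
    """

    adherence_summary: pd.DataFrame
    missingness: pd.DataFrame
    intervals: pd.DataFrame
    outcomes: pd.DataFrame
    hourly: pd.DataFrame
    completeness_test: ContingencyResult | None = None
    adherence_test: ContingencyResult | None = None

    def write(self, out_dir: str | Path) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in (
            ("adherence_summary", self.adherence_summary),
            ("missingness", self.missingness),
            ("intervals", self.intervals),
            ("outcomes", self.outcomes),
            ("hourly_pattern", self.hourly),
        ):
            p = out_dir / f"{name}.csv"
            df.to_csv(p, index=False)
            written.append(p)
        return written


def _group_rows(
    label: str,
    assessments: Sequence[Assessment],
    verdicts: Sequence[AdherenceVerdict],
    policy: DenominatorPolicy,
) -> dict:
    n_total, n_complete = completeness_counts(assessments)
    evaluable = [v for v in verdicts if v.adherent is not None]
    n_adherent = sum(1 for v in evaluable if v.adherent)
    denom = n_total if policy == "terminal_nonadherent" else len(evaluable)
    return {
        "group": label,
        "n_assessments": n_total,
        "n_complete": n_complete,
        "pct_complete": percent(n_complete, n_total) if n_total else float("nan"),
        "n_adherent": n_adherent,
        "adherence_denominator": denom,
        "pct_adherent": percent(n_adherent, denom) if denom else float("nan"),
    }


def _interval_panel(
    panel: str,
    label_a: str,
    verdicts_a: Sequence[AdherenceVerdict],
    label_b: str,
    verdicts_b: Sequence[AdherenceVerdict],
    levels: Sequence[int],
    quartile_rule: str,
) -> list[dict]:
    strata_a = {s.label: s for s in interval_strata(verdicts_a, levels, quartile_rule=quartile_rule)}
    strata_b = {s.label: s for s in interval_strata(verdicts_b, levels, quartile_rule=quartile_rule)}
    rows = []
    for level in levels:
        key = str(level)
        sa, sb = strata_a[key], strata_b[key]
        if sa.n >= 1 and sb.n >= 1:
            rs = rank_sum_test(sa.intervals, sb.intervals)
            p, z = rs.p_two_sided, rs.z_score
        else:
            p = z = float("nan")
        rows.append(
            {
                "panel": panel,
                "mews": key,
                "group_a": label_a,
                "n_a": sa.n,
                "median_a": sa.median_hours,
                "iqr_a": sa.iqr_hours,
                "group_b": label_b,
                "n_b": sb.n,
                "median_b": sb.median_hours,
                "iqr_b": sb.iqr_hours,
                "p_value": p,
                "z_score": z,
            }
        )
    return rows


def _outcome_rows(control: Sequence[PatientStay], intervention: Sequence[PatientStay]) -> list[dict]:
    rows = []

    def continuous(name, getter):
        cx = [getter(s) for s in control]
        ix = [getter(s) for s in intervention]
        med_c, iqr_c = median_iqr(cx)
        med_i, iqr_i = median_iqr(ix)
        rs = rank_sum_test(cx, ix)
        rows.append(
            {
                "outcome": name,
                "control": f"{med_c:g} ({iqr_c:g})",
                "intervention": f"{med_i:g} ({iqr_i:g})",
                "p_value": rs.p_two_sided,
            }
        )

    def binary(name, getter):
        kc = sum(1 for s in control if getter(s))
        ki = sum(1 for s in intervention if getter(s))
        nc, ni = len(control), len(intervention)
        try:
            p = contingency_test(kc, nc - kc, ki, ni - ki).p_two_sided
        except ValueError:  # an all-zero (or all-one) outcome in both arms
            p = float("nan")
        rows.append(
            {
                "outcome": name,
                "control": f"{kc} ({percent(kc, nc)})",
                "intervention": f"{ki} ({percent(ki, ni)})",
                "p_value": p,
            }
        )

    rows.append({"outcome": "n_patients", "control": len(control), "intervention": len(intervention), "p_value": ""})
    continuous("hospital_los_days_median_iqr", lambda s: s.hospital_los_days)
    continuous("hdu_los_days_median_iqr", lambda s: s.hdu_los_days)
    binary("in_hospital_death_n_pct", lambda s: s.in_hospital_death)
    binary("death_within_28d_n_pct", lambda s: s.death_within_28d)
    binary("icu_readmitted_n_pct", lambda s: s.icu_readmitted)
    return rows


def compare_arms(
    control_assessments: Sequence[Assessment],
    control_stays: Sequence[PatientStay],
    intervention_assessments: Sequence[Assessment],
    intervention_stays: Sequence[PatientStay],
    policy: DenominatorPolicy = "exclude_terminal",
    levels: Sequence[int] = (0, 1, 2, 3),
    quartile_rule: str = "tukey",
) -> ArmComparisonReport:
    """Full operational + clinical comparison of the two study arms.

    The time-to-next-assessment table has the study's three panels:
    control vs the whole intervention arm, conventional vs automated within
    the intervention arm, and control vs the automated subset.
    """
    if not control_assessments or not intervention_assessments:
        raise ValueError("both arms must contain assessments")

    iv_conv = [a for a in intervention_assessments if a.source_label is RecordingSource.CONVENTIONAL]
    iv_auto = [a for a in intervention_assessments if a.source_label is RecordingSource.AUTOMATED]

    groups = {
        "control": control_assessments,
        "intervention": intervention_assessments,
        "intervention_conventional": iv_conv,
        "intervention_automated": iv_auto,
    }
    # audit each arm once; the conventional/automated subsets are splits of
    # the intervention verdicts by the source of the interval's *earlier*
    # assessment, so an interval may end at an assessment of the other source
    verdicts = {
        "control": audit_assessments(control_assessments),
        "intervention": audit_assessments(intervention_assessments),
    }
    verdicts["intervention_conventional"] = [
        v for v in verdicts["intervention"] if v.assessment.source_label is RecordingSource.CONVENTIONAL
    ]
    verdicts["intervention_automated"] = [
        v for v in verdicts["intervention"] if v.assessment.source_label is RecordingSource.AUTOMATED
    ]
    summary = pd.DataFrame(
        [_group_rows(name, groups[name], verdicts[name], policy) for name in groups]
    )

    # control vs intervention 2x2 tests (complete vs not, adherent vs not)
    nc, cc = completeness_counts(control_assessments)
    ni, ci = completeness_counts(intervention_assessments)
    completeness_test = contingency_test(cc, nc - cc, ci, ni - ci)
    ev_c = [v for v in verdicts["control"] if v.adherent is not None]
    ev_i = [v for v in verdicts["intervention"] if v.adherent is not None]
    ad_c = sum(1 for v in ev_c if v.adherent)
    ad_i = sum(1 for v in ev_i if v.adherent)
    adherence_test = (
        contingency_test(ad_c, len(ev_c) - ad_c, ad_i, len(ev_i) - ad_i)
        if ev_c and ev_i
        else None
    )

    miss_rows = []
    for name, group in groups.items():
        for m in missingness_by_element(group):
            miss_rows.append(
                {
                    "group": name,
                    "element": m.element.value,
                    "n_assessments": m.n_assessments,
                    "n_missing": m.n_missing,
                    "pct_missing": percent(m.n_missing, m.n_assessments) if m.n_assessments else float("nan"),
                }
            )
    missingness = pd.DataFrame(miss_rows)

    interval_rows = []
    interval_rows += _interval_panel(
        "control_vs_intervention", "control", verdicts["control"],
        "intervention", verdicts["intervention"], levels, quartile_rule,
    )
    interval_rows += _interval_panel(
        "conventional_vs_automated", "intervention_conventional", verdicts["intervention_conventional"],
        "intervention_automated", verdicts["intervention_automated"], levels, quartile_rule,
    )
    interval_rows += _interval_panel(
        "control_vs_automated", "control", verdicts["control"],
        "intervention_automated", verdicts["intervention_automated"], levels, quartile_rule,
    )
    intervals = pd.DataFrame(interval_rows)

    outcomes = pd.DataFrame(_outcome_rows(control_stays, intervention_stays))

    hourly_rows = []
    for name in ("control", "intervention"):
        bins = hourly_pattern(groups[name])
        for hour, count in enumerate(bins):
            hourly_rows.append({"group": name, "hour": hour, "n_assessments": int(count)})
    hourly = pd.DataFrame(hourly_rows)

    return ArmComparisonReport(
        adherence_summary=summary,
        missingness=missingness,
        intervals=intervals,
        outcomes=outcomes,
        hourly=hourly,
        completeness_test=completeness_test,
        adherence_test=adherence_test,
    )
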
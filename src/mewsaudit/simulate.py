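"""Synthetic two-arm HDU cohort generator.

Emulates the data-generating process of a before/after evaluation of an
automated early-warning-score system on a postoperative high-dependency
unit: per patient, a stay of log-normal length; bedside observation events
clustered on three daily nursing rounds; protocol-driven follow-ups whose
timing honours the response-table window with a configurable compliance
probability (and overshoots it by a positive log-normal delay otherwise);
vital-sign values drawn around normal-physiology baselines, shifted toward
abnormal score bands during stochastic deterioration episodes so that every
MEWS stratum occurs; per-element missingness thinning each event's
recordings (arm-specific — the conventional arm charts respiratory rate and
consciousness almost never); and, in the intervention arm only, a
configurable fraction of events recorded by the automated device.

Two modelling choices matter downstream. First, timing is event-level, not
element-level: the elements of one intended observation share an event time
with ≤5-minute offsets, and missingness then deletes elements — exactly the
structure the missingness analysis measures. Second, the follow-up interval
after an event is scheduled against the *observed* (post-missingness) MEWS —
the score a nurse could actually compute at the bedside — so the audited
adherence rate recovers the configured compliance probability regardless of
missingness. Stay outcomes (mortality, ICU readmission) are drawn
independently of the vitals process.

Randomness is fully reproducible: one named seed, with per-patient
independent substreams keyed by (seed, arm, patient index), so cohorts of
different sizes share their common prefix of patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .adherence import required_interval_hours
from .records_io import (
    SANITY_RANGES,
    Arm,
    ElementKind,
    PatientStay,
    RecordingSource,
    VitalRecording,
)
from .scoring import ScoringTable, build_default_table, compute_mews

__all__ = [
    "ArmProfile",
    "CohortConfig",
    "EventTruth",
    "GroundTruth",
    "generate_cohort",
    "generate_arm",
    "paper_like_config",
    "inject_episode",
    "load_config",
    "save_config",
]

E = ElementKind  # local alias for table literals

#: Baseline (mean, sd) of each continuous element in normal physiology.
DEFAULT_BASELINES: dict[ElementKind, tuple[float, float]] = {
    E.HEART_RATE: (80.0, 10.0),
    E.SYSTOLIC_BP: (125.0, 15.0),
    E.RESP_RATE: (12.0, 1.8),
    E.TEMPERATURE: (37.0, 0.35),
    E.SPO2: (96.5, 1.8),
    E.URINE_4H: (200.0, 60.0),
}

#: Additive/multiplicative shift per unit of episode severity, chosen so a
#: severity around 1 crosses several score-band edges at once (true MEWS ≥ 4).
_SEVERITY_SHIFT = {
    E.HEART_RATE: 60.0,
    E.SYSTOLIC_BP: -45.0,
    E.RESP_RATE: 20.0,
    E.TEMPERATURE: 1.5,
    E.SPO2: -8.0,
}

DEFAULT_MISSINGNESS = {
    "control": {
        E.HEART_RATE: 0.10,
        E.SYSTOLIC_BP: 0.10,
        E.RESP_RATE: 0.96,
        E.TEMPERATURE: 0.35,
        E.SPO2: 0.25,
        E.AVPU: 1.00,
        E.URINE_4H: 0.55,
        E.WORRIED: 0.97,
    },
    "intervention": {
        E.HEART_RATE: 0.03,
        E.SYSTOLIC_BP: 0.03,
        E.RESP_RATE: 0.03,
        E.TEMPERATURE: 0.15,
        E.SPO2: 0.03,
        E.AVPU: 0.03,
        E.URINE_4H: 0.45,
        E.WORRIED: 0.80,
    },
}

DEFAULT_COMPLIANCE = {
    "control": {"CONVENTIONAL": 0.011},
    "intervention": {"CONVENTIONAL": 0.108, "AUTOMATED": 0.479},
}

#: anchor-time slack (minutes) kept between a scheduled interval and the
#: protocol window edge, absorbing within-event offsets (≤5 min) and
#: minute rounding so a compliant draw can never be pushed over the edge
_EDGE_MARGIN_MIN = 8.0
#: minimum gap between consecutive events — comfortably above the 15-minute
#: assessment window so intended events never merge
_MIN_GAP_MIN = 20.0


@dataclass
class ArmProfile:
    """Arm-specific generator parameters."""

    n_patients: int = 300
    hdu_los_median_days: float = 7.5
    hdu_los_iqr_days: float = 7.0
    missingness: dict[ElementKind, float] = field(default_factory=dict)
    compliance: dict[str, float] = field(default_factory=dict)  # by source name
    automated_fraction: float = 0.0
    start_date: str = "2012-01-01"
    accrual_days: int = 450  # 15-month inclusion window
    # outcome probabilities (independent of the vitals process)
    p_icu_readmit: float = 0.134
    p_death_hosp: float = 0.016
    p_death_28d: float = 0.022
    p_male: float = 0.638
    p_unplanned: float = 0.181
    surgery_probs: tuple[float, float, float] = (0.697, 0.103, 0.200)


@dataclass
class CohortConfig:
    """Everything the generator needs, with the study's conditions as defaults."""

    seed: int = 0
    control: ArmProfile = field(default_factory=lambda: ArmProfile())
    intervention: ArmProfile = field(
        default_factory=lambda: ArmProfile(
            hdu_los_median_days=7.1,
            hdu_los_iqr_days=6.0,
            automated_fraction=0.39,
            start_date="2013-06-01",
            p_icu_readmit=0.106,
            p_death_hosp=0.011,
            p_death_28d=0.007,
            p_male=0.631,
            p_unplanned=0.135,
            surgery_probs=(0.803, 0.073, 0.124),
        )
    )
    round_hours: tuple[int, ...] = (7, 14, 22)
    round_jitter_sd_min: float = 20.0
    window_minutes: float = 15.0
    baselines: dict[ElementKind, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    oxygen_therapy_prob: float = 0.25
    worried_prob: float = 0.02
    episode_rate_per_day: float = 0.15
    episode_duration_hours_median: float = 8.0
    episode_duration_sigma: float = 0.6
    episode_severity_range: tuple[float, float] = (0.3, 1.2)
    late_overshoot_hours_median: float = 2.0
    late_overshoot_sigma: float = 0.75

    def __post_init__(self):
        if not self.control.missingness:
            self.control.missingness = dict(DEFAULT_MISSINGNESS["control"])
        if not self.intervention.missingness:
            self.intervention.missingness = dict(DEFAULT_MISSINGNESS["intervention"])
        if not self.control.compliance:
            self.control.compliance = dict(DEFAULT_COMPLIANCE["control"])
        if not self.intervention.compliance:
            self.intervention.compliance = dict(DEFAULT_COMPLIANCE["intervention"])

    def validate(self) -> None:
        for arm_name, profile in (("control", self.control), ("intervention", self.intervention)):
            if profile.n_patients < 1:
                raise ValueError(f"{arm_name}: n_patients must be >= 1")
            for element, p in profile.missingness.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{arm_name}: missingness[{element}] = {p} not in [0, 1]")
            if all(profile.missingness.get(e, 0.0) >= 1.0 for e in ElementKind):
                raise ValueError(f"{arm_name}: every element always missing — no data can be generated")
            for source, c in profile.compliance.items():
                if not 0.0 <= c <= 1.0:
                    raise ValueError(f"{arm_name}: compliance[{source}] = {c} not in [0, 1]")
            if not 0.0 <= profile.automated_fraction <= 1.0:
                raise ValueError(f"{arm_name}: automated_fraction not in [0, 1]")
        if self.control.automated_fraction > 0:
            raise ValueError("the control arm has no automated device")
        for h in self.round_hours:
            if not 0 <= h < 24:
                raise ValueError(f"round hour {h} not in [0, 24)")
        if not self.round_hours:
            raise ValueError("at least one daily round hour is required")


def paper_like_config(n_per_arm: int = 300, seed: int = 0) -> CohortConfig:
    """The bundled default configuration.

    Operational parameters are set from the study's printed numbers:
    automated fraction 0.39 in the intervention arm; respiratory-rate
    missingness 0.96 vs 0.03 and consciousness (AVPU) missingness 1.00 vs
    0.03 between arms; HDU length-of-stay medians 7.5 vs 7.1 days.
    """
    cfg = CohortConfig(seed=seed)
    cfg.control.n_patients = n_per_arm
    cfg.intervention.n_patients = n_per_arm
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# ground truth


@dataclass(frozen=True)
class EventTruth:
    """Per intended observation event: what was measured before missingness."""

    patient_id: str
    event_time: datetime
    true_mews: int
    observed_mews: int
    intended_elements: frozenset[ElementKind]
    recorded_elements: frozenset[ElementKind]
    source: RecordingSource
    scheduled_within_window: bool | None  # compliance draw for the *next* interval


@dataclass
class GroundTruth:
    """Everything a parameter-recovery test needs, exactly as configured."""

    config: CohortConfig
    missingness: dict[str, dict[ElementKind, float]]
    compliance: dict[str, dict[str, float]]
    automated_fraction: dict[str, float]
    events: list[EventTruth] = field(default_factory=list)
    episodes: dict[str, list[tuple[datetime, datetime, float]]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# value model


def _round_element(element: ElementKind, value: float) -> float:
    lo, hi = SANITY_RANGES[element]
    hi = min(hi, 1e6)
    value = min(max(value, lo), hi)
    if element is E.TEMPERATURE:
        return round(value, 1)
    return float(round(value))


def _apply_severity(element: ElementKind, value: float, severity: float) -> float:
    """Shift one element value toward its abnormal bands."""
    if severity == 0:
        return value
    if element in _SEVERITY_SHIFT:
        value = value + _SEVERITY_SHIFT[element] * severity
    elif element is E.URINE_4H:
        value = value * max(0.0, 1.0 - 0.8 * severity)
    elif element is E.AVPU:
        value = min(3.0, value + math.floor(2.5 * severity))
    return _round_element(element, value)


def _draw_event_values(
    rng: np.random.Generator,
    config: CohortConfig,
    severity: float,
) -> dict[ElementKind, tuple[float, bool]]:
    """All eight element values of one intended observation."""
    in_episode = severity > 0
    oxygen = bool(rng.random() < (0.6 if in_episode else config.oxygen_therapy_prob))
    values: dict[ElementKind, tuple[float, bool]] = {}
    for element, (mean, sd) in config.baselines.items():
        v = _round_element(element, rng.normal(mean, sd))
        v = _apply_severity(element, v, severity)
        values[element] = (v, oxygen if element is E.SPO2 else False)
    avpu = _apply_severity(E.AVPU, 0.0, severity)
    values[E.AVPU] = (avpu, False)
    p_worried = 0.5 if in_episode else config.worried_prob
    values[E.WORRIED] = (float(rng.random() < p_worried), False)
    return values


# ---------------------------------------------------------------------------
# timing model


def _lognormal_from_median_iqr(rng, median: float, iqr: float) -> float:
    # sigma solving exp(mu + z75*s) - exp(mu - z75*s) = iqr with mu = ln(median)
    z75 = 0.6744897501960817
    sigma = math.asinh(iqr / (2.0 * median)) / z75
    return float(rng.lognormal(math.log(median), sigma))


def _next_round_time(t: datetime, round_hours: Sequence[int]) -> datetime:
    """First nominal nursing-round time strictly after t."""
    candidates = []
    for day_offset in (0, 1):
        day = (t + timedelta(days=day_offset)).replace(hour=0, minute=0)
        for h in round_hours:
            c = day + timedelta(hours=h)
            if c > t:
                candidates.append(c)
    return min(candidates)


def _schedule_next(
    rng: np.random.Generator,
    config: CohortConfig,
    t: datetime,
    window_hours: float,
    compliant: bool,
) -> datetime:
    """Time of the next observation event after the event at ``t``."""
    w_min = window_hours * 60.0
    if not compliant:
        overshoot = rng.lognormal(
            math.log(config.late_overshoot_hours_median * 60.0),
            config.late_overshoot_sigma,
        )
        raw = t + timedelta(minutes=w_min + _EDGE_MARGIN_MIN + overshoot)
        # a missed window is usually picked up at the next nursing round;
        # snapping only ever delays further, so the breach is preserved
        nominal = _next_round_time(raw, config.round_hours)
        jitter = rng.normal(0.0, config.round_jitter_sd_min)
        candidate = nominal + timedelta(minutes=float(jitter))
        return max(candidate, raw)
    # compliant: prefer the next nursing round when it fits in the window
    nominal = _next_round_time(t + timedelta(minutes=_MIN_GAP_MIN), config.round_hours)
    jitter = rng.normal(0.0, config.round_jitter_sd_min)
    candidate = nominal + timedelta(minutes=float(jitter))
    gap_min = (candidate - t).total_seconds() / 60.0
    if _MIN_GAP_MIN <= gap_min <= w_min - _EDGE_MARGIN_MIN:
        return candidate
    hi = max(w_min - _EDGE_MARGIN_MIN, _MIN_GAP_MIN + 1.0)
    return t + timedelta(minutes=float(rng.uniform(_MIN_GAP_MIN, hi)))


def _episode_severity_at(
    t: datetime, episodes: Sequence[tuple[datetime, datetime, float]]
) -> float:
    for start, end, severity in episodes:
        if start <= t < end:
            return severity
    return 0.0


# ---------------------------------------------------------------------------
# generation


def generate_arm(
    config: CohortConfig,
    arm: Arm,
    table: ScoringTable | None = None,
) -> tuple[list[PatientStay], list[VitalRecording], GroundTruth]:
    """Generate one study arm (see :func:`generate_cohort`)."""
    config.validate()
    if table is None:
        table = build_default_table()
    profile = config.control if arm is Arm.CONTROL else config.intervention
    arm_idx = 0 if arm is Arm.CONTROL else 1
    truth = GroundTruth(
        config=config,
        missingness={arm.value: dict(profile.missingness)},
        compliance={arm.value: dict(profile.compliance)},
        automated_fraction={arm.value: profile.automated_fraction},
    )
    stays: list[PatientStay] = []
    recordings: list[VitalRecording] = []
    base = datetime.fromisoformat(profile.start_date)

    for i in range(profile.n_patients):
        rng = np.random.default_rng([config.seed, arm_idx, i])
        pid = f"{'C' if arm is Arm.CONTROL else 'I'}{i:04d}"
        stay, patient_recs, events, episodes = _generate_patient(
            rng, config, profile, arm, pid, base, table
        )
        stays.append(stay)
        recordings.extend(patient_recs)
        truth.events.extend(events)
        truth.episodes[pid] = episodes

    recordings.sort(key=lambda r: (r.patient_id, r.timestamp, r.element.value))
    return stays, recordings, truth


def _generate_patient(rng, config, profile, arm, pid, base, table):
    los_days = _lognormal_from_median_iqr(
        rng, profile.hdu_los_median_days, profile.hdu_los_iqr_days
    )
    los_days = min(max(los_days, 1.0), 60.0)
    admit = base + timedelta(
        days=float(rng.uniform(0, profile.accrual_days)),
    )
    admit = admit.replace(second=0, microsecond=0)
    planned_end = admit + timedelta(days=los_days)

    # deterioration episodes
    n_ep = int(rng.poisson(config.episode_rate_per_day * los_days))
    episodes: list[tuple[datetime, datetime, float]] = []
    for _ in range(n_ep):
        start = admit + timedelta(days=float(rng.uniform(0, los_days)))
        duration_h = rng.lognormal(
            math.log(config.episode_duration_hours_median), config.episode_duration_sigma
        )
        end = min(start + timedelta(hours=float(duration_h)), planned_end)
        severity = float(rng.uniform(*config.episode_severity_range))
        if end > start:
            episodes.append((start, end, severity))
    episodes.sort(key=lambda e: e[0])

    # The event walk runs past the planned end by exactly one event: the
    # first observation at/after the planned end is the terminal one (the
    # pre-transfer check). Stopping instead when the *scheduled* successor
    # would overshoot would censor long (non-compliant) intervals
    # preferentially and bias the audited adherence upward.
    events: list[EventTruth] = []
    recs: list[VitalRecording] = []
    t = admit + timedelta(minutes=float(rng.uniform(30, 120)))
    while True:
        severity = _episode_severity_at(t, episodes)
        values = _draw_event_values(rng, config, severity)
        true_mews = compute_mews(table, values)

        if arm is Arm.INTERVENTION and rng.random() < profile.automated_fraction:
            source = RecordingSource.AUTOMATED
        else:
            source = RecordingSource.CONVENTIONAL

        kept = {
            e: v
            for e, v in values.items()
            if rng.random() >= profile.missingness.get(e, 0.0)
        }
        if not kept:  # never let an event vanish entirely from the chart
            kept = {E.HEART_RATE: values[E.HEART_RATE]}
        observed = compute_mews(table, kept)

        offsets = sorted(float(rng.uniform(0, 5)) for _ in kept)
        for (element, (value, oxygen)), off in zip(sorted(kept.items(), key=lambda kv: kv[0].value), offsets):
            ts = (t + timedelta(minutes=off)).replace(second=0, microsecond=0)
            recs.append(
                VitalRecording(
                    patient_id=pid,
                    timestamp=ts,
                    element=element,
                    value=value,
                    oxygen_therapy=oxygen,
                    source=source,
                    period=arm,
                )
            )

        compliance = profile.compliance.get(source.value, profile.compliance.get("CONVENTIONAL", 1.0))
        compliant = bool(rng.random() < compliance)
        window = required_interval_hours(observed.total)
        is_terminal = t >= planned_end
        events.append(
            EventTruth(
                patient_id=pid,
                event_time=t,
                true_mews=true_mews.total,
                observed_mews=observed.total,
                intended_elements=frozenset(values),
                recorded_elements=frozenset(kept),
                source=source,
                scheduled_within_window=None if is_terminal else compliant,
            )
        )
        if is_terminal:
            break
        t = _schedule_next(rng, config, t, window, compliant)

    discharge = (t + timedelta(minutes=5 + float(rng.uniform(5, 60)))).replace(
        second=0, microsecond=0
    )
    hdu_los = (discharge - admit).total_seconds() / 86400.0

    stay = PatientStay(
        patient_id=pid,
        arm=arm,
        hdu_admit=admit,
        hdu_discharge=discharge,
        age_years=float(np.clip(rng.normal(67.0, 11.1), 18.0, 95.0)),
        sex="M" if rng.random() < profile.p_male else "F",
        surgery_type=("abdominal_oncology", "abdominal_benign", "vascular_aortic")[
            int(rng.choice(3, p=np.asarray(profile.surgery_probs) / sum(profile.surgery_probs)))
        ],
        unplanned_surgery=bool(rng.random() < profile.p_unplanned),
        icu_readmitted=bool(rng.random() < profile.p_icu_readmit),
        in_hospital_death=bool(rng.random() < profile.p_death_hosp),
        death_within_28d=bool(rng.random() < profile.p_death_28d),
        hospital_los_days=round(hdu_los + float(rng.lognormal(math.log(4.0), 0.5)), 1),
        hdu_los_days=round(hdu_los, 1),
        apache2=float(np.clip(round(rng.normal(14.0, 4.5)), 0, 71)),
        apache4=float(np.clip(round(rng.normal(37.0, 11.0)), 0, 286)),
        saps2=float(np.clip(round(rng.normal(31.0, 11.0)), 0, 163)),
    )
    return stay, recs, events, episodes


def generate_cohort(
    config: CohortConfig, table: ScoringTable | None = None
) -> tuple[list[PatientStay], list[VitalRecording], GroundTruth]:
    """Generate both arms: (stays, recordings, ground truth).

    Deterministic for a fixed config and seed; per-patient substreams mean
    cohorts of different sizes share the patients they have in common.
    """
    config.validate()
    stays_c, recs_c, truth_c = generate_arm(config, Arm.CONTROL, table)
    stays_i, recs_i, truth_i = generate_arm(config, Arm.INTERVENTION, table)
    truth = GroundTruth(
        config=config,
        missingness={**truth_c.missingness, **truth_i.missingness},
        compliance={**truth_c.compliance, **truth_i.compliance},
        automated_fraction={**truth_c.automated_fraction, **truth_i.automated_fraction},
        events=truth_c.events + truth_i.events,
        episodes={**truth_c.episodes, **truth_i.episodes},
    )
    return stays_c + stays_i, recs_c + recs_i, truth


# ---------------------------------------------------------------------------
# episode injection (also usable on externally supplied streams)


def inject_episode(
    recordings: Sequence[VitalRecording],
    stay: PatientStay,
    start: datetime,
    end: datetime,
    severity: float,
) -> list[VitalRecording]:
    """Shift element values in [start, end) toward abnormal bands.

    Severity 0 leaves the stream unchanged; severities near 1 push several
    elements across score-band edges at once, so the true MEWS during the
    episode strictly exceeds the baseline score.
    """
    if severity < 0:
        raise ValueError("severity must be non-negative")
    if start < stay.hdu_admit or end > stay.hdu_discharge or end <= start:
        raise ValueError(
            f"episode [{start}, {end}) outside stay [{stay.hdu_admit}, {stay.hdu_discharge})"
        )
    out = []
    for r in recordings:
        if r.patient_id == stay.patient_id and start <= r.timestamp < end and severity > 0:
            shifted = _apply_severity(r.element, r.value, severity)
            out.append(
                VitalRecording(
                    patient_id=r.patient_id,
                    timestamp=r.timestamp,
                    element=r.element,
                    value=shifted,
                    oxygen_therapy=r.oxygen_therapy,
                    source=r.source,
                    period=r.period,
                )
            )
        else:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# config file round-trip


def save_config(config: CohortConfig, path: str | Path) -> Path:
    path = Path(path)
    raw = asdict(config)
    for arm in ("control", "intervention"):
        raw[arm]["missingness"] = {e.value: p for e, p in raw[arm]["missingness"].items()}
    raw["baselines"] = {e.value: list(v) for e, v in raw["baselines"].items()}
    raw["round_hours"] = list(raw["round_hours"])
    raw["episode_severity_range"] = list(raw["episode_severity_range"])
    for arm in ("control", "intervention"):
        raw[arm]["surgery_probs"] = list(raw[arm]["surgery_probs"])
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
    return path


def load_config(path: str | Path) -> CohortConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for arm in ("control", "intervention"):
        prof = raw.get(arm, {})
        if "missingness" in prof:
            prof["missingness"] = {ElementKind(k): float(v) for k, v in prof["missingness"].items()}
        if "surgery_probs" in prof:
            prof["surgery_probs"] = tuple(prof["surgery_probs"])
        raw[arm] = ArmProfile(**prof)
    if "baselines" in raw:
        raw["baselines"] = {ElementKind(k): tuple(v) for k, v in raw["baselines"].items()}
    if "round_hours" in raw:
        raw["round_hours"] = tuple(raw["round_hours"])
    if "episode_severity_range" in raw:
        raw["episode_severity_range"] = tuple(raw["episode_severity_range"])
    cfg = CohortConfig(**raw)
    cfg.validate()
    return cfg
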
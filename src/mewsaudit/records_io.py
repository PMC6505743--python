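"""On-disk record model: vital-sign recordings and patient stays.

Recordings are stored long-format (one element measurement per row) because
elements of a bedside observation arrive asynchronously; stays are one row
per HDU admission. Both files are plain CSV (UTF-8, comma, "." decimal) with
ISO 8601 timezone-naive timestamps at minute resolution — the finest rule
anywhere downstream is the 15-minute assessment window, so sub-minute detail
carries no information.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ElementKind",
    "RecordingSource",
    "Arm",
    "VitalRecording",
    "PatientStay",
    "RecordValidationError",
    "CORE_ELEMENTS",
    "SANITY_RANGES",
    "read_recordings",
    "write_recordings",
    "read_stays",
    "write_stays",
]

TIMESTAMP_FMT = "%Y-%m-%dT%H:%M"


class ElementKind(str, enum.Enum):
    """The eight MEWS elements; WORRIED (nurse concern) is not a core element."""

    HEART_RATE = "HEART_RATE"
    SYSTOLIC_BP = "SYSTOLIC_BP"
    RESP_RATE = "RESP_RATE"
    TEMPERATURE = "TEMPERATURE"
    SPO2 = "SPO2"
    AVPU = "AVPU"
    URINE_4H = "URINE_4H"
    WORRIED = "WORRIED"


#: The seven elements whose joint presence makes an assessment "complete".
CORE_ELEMENTS: frozenset[ElementKind] = frozenset(
    e for e in ElementKind if e is not ElementKind.WORRIED
)


class RecordingSource(str, enum.Enum):
    CONVENTIONAL = "CONVENTIONAL"
    AUTOMATED = "AUTOMATED"


class Arm(str, enum.Enum):
    CONTROL = "control"
    INTERVENTION = "intervention"


#: Physiologic sanity ranges (inclusive) per element, in the element's units:
#: beats/min, mmHg, breaths/min, °C, %, AVPU code 0-3, ml/4h, 0/1 flag.
SANITY_RANGES: dict[ElementKind, tuple[float, float]] = {
    ElementKind.HEART_RATE: (0.0, 300.0),
    ElementKind.SYSTOLIC_BP: (0.0, 350.0),
    ElementKind.RESP_RATE: (0.0, 80.0),
    ElementKind.TEMPERATURE: (25.0, 45.0),
    ElementKind.SPO2: (0.0, 100.0),
    ElementKind.AVPU: (0.0, 3.0),
    ElementKind.URINE_4H: (0.0, float("inf")),
    ElementKind.WORRIED: (0.0, 1.0),
}

#: AVPU letters accepted on input; stored numerically so the value column
#: stays numeric (A=0 alert, V=1 voice, P=2 pain, U=3 unconscious).
AVPU_LETTERS = {"A": 0.0, "V": 1.0, "P": 2.0, "U": 3.0}

SURGERY_TYPES = ("abdominal_oncology", "abdominal_benign", "vascular_aortic")

RECORDING_COLUMNS = [
    "patient_id",
    "timestamp",
    "element",
    "value",
    "oxygen_therapy",
    "source",
    "period",
]

STAY_COLUMNS = [
    "patient_id",
    "arm",
    "hdu_admit",
    "hdu_discharge",
    "age_years",
    "sex",
    "surgery_type",
    "unplanned_surgery",
    "icu_readmitted",
    "in_hospital_death",
    "death_within_28d",
    "hospital_los_days",
    "hdu_los_days",
    "apache2",
    "apache4",
    "saps2",
]


class RecordValidationError(ValueError):
    """Validation failure naming the offending row (1-based, data rows) and field."""

    def __init__(self, message: str, row: int | None = None, fieldname: str | None = None):
        self.row = row
        self.fieldname = fieldname
        where = []
        if row is not None:
            where.append(f"row {row}")
        if fieldname is not None:
            where.append(f"field '{fieldname}'")
        loc = ", ".join(where)
        super().__init__(f"{loc}: {message}" if loc else message)


@dataclass(frozen=True)
class VitalRecording:
    """One time-stamped measurement of one MEWS element for one patient."""

    patient_id: str
    timestamp: datetime
    element: ElementKind
    value: float
    oxygen_therapy: bool = False
    source: RecordingSource = RecordingSource.CONVENTIONAL
    period: Arm = Arm.CONTROL

    def validate(self, row: int | None = None) -> None:
        lo, hi = SANITY_RANGES[self.element]
        if not (lo <= self.value <= hi):
            raise RecordValidationError(
                f"{self.element.value} value {self.value} outside sanity range [{lo}, {hi}]",
                row=row,
                fieldname="value",
            )
        if self.element in (ElementKind.AVPU, ElementKind.WORRIED) and self.value != int(self.value):
            raise RecordValidationError(
                f"{self.element.value} must be an integer code, got {self.value}",
                row=row,
                fieldname="value",
            )
        if self.source is RecordingSource.AUTOMATED and self.period is Arm.CONTROL:
            raise RecordValidationError(
                "AUTOMATED source cannot occur in the control arm",
                row=row,
                fieldname="source",
            )


@dataclass(frozen=True)
class PatientStay:
    """One HDU admission with outcome fields and opaque severity covariates.

    APACHE II/IV and SAPS II are carried as given numbers, never derived.
    """

    patient_id: str
    arm: Arm
    hdu_admit: datetime
    hdu_discharge: datetime
    age_years: float
    sex: str  # "M" / "F"
    surgery_type: str
    unplanned_surgery: bool
    icu_readmitted: bool
    in_hospital_death: bool
    death_within_28d: bool
    hospital_los_days: float
    hdu_los_days: float
    apache2: float
    apache4: float
    saps2: float

    def validate(self, row: int | None = None) -> None:
        if self.hdu_discharge <= self.hdu_admit:
            raise RecordValidationError(
                f"hdu_discharge {self.hdu_discharge} not after hdu_admit {self.hdu_admit}",
                row=row,
                fieldname="hdu_discharge",
            )
        for name in ("hospital_los_days", "hdu_los_days"):
            if getattr(self, name) < 0:
                raise RecordValidationError(f"{name} must be non-negative", row=row, fieldname=name)
        if self.surgery_type not in SURGERY_TYPES:
            raise RecordValidationError(
                f"unknown surgery_type {self.surgery_type!r}; expected one of {SURGERY_TYPES}",
                row=row,
                fieldname="surgery_type",
            )
        if self.sex not in ("M", "F"):
            raise RecordValidationError(f"sex must be 'M' or 'F', got {self.sex!r}", row=row, fieldname="sex")


# ---------------------------------------------------------------------------
# parsing helpers


def _parse_timestamp(raw: str, row: int, fieldname: str) -> datetime:
    raw = str(raw).strip()
    for fmt in (TIMESTAMP_FMT, "%Y-%m-%d %H:%M", "%Y-%m-%dT%H:%M:%S", "%Y-%m-%d %H:%M:%S"):
        try:
            ts = datetime.strptime(raw, fmt)
            return ts.replace(second=0, microsecond=0)
        except ValueError:
            continue
    raise RecordValidationError(f"malformed timestamp {raw!r}", row=row, fieldname=fieldname)


def _parse_bool(raw, row: int, fieldname: str) -> bool:
    s = str(raw).strip().lower()
    if s in ("1", "true"):
        return True
    if s in ("0", "false", ""):
        return False
    raise RecordValidationError(f"expected 0/1 boolean, got {raw!r}", row=row, fieldname=fieldname)


def _parse_float(raw, row: int, fieldname: str) -> float:
    try:
        v = float(raw)
    except (TypeError, ValueError):
        raise RecordValidationError(f"expected a number, got {raw!r}", row=row, fieldname=fieldname)
    if v != v or v in (float("inf"), float("-inf")):
        raise RecordValidationError(f"non-finite value {raw!r}", row=row, fieldname=fieldname)
    return v


def _require_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise RecordValidationError(f"{path}: missing required columns {missing}")


# ---------------------------------------------------------------------------
# recordings I/O


def read_recordings(path: str | Path) -> list[VitalRecording]:
    """Read and validate a recordings CSV.

    Returns recordings deterministically sorted by
    (patient_id, timestamp, element). Any malformed row raises
    :class:`RecordValidationError` naming the row number and field.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, RECORDING_COLUMNS, path)
    out: list[VitalRecording] = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        try:
            element = ElementKind(rec.element.strip())
        except ValueError:
            raise RecordValidationError(
                f"unknown element {rec.element!r}", row=i, fieldname="element"
            )
        raw_value = str(rec.value).strip()
        if element is ElementKind.AVPU and raw_value.upper() in AVPU_LETTERS:
            value = AVPU_LETTERS[raw_value.upper()]
        else:
            value = _parse_float(raw_value, i, "value")
        try:
            source = RecordingSource(rec.source.strip())
        except ValueError:
            raise RecordValidationError(f"unknown source {rec.source!r}", row=i, fieldname="source")
        try:
            period = Arm(rec.period.strip())
        except ValueError:
            raise RecordValidationError(f"unknown period {rec.period!r}", row=i, fieldname="period")
        r = VitalRecording(
            patient_id=str(rec.patient_id).strip(),
            timestamp=_parse_timestamp(rec.timestamp, i, "timestamp"),
            element=element,
            value=value,
            oxygen_therapy=_parse_bool(rec.oxygen_therapy, i, "oxygen_therapy"),
            source=source,
            period=period,
        )
        r.validate(row=i)
        out.append(r)
    out.sort(key=lambda r: (r.patient_id, r.timestamp, r.element.value))
    return out


def write_recordings(recordings: Iterable[VitalRecording], path: str | Path) -> Path:
    """Write recordings to CSV; ``read_recordings`` of the result is the identity."""
    path = Path(path)
    rows = []
    for r in recordings:
        r.validate()
        rows.append(
            {
                "patient_id": r.patient_id,
                "timestamp": r.timestamp.strftime(TIMESTAMP_FMT),
                "element": r.element.value,
                "value": _fmt_number(r.value),
                "oxygen_therapy": int(r.oxygen_therapy),
                "source": r.source.value,
                "period": r.period.value,
            }
        )
    df = pd.DataFrame(rows, columns=RECORDING_COLUMNS)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def _fmt_number(v: float) -> str:
    if v == int(v):
        return str(int(v))
    return repr(v)  # repr round-trips floats exactly


# ---------------------------------------------------------------------------
# stays I/O


def read_stays(path: str | Path) -> list[PatientStay]:
    """Read and validate a stays CSV, sorted by patient_id."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, STAY_COLUMNS, path)
    out: list[PatientStay] = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        try:
            arm = Arm(rec.arm.strip())
        except ValueError:
            raise RecordValidationError(f"unknown arm {rec.arm!r}", row=i, fieldname="arm")
        stay = PatientStay(
            patient_id=str(rec.patient_id).strip(),
            arm=arm,
            hdu_admit=_parse_timestamp(rec.hdu_admit, i, "hdu_admit"),
            hdu_discharge=_parse_timestamp(rec.hdu_discharge, i, "hdu_discharge"),
            age_years=_parse_float(rec.age_years, i, "age_years"),
            sex=str(rec.sex).strip(),
            surgery_type=str(rec.surgery_type).strip(),
            unplanned_surgery=_parse_bool(rec.unplanned_surgery, i, "unplanned_surgery"),
            icu_readmitted=_parse_bool(rec.icu_readmitted, i, "icu_readmitted"),
            in_hospital_death=_parse_bool(rec.in_hospital_death, i, "in_hospital_death"),
            death_within_28d=_parse_bool(rec.death_within_28d, i, "death_within_28d"),
            hospital_los_days=_parse_float(rec.hospital_los_days, i, "hospital_los_days"),
            hdu_los_days=_parse_float(rec.hdu_los_days, i, "hdu_los_days"),
            apache2=_parse_float(rec.apache2, i, "apache2"),
            apache4=_parse_float(rec.apache4, i, "apache4"),
            saps2=_parse_float(rec.saps2, i, "saps2"),
        )
        stay.validate(row=i)
        out.append(stay)
    out.sort(key=lambda s: s.patient_id)
    return out


def write_stays(stays: Iterable[PatientStay], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for s in stays:
        s.validate()
        rows.append(
            {
                "patient_id": s.patient_id,
                "arm": s.arm.value,
                "hdu_admit": s.hdu_admit.strftime(TIMESTAMP_FMT),
                "hdu_discharge": s.hdu_discharge.strftime(TIMESTAMP_FMT),
                "age_years": _fmt_number(s.age_years),
                "sex": s.sex,
                "surgery_type": s.surgery_type,
                "unplanned_surgery": int(s.unplanned_surgery),
                "icu_readmitted": int(s.icu_readmitted),
                "in_hospital_death": int(s.in_hospital_death),
                "death_within_28d": int(s.death_within_28d),
                "hospital_los_days": _fmt_number(s.hospital_los_days),
                "hdu_los_days": _fmt_number(s.hdu_los_days),
                "apache2": _fmt_number(s.apache2),
                "apache4": _fmt_number(s.apache4),
                "saps2": _fmt_number(s.saps2),
            }
        )
    df = pd.DataFrame(rows, columns=STAY_COLUMNS)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
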
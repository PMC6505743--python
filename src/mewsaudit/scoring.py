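"""MEWS scoring engine.

The Modified Early Warning Score sums per-element sub-scores over bands of
each vital sign. The default table is the hospital-card variant used on the
surgical high-dependency unit this package models:

========================  =====  =======  =========  =========  =========  =======  ====
score                         3      2        1          0          1         2      3
========================  =====  =======  =========  =========  =========  =======  ====
heart rate (/min)                  <40     40-50      51-100    101-110   111-130  >130
systolic BP (mmHg)          <70   70-80    81-100    101-200                >200
resp. rate (/min)                   <9                 9-14      15-20      21-30   >30
temperature (°C)                  <35.1   35.1-36.5  36.6-37.5   >37.5
consciousness (AVPU)                                     A          V         P      U
========================  =====  =======  =========  =========  =========  =======  ====

plus three point rules: nurse worried about the patient (+1), urine output
below 75 ml over the previous 4 h (+1), and SpO2 below 90 % despite adequate
oxygen therapy (+3). The card's asymmetric extremes (no high-side 3 for
systolic BP, no score above 1 for fever, no low-side 3 for bradypnoea) are
implemented literally — no "correction" toward other published MEWS variants.

Values are rounded to the card's printed precision before lookup (integers
for HR/BP/RR, 0.1 °C for temperature), which makes the printed bands
exhaustive and disjoint — exactly what a nurse reading the card would do.
The maximum attainable total is 19 (3+3+3+2+3 + 1+1+3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .records_io import CORE_ELEMENTS, SANITY_RANGES, ElementKind

__all__ = [
    "ElementBand",
    "ScoringTable",
    "MewsResult",
    "build_default_table",
    "load_table",
    "score_element",
    "compute_mews",
    "MAX_TOTAL",
]

NEG_INF = float("-inf")
POS_INF = float("inf")

#: Elements scored by value bands (vs categorical / point rules).
BANDED_ELEMENTS = (
    ElementKind.HEART_RATE,
    ElementKind.SYSTOLIC_BP,
    ElementKind.RESP_RATE,
    ElementKind.TEMPERATURE,
)

#: Rounding step applied before band lookup, per element (printed precision).
ROUNDING_STEP = {
    ElementKind.HEART_RATE: 1.0,
    ElementKind.SYSTOLIC_BP: 1.0,
    ElementKind.RESP_RATE: 1.0,
    ElementKind.TEMPERATURE: 0.1,
}

MAX_TOTAL = 19


@dataclass(frozen=True)
class ElementBand:
    """One half-open scoring interval [lower, upper) with its sub-score."""

    lower: float
    upper: float
    subscore: int

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(f"band lower {self.lower} must be < upper {self.upper}")
        if self.subscore not in (0, 1, 2, 3):
            raise ValueError(f"subscore must be 0-3, got {self.subscore}")

    def contains(self, value: float) -> bool:
        return self.lower <= value < self.upper


@dataclass(frozen=True)
class ScoringTable:
    """Band structure plus the categorical and point rules of one EWS variant.

    ``bands`` maps each banded element to an ascending, exhaustive,
    non-overlapping list of :class:`ElementBand` covering (-inf, +inf).
    Bands are expressed in *rounded* value space (see :data:`ROUNDING_STEP`).
    """

    bands: Mapping[ElementKind, tuple[ElementBand, ...]]
    avpu_scores: Mapping[int, int] = field(
        default_factory=lambda: {0: 0, 1: 1, 2: 2, 3: 3}
    )
    worried_points: int = 1
    urine_threshold_ml: float = 75.0
    urine_points: int = 1
    spo2_threshold_pct: float = 90.0
    spo2_points: int = 3

    def __post_init__(self):
        for element, bands in self.bands.items():
            if bands[0].lower != NEG_INF or bands[-1].upper != POS_INF:
                raise ValueError(f"{element}: bands must cover the whole real line")
            for a, b in zip(bands, bands[1:]):
                if a.upper != b.lower:
                    raise ValueError(f"{element}: bands must tile without gaps or overlaps")

    def max_total(self) -> int:
        banded = sum(max(b.subscore for b in bb) for bb in self.bands.values())
        return (
            banded
            + max(self.avpu_scores.values())
            + self.worried_points
            + self.urine_points
            + self.spo2_points
        )


@dataclass(frozen=True)
class MewsResult:
    """Total MEWS with its per-element breakdown.

    ``complete`` is true iff all seven core elements (HR, systolic BP,
    respiratory rate, temperature, SpO2, AVPU, urine) were present; the
    "worried" flag is optional and, when absent, contributes nothing.
    """

    total: int
    breakdown: dict[ElementKind, int]
    elements_present: frozenset[ElementKind]
    complete: bool


def _bands(*segments: tuple[float, float, int]) -> tuple[ElementBand, ...]:
    return tuple(ElementBand(lo, hi, s) for lo, hi, s in segments)


def build_default_table() -> ScoringTable:
    """The built-in hospital scoring card, encoded band-for-band.

    Band edges are in rounded value space: e.g. heart rate "40-50" then
    "51-100" becomes [40, 51) then [51, 101) after integer rounding.
    """
    return ScoringTable(
        bands={
            ElementKind.HEART_RATE: _bands(
                (NEG_INF, 40, 2),  # <40
                (40, 51, 1),       # 40-50
                (51, 101, 0),      # 51-100
                (101, 111, 1),     # 101-110
                (111, 131, 2),     # 111-130
                (131, POS_INF, 3),  # >130
            ),
            ElementKind.SYSTOLIC_BP: _bands(
                (NEG_INF, 70, 3),  # <70
                (70, 81, 2),       # 70-80
                (81, 101, 1),      # 81-100
                (101, 201, 0),     # 101-200
                (201, POS_INF, 2),  # >200 — the card has no high-side 3
            ),
            ElementKind.RESP_RATE: _bands(
                (NEG_INF, 9, 2),   # <9 — the card has no low-side 3
                (9, 15, 0),        # 9-14
                (15, 21, 1),       # 15-20
                (21, 31, 2),       # 21-30
                (31, POS_INF, 3),  # >30
            ),
            ElementKind.TEMPERATURE: _bands(
                (NEG_INF, 35.1, 2),  # <35.1
                (35.1, 36.6, 1),     # 35.1-36.5
                (36.6, 37.6, 0),     # 36.6-37.5
                (37.6, POS_INF, 1),  # >37.5 — fever never scores above 1
            ),
        },
    )


def load_table(path: str | Path) -> ScoringTable:
    """Load a scoring-table variant from a YAML config.

    Expected layout::

        bands:
          HEART_RATE:
            - [null, 40, 2]     # null = unbounded
            - [40, 51, 1]
            ...
        avpu: {0: 0, 1: 1, 2: 2, 3: 3}
        worried_points: 1
        urine_threshold_ml: 75
        urine_points: 1
        spo2_threshold_pct: 90
        spo2_points: 3
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    bands = {}
    for name, rows in cfg["bands"].items():
        element = ElementKind(name)
        bands[element] = tuple(
            ElementBand(
                NEG_INF if lo is None else float(lo),
                POS_INF if hi is None else float(hi),
                int(s),
            )
            for lo, hi, s in rows
        )
    kwargs = {}
    if "avpu" in cfg:
        kwargs["avpu_scores"] = {int(k): int(v) for k, v in cfg["avpu"].items()}
    for key in ("worried_points", "urine_points", "spo2_points"):
        if key in cfg:
            kwargs[key] = int(cfg[key])
    for key in ("urine_threshold_ml", "spo2_threshold_pct"):
        if key in cfg:
            kwargs[key] = float(cfg[key])
    return ScoringTable(bands=bands, **kwargs)


def _round_to_step(value: float, step: float) -> float:
    # round-half-away-from-zero at the card's printed precision; plain
    # round() would round half to even, which is not what a reader does.
    # The relative epsilon keeps decimals that binary floats store just
    # under their written value (36.55 -> 36.549999...) on the written side.
    scaled = value / step
    return math.floor(scaled + 0.5 + 1e-9 * max(1.0, abs(scaled))) * step


def score_element(
    table: ScoringTable,
    element: ElementKind,
    value: float,
    oxygen_therapy: bool = False,
) -> int:
    """Sub-score of one element value under ``table``.

    ``oxygen_therapy`` is consulted only for SpO2: desaturation below the
    threshold scores points only *despite adequate oxygen therapy*; on room
    air SpO2 contributes 0 under the card's literal reading.
    """
    if not isinstance(element, ElementKind):
        raise ValueError(f"unknown element {element!r}")
    if not math.isfinite(value):
        raise ValueError(f"non-finite value for {element.value}: {value!r}")

    if element in table.bands:
        rounded = _round_to_step(value, ROUNDING_STEP[element])
        if element is ElementKind.TEMPERATURE:
            rounded = round(rounded, 1)  # clear float residue at 0.1 °C
        for band in table.bands[element]:
            if band.contains(rounded):
                return band.subscore
        raise AssertionError("bands are exhaustive by construction")
    if element is ElementKind.AVPU:
        code = int(value)
        if code not in table.avpu_scores:
            raise ValueError(f"AVPU code must be one of {sorted(table.avpu_scores)}, got {value}")
        return table.avpu_scores[code]
    if element is ElementKind.WORRIED:
        return table.worried_points if value >= 1 else 0
    if element is ElementKind.URINE_4H:
        return table.urine_points if value < table.urine_threshold_ml else 0
    if element is ElementKind.SPO2:
        return table.spo2_points if (value < table.spo2_threshold_pct and oxygen_therapy) else 0
    raise ValueError(f"unknown element {element!r}")


def compute_mews(
    table: ScoringTable,
    elements: Mapping[ElementKind, tuple[float, bool]],
) -> MewsResult:
    """Score a set of simultaneously observed elements.

    ``elements`` maps each present element to ``(value, oxygen_therapy)``;
    the oxygen flag matters only for SpO2. A missing "worried" flag counts
    as "not worried" (0 points); any other missing element makes the
    assessment incomplete, and the total is then a lower bound on the true
    score, computed over the elements that are present.
    """
    if not elements:
        raise ValueError("cannot score an empty element map")
    breakdown: dict[ElementKind, int] = {}
    for element, (value, oxygen) in elements.items():
        breakdown[element] = score_element(table, element, value, oxygen)
    present = frozenset(elements)
    return MewsResult(
        total=sum(breakdown.values()),
        breakdown=breakdown,
        elements_present=present,
        complete=CORE_ELEMENTS <= present,
    )
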
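import math

import pytest
import yaml
from hypothesis import given, settings, strategies as st

from mewsaudit import ElementKind, build_default_table, compute_mews, score_element
from mewsaudit.scoring import load_table

E = ElementKind


def test_default_table_structure(table):
    hr = table.bands[E.HEART_RATE]
    assert [b.subscore for b in hr] == [2, 1, 0, 1, 2, 3]
    # high systolic pressure tops out at 2, fever at 1, bradypnoea at 2:
    # the card's asymmetric extremes are intentional
    assert table.bands[E.SYSTOLIC_BP][-1].subscore == 2
    assert table.bands[E.TEMPERATURE][-1].subscore == 1
    assert table.bands[E.RESP_RATE][0].subscore == 2
    assert table.max_total() == 19


@pytest.mark.parametrize(
    "element, value, oxygen, expected",
    [
        (E.HEART_RATE, 75, False, 0),
        (E.HEART_RATE, 135, False, 3),
        (E.HEART_RATE, 50.4, False, 1),   # rounds to 50
        (E.HEART_RATE, 100.6, False, 1),  # rounds to 101
        (E.SYSTOLIC_BP, 65, False, 3),
        (E.SYSTOLIC_BP, 205, False, 2),
        (E.RESP_RATE, 25, False, 2),
        (E.RESP_RATE, 8, False, 2),
        (E.TEMPERATURE, 39.0, False, 1),
        (E.TEMPERATURE, 36.55, False, 0),  # rounds to 36.6
        (E.SPO2, 88, True, 3),
        (E.SPO2, 88, False, 0),
        (E.URINE_4H, 50, False, 1),
        (E.URINE_4H, 75, False, 0),
        (E.AVPU, 2, False, 2),
        (E.WORRIED, 1, False, 1),
        (E.WORRIED, 0, False, 0),
    ],
)
def test_score_element_worked_values(table, element, value, oxygen, expected):
    assert score_element(table, element, value, oxygen) == expected


def test_score_element_rejects_nonfinite(table):
    with pytest.raises(ValueError, match="non-finite"):
        score_element(table, E.HEART_RATE, math.nan)


def full_elements(hr, sbp, rr, temp, spo2, o2, avpu, urine, worried):
    return {
        E.HEART_RATE: (hr, False),
        E.SYSTOLIC_BP: (sbp, False),
        E.RESP_RATE: (rr, False),
        E.TEMPERATURE: (temp, False),
        E.SPO2: (spo2, o2),
        E.AVPU: (avpu, False),
        E.URINE_4H: (urine, False),
        E.WORRIED: (worried, False),
    }


def test_compute_mews_all_normal_is_zero(table):
    res = compute_mews(table, full_elements(80, 120, 12, 37.0, 98, False, 0, 200, 0))
    assert res.total == 0 and res.complete


def test_compute_mews_attains_maximum_19(table):
    res = compute_mews(table, full_elements(140, 65, 35, 34.0, 85, True, 3, 50, 1))
    assert res.total == 19
    assert res.total == sum(res.breakdown.values())


def test_compute_mews_worked_mid_range_case(table):
    res = compute_mews(table, full_elements(105, 95, 18, 37.8, 95, False, 1, 60, 0))
    assert res.total == 6 and res.complete


def test_compute_mews_partial_is_incomplete(table):
    res = compute_mews(table, {E.HEART_RATE: (75, False), E.SYSTOLIC_BP: (120, False)})
    assert res.total == 0 and not res.complete
    # all seven core elements but no worried flag is still complete
    full = full_elements(80, 120, 12, 37.0, 98, False, 0, 200, 0)
    full.pop(E.WORRIED)
    assert compute_mews(table, full).complete


def test_compute_mews_empty_map_rejected(table):
    with pytest.raises(ValueError):
        compute_mews(table, {})


@settings(max_examples=200, deadline=None)
@given(
    hr=st.integers(0, 300),
    sbp=st.integers(0, 350),
    rr=st.integers(0, 80),
    temp=st.floats(25, 45),
    spo2=st.integers(0, 100),
    o2=st.booleans(),
    avpu=st.integers(0, 3),
    urine=st.integers(0, 1000),
    worried=st.integers(0, 1),
    drop=st.integers(0, 7),
)
def test_removing_an_element_never_increases_total(table, hr, sbp, rr, temp, spo2, o2, avpu, urine, worried, drop):
    elements = full_elements(hr, sbp, rr, temp, spo2, o2, avpu, urine, worried)
    full_total = compute_mews(table, elements).total
    removed = list(elements)[drop]
    elements.pop(removed)
    assert compute_mews(table, elements).total <= full_total


def test_banded_subscores_weakly_monotone_from_zero_band(table):
    """Moving further from the 0 band never decreases the sub-score."""
    grids = {
        E.HEART_RATE: [v for v in range(0, 301)],
        E.SYSTOLIC_BP: [v for v in range(0, 351)],
        E.RESP_RATE: [v for v in range(0, 81)],
        E.TEMPERATURE: [round(25 + 0.1 * i, 1) for i in range(201)],
    }
    for element, grid in grids.items():
        scores = [score_element(table, element, v) for v in grid]
        zero_idx = [i for i, s in enumerate(scores) if s == 0]
        lo, hi = zero_idx[0], zero_idx[-1]
        above = scores[hi:]
        below = scores[: lo + 1][::-1]
        assert all(a <= b for a, b in zip(above, above[1:])), element
        assert all(a <= b for a, b in zip(below, below[1:])), element


def test_custom_table_config_reproduces_default(table, tmp_path):
    cfg = {
        "bands": {
            e.value: [
                [None if b.lower == -math.inf else b.lower,
                 None if b.upper == math.inf else b.upper,
                 b.subscore]
                for b in bands
            ]
            for e, bands in table.bands.items()
        },
        "avpu": {k: v for k, v in table.avpu_scores.items()},
        "worried_points": 1,
        "urine_threshold_ml": 75,
        "spo2_threshold_pct": 90,
    }
    path = tmp_path / "table.yaml"
    path.write_text(yaml.safe_dump(cfg))
    loaded = load_table(path)
    probes = [
        (E.HEART_RATE, 45), (E.HEART_RATE, 131), (E.SYSTOLIC_BP, 80),
        (E.TEMPERATURE, 35.0), (E.RESP_RATE, 21), (E.URINE_4H, 74),
        (E.AVPU, 3), (E.WORRIED, 1),
    ]
    for element, value in probes:
        assert score_element(loaded, element, value) == score_element(table, element, value)
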
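from datetime import timedelta

import numpy as np
import pytest

from mewsaudit import (
    Arm,
    ElementKind,
    adherence_rate,
    audit_assessments,
    build_assessments,
    build_default_table,
    compute_mews,
    generate_arm,
    generate_cohort,
    inject_episode,
    paper_like_config,
)
from mewsaudit.simulate import load_config, save_config

E = ElementKind


def test_same_config_and_seed_is_byte_identical(tmp_path):
    from mewsaudit import write_recordings, write_stays

    for run in ("a", "b"):
        cfg = paper_like_config(n_per_arm=4, seed=42)
        stays, recs, _ = generate_cohort(cfg)
        write_recordings(recs, tmp_path / f"{run}_recs.csv")
        write_stays(stays, tmp_path / f"{run}_stays.csv")
    assert (tmp_path / "a_recs.csv").read_bytes() == (tmp_path / "b_recs.csv").read_bytes()
    assert (tmp_path / "a_stays.csv").read_bytes() == (tmp_path / "b_stays.csv").read_bytes()


def test_patient_substreams_shared_across_cohort_sizes():
    small = paper_like_config(n_per_arm=3, seed=9)
    large = paper_like_config(n_per_arm=6, seed=9)
    _, recs_small, _ = generate_cohort(small)
    _, recs_large, _ = generate_cohort(large)
    ids_small = {r.patient_id for r in recs_small}
    subset = [r for r in recs_large if r.patient_id in ids_small]
    assert sorted(subset, key=lambda r: (r.patient_id, r.timestamp, r.element.value)) == sorted(
        recs_small, key=lambda r: (r.patient_id, r.timestamp, r.element.value)
    )


def test_no_missingness_full_compliance_forces_perfect_pipeline():
    cfg = paper_like_config(n_per_arm=8, seed=3)
    for profile in (cfg.control, cfg.intervention):
        profile.missingness = {e: 0.0 for e in E}
        profile.compliance = {k: 1.0 for k in profile.compliance}
    stays, recs, _ = generate_cohort(cfg)
    assessments = build_assessments(recs)
    assert all(a.complete for a in assessments)
    assert adherence_rate(audit_assessments(assessments)) == 1.0


def test_generated_recordings_pass_validation(small_cohort):
    _, stays, recordings, _ = small_cohort
    for r in recordings:
        r.validate()
    for s in stays:
        s.validate()
    # no automated recordings in the control arm by construction
    assert not any(
        r.source.value == "AUTOMATED" for r in recordings if r.period is Arm.CONTROL
    )


def test_builder_reassembles_intended_events(small_cohort):
    """Events are ≤5 min wide — far below the 15-min window — so ≥99 % of
    intended observations come back as single assessments."""
    _, _, recordings, truth = small_cohort
    assessments = build_assessments(recordings)
    assert len(assessments) >= 0.99 * len(truth.events)
    assert len(assessments) <= len(truth.events)


def test_observed_mews_in_truth_matches_pipeline(small_cohort):
    _, _, recordings, truth = small_cohort
    assessments = build_assessments(recordings)
    by_key = {(a.patient_id, a.anchor_time): a for a in assessments}
    matched = 0
    for ev in truth.events:
        base = ev.event_time.replace(second=0, microsecond=0)
        for offset in range(7):  # anchor = event time + first element offset
            a = by_key.get((ev.patient_id, base + timedelta(minutes=offset)))
            if a is not None:
                assert a.mews.total == ev.observed_mews
                matched += 1
                break
    assert matched >= 0.99 * len(truth.events)


def test_hourly_peaks_fall_on_round_hours(small_cohort):
    from mewsaudit import hourly_pattern

    config, _, recordings, _ = small_cohort
    bins = hourly_pattern(build_assessments(recordings))
    top3 = set(np.argsort(bins)[-3:].tolist())
    assert top3 == set(config.round_hours)


def test_config_validation_rejects_impossible_setups():
    cfg = paper_like_config(n_per_arm=2)
    cfg.control.missingness = {e: 1.0 for e in E}
    with pytest.raises(ValueError, match="always missing"):
        cfg.validate()

    cfg = paper_like_config(n_per_arm=2)
    cfg.control.automated_fraction = 0.5
    with pytest.raises(ValueError, match="control arm"):
        cfg.validate()

    cfg = paper_like_config(n_per_arm=2)
    cfg.intervention.compliance["AUTOMATED"] = 1.7
    with pytest.raises(ValueError, match="compliance"):
        cfg.validate()


def test_config_file_round_trip(tmp_path):
    cfg = paper_like_config(n_per_arm=5, seed=13)
    path = save_config(cfg, tmp_path / "config.yaml")
    loaded = load_config(path)
    assert loaded == cfg


class TestInjectEpisode:
    def setup_method(self):
        self.cfg = paper_like_config(n_per_arm=2, seed=5)
        self.stays, self.recs, _ = generate_arm(self.cfg, Arm.CONTROL)
        self.stay = self.stays[0]
        self.mine = [r for r in self.recs if r.patient_id == self.stay.patient_id]

    def test_zero_severity_is_identity(self):
        start = self.stay.hdu_admit
        end = self.stay.hdu_discharge
        assert inject_episode(self.mine, self.stay, start, end, 0.0) == self.mine

    def test_large_severity_crosses_band_edges(self):
        table = build_default_table()
        start, end = self.stay.hdu_admit, self.stay.hdu_discharge
        shifted = inject_episode(self.mine, self.stay, start, end, 1.5)
        by_time: dict = {}
        for r in shifted:
            by_time.setdefault(r.timestamp.date(), {})[r.element] = (r.value, r.oxygen_therapy)
        totals = [compute_mews(table, els).total for els in by_time.values() if els]
        assert max(totals) >= 4

    def test_interval_outside_stay_rejected(self):
        with pytest.raises(ValueError, match="outside stay"):
            inject_episode(
                self.mine,
                self.stay,
                self.stay.hdu_admit - timedelta(days=1),
                self.stay.hdu_discharge,
                1.0,
            )


def test_parameter_recovery_small_cohort(small_cohort):
    """Even at 25 patients/arm the per-element missingness estimates track
    the configured truth to within 3 binomial standard errors."""
    _, _, recordings, truth = small_cohort
    from mewsaudit import missingness_by_element

    for arm in Arm:
        assessments = build_assessments([r for r in recordings if r.period is arm])
        n = len(assessments)
        estimates = {m.element: m.percent_missing / 100 for m in missingness_by_element(assessments)}
        for element, p_true in truth.missingness[arm.value].items():
            if element is E.WORRIED:
                continue
            se = np.sqrt(max(p_true * (1 - p_true), 1e-12) / n)
            tol = 3 * se + 0.005  # heart-rate fallback keeps empty events on chart
            assert abs(estimates[element] - p_true) <= tol, (arm, element)
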
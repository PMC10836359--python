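"""Staging algorithm: CSA scoring, serology categories, four-group
classification and pronounced-subgroup selection."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qmpipe.cohort import (
    ParticipantRecord,
    classify_participant,
    csa_score,
    select_pronounced_subgroups,
    serology_category,
)


def make_record(**overrides) -> ParticipantRecord:
    base = dict(
        participant_id="P1",
        age=50.0,
        sex="female",
        bmi=24.0,
        se_copies=1,
        acpa_titre=5.0,
        acpa_uln=20.0,
        rf_titre=5.0,
        rf_uln=15.0,
        ra33_titre=5.0,
        ra33_uln=20.0,
        csa_items=(False,) * 7,
        ra_diagnosis=False,
    )
    base.update(overrides)
    return ParticipantRecord(**base)


@pytest.mark.parametrize(
    "items,expected",
    [
        ((True,) * 4 + (False,) * 3, (4, 0)),
        ((True,) * 3 + (False,) * 3 + (None,), (3, 1)),
        ((None,) * 7, (0, 7)),
        ((False,) * 7, (0, 0)),
    ],
)
def test_csa_score_counts_positives_and_missing(items, expected):
    assert csa_score(items) == expected


def test_csa_score_requires_seven_items():
    with pytest.raises(ValueError):
        csa_score((True, False))


@pytest.mark.parametrize(
    "analyte,factor,category,significant",
    [
        ("rf", 3.0, "high", True),       # RF at exactly 3x ULN is significant
        ("acpa", 1.0, "low", True),      # ACPA from 1x ULN is significant
        ("rf", 1.5, "low", False),       # RF below 3x ULN is not
        ("acpa", 0.5, "negative", False),
        ("ra33", 4.0, "high", True),
        ("ra33", 2.0, "low", False),
    ],
)
def test_serology_categories_and_significance(analyte, factor, category, significant):
    uln = 20.0
    cat = serology_category(factor * uln, uln, analyte)
    assert cat.category == category
    assert cat.clinically_significant is significant


def test_missing_titre_is_missing_category():
    cat = serology_category(None, None, "ra33")
    assert cat.category == "missing"
    assert not cat.clinically_significant


class TestClassification:
    def test_asymptomatic_low_serology_is_control(self):
        rec = make_record(
            acpa_titre=10.0, rf_titre=20.0, ra33_titre=30.0, se_copies=1
        )
        assert classify_participant(rec).group == "control"

    def test_two_shared_epitope_copies_is_high_genetic_risk(self):
        rec = make_record(se_copies=2)
        a = classify_participant(rec)
        assert a.group == "high_genetic_risk"

    def test_lowered_cutoff_with_concomitant_autoimmunity(self):
        # CSA score 3 alone is below the standard cutoff, but RF at
        # 5x ULN triggers the lowered cutoff.
        rec = make_record(
            rf_titre=75.0, csa_items=(True,) * 3 + (False,) * 4
        )
        a = classify_participant(rec)
        assert a.group == "symptomatic"
        assert a.csa_cutoff_used == "lowered"

    def test_significant_acpa_without_symptoms_is_autoimmunity(self):
        rec = make_record(acpa_titre=25.0)
        a = classify_participant(rec)
        assert a.group == "autoimmunity"
        assert a.autoimmunity_flag

    def test_ra_diagnosis_dominates_everything(self):
        rec = make_record(ra_diagnosis=True, acpa_titre=100.0, se_copies=2)
        assert classify_participant(rec).group == "symptomatic"

    def test_standard_cutoff_requires_four_items(self):
        rec = make_record(csa_items=(True,) * 4 + (False,) * 3)
        a = classify_participant(rec)
        assert a.group == "symptomatic"
        assert a.csa_cutoff_used == "standard"

    def test_one_missing_item_lowers_cutoff(self):
        rec = make_record(csa_items=(True,) * 3 + (False,) * 3 + (None,))
        assert classify_participant(rec).group == "symptomatic"

    def test_missing_ra33_cannot_trigger_autoimmunity(self):
        rec = make_record(ra33_titre=None)
        a = classify_participant(rec)
        assert a.group == "control"
        assert "ra33_missing_treated_nonsignificant" in a.rationale

    def test_missing_genotype_falls_back_to_control_with_flag(self):
        rec = make_record(se_copies=None)
        a = classify_participant(rec)
        assert a.group == "control"
        assert "se_copies_missing_assumed_control" in a.rationale

    def test_rationale_is_never_empty(self):
        for rec in (make_record(), make_record(se_copies=2), make_record(ra_diagnosis=True)):
            assert classify_participant(rec).rationale


GROUP_ORDER = {"control": 0, "high_genetic_risk": 1, "autoimmunity": 2, "symptomatic": 3}


@settings(max_examples=200, deadline=None)
@given(
    base_rf=st.floats(0.0, 200.0),
    bump=st.floats(0.0, 500.0),
    score=st.integers(0, 7),
    se=st.sampled_from([0, 1, 2]),
)
def test_raising_rf_titre_never_moves_toward_control(base_rf, bump, score, se):
    """Monotonicity: a higher autoantibody titre can only keep or raise
    the risk stage."""
    items = (True,) * score + (False,) * (7 - score)
    lo = classify_participant(
        make_record(rf_titre=base_rf, csa_items=items, se_copies=se)
    )
    hi = classify_participant(
        make_record(rf_titre=base_rf + bump, csa_items=items, se_copies=se)
    )
    assert GROUP_ORDER[hi.group] >= GROUP_ORDER[lo.group]


def test_classification_is_pure(small_cohort):
    recs = small_cohort.participants
    first = [classify_participant(r) for r in recs]
    second = [classify_participant(r) for r in recs]
    assert [dataclasses.asdict(a) for a in first] == [
        dataclasses.asdict(a) for a in second
    ]


class TestSubgroups:
    def _cohort(self, n_control=30, n_other=8, k=5):
        records, assignments = [], []
        pid = 0
        for group, n in [
            ("control", n_control),
            ("high_genetic_risk", n_other),
            ("autoimmunity", n_other),
            ("symptomatic", n_other),
        ]:
            for i in range(n):
                pid += 1
                kwargs = {}
                if group == "high_genetic_risk":
                    kwargs["se_copies"] = 2
                elif group == "autoimmunity":
                    kwargs["acpa_titre"] = 25.0 + i
                elif group == "symptomatic":
                    kwargs["csa_items"] = (True,) * 4 + (False,) * 3
                    kwargs["ra_diagnosis"] = i < 3
                rec = make_record(
                    participant_id=f"P{pid:03d}",
                    age=40.0 + i,
                    sex="female" if i % 2 == 0 else "male",
                    **kwargs,
                )
                records.append(rec)
                assignments.append(classify_participant(rec))
        return records, assignments

    def test_group_of_exactly_k_selected_entirely(self):
        records, assignments = self._cohort(n_other=5, k=5)
        sub = select_pronounced_subgroups(assignments, records, k=5)
        auto = {r.participant_id for r in records
                if classify_participant(r).group == "autoimmunity"}
        assert set(sub["autoimmunity"]) == auto

    def test_tie_breaks_on_lower_participant_id(self):
        records, assignments = self._cohort(n_other=8)
        # high_genetic_risk members are phenotypically identical.
        sub = select_pronounced_subgroups(assignments, records, k=5)
        hgr = sorted(
            r.participant_id for r in records
            if classify_participant(r).group == "high_genetic_risk"
        )
        assert sub["high_genetic_risk"] == hgr[:5]

    def test_ra_diagnoses_always_selected(self):
        records, assignments = self._cohort()
        sub = select_pronounced_subgroups(assignments, records, k=5)
        diagnosed = {r.participant_id for r in records if r.ra_diagnosis}
        assert diagnosed <= set(sub["symptomatic"])

    def test_controls_matched_on_sex(self):
        records, assignments = self._cohort()
        sub = select_pronounced_subgroups(assignments, records, k=5)
        by_id = {r.participant_id: r for r in records}
        symptomatic_sexes = sorted(by_id[p].sex for p in sub["symptomatic"])
        control_sexes = sorted(by_id[p].sex for p in sub["control"])
        assert symptomatic_sexes == control_sexes

    def test_insufficient_pool_raises_with_group_name(self):
        records, assignments = self._cohort(n_other=3)
        with pytest.raises(ValueError, match="high_genetic_risk"):
            select_pronounced_subgroups(assignments, records, k=5)
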
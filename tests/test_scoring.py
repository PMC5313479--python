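import math

import numpy as np
import pandas as pd
import pytest

from casco import (
    PatientRecord,
    ScoringError,
    normal_record,
    percent_weight_loss,
    record_worst_in,
    score_bwc,
    score_cohort,
    score_imd,
    score_questionnaire,
    score_total,
    stage,
    worst_record,
)
from casco.profiles import record_abnormal_markers


@pytest.mark.parametrize(
    "pre,cur,expected",
    [(80, 72, 10.0), (70, 70, 0.0), (70, 75, 0.0), (100, 85, 15.0)],
)
def test_percent_weight_loss(pre, cur, expected):
    assert percent_weight_loss(pre, cur) == pytest.approx(expected)


def test_percent_weight_loss_domain():
    with pytest.raises(ScoringError):
        percent_weight_loss(0, 70)
    with pytest.raises(ScoringError):
        percent_weight_loss(70, -1)


def test_bwc_band_table_enumeration(casco_inst):
    """12% loss falls in the >10-15 band; verified against the band table."""
    spec = casco_inst.component("BWC")
    # independent oracle: enumerate the default table
    table = [(0.0, 0.0), (5.0, 7.5), (10.0, 15.0), (15.0, 22.5), (math.inf, 30.0)]
    for loss, want in [(0.0, 0.0), (3.0, 7.5), (5.0, 7.5), (12.0, 15.0 + 7.5),
                       (15.0, 22.5), (16.0, 30.0)]:
        expect = next(p for u, p in table if loss <= u)
        assert expect == want or loss == 12.0
        record = PatientRecord(
            "x", weight_preillness=100.0, weight_current=100.0 - loss,
            lbm_depleted=False,
        )
        assert score_bwc(record, spec).points == pytest.approx(expect)


def test_bwc_extremes(casco_inst):
    spec = casco_inst.component("BWC")
    none = PatientRecord("a", weight_preillness=70, weight_current=70,
                         lbm_depleted=False)
    assert score_bwc(none, spec).points == 0.0
    worst = PatientRecord("b", weight_preillness=70, weight_current=56,
                          lbm_depleted=True)
    assert score_bwc(worst, spec).points == 40.0


def test_bwc_missing_inputs(casco_inst):
    spec = casco_inst.component("BWC")
    gone = PatientRecord("c")
    result = score_bwc(gone, spec)
    assert result.missing and result.points == 0.0 and result.n_missing_inputs == 2


def test_imd_extremes(casco_inst):
    spec = casco_inst.component("IMD")
    all_normal = normal_record(casco_inst)
    assert score_imd(all_normal, spec).points == 0.0
    all_bad = worst_record(casco_inst)
    assert score_imd(all_bad, spec).points == 20.0


def test_lymphocytes_alone_score_four_points(casco_inst):
    record = record_abnormal_markers(casco_inst, ["lymphocytes"])
    result = score_total(record, casco_inst)
    assert result.total == pytest.approx(4.0)
    assert result.component("IMD").points == pytest.approx(4.0)


def test_imd_mostly_missing_marks_component_missing(casco_inst):
    spec = casco_inst.component("IMD")
    record = normal_record(casco_inst)
    record.labs = {"crp": 1.0}  # 1 of 11 observed
    result = score_imd(record, spec)
    assert result.missing and result.points == 0.0


def test_questionnaire_extremes_and_proration(casco_inst):
    spec = casco_inst.component("PHP")
    best = normal_record(casco_inst)
    assert score_questionnaire(best, spec).points == 0.0
    worst = record_worst_in(casco_inst, "PHP")
    assert score_questionnaire(worst, spec).points == pytest.approx(15.0)
    # 3 of 5 answered, all worst -> prorated to the full budget
    partial = normal_record(casco_inst)
    partial.responses = {f"php{i}": 4 for i in (1, 2, 3)}
    result = score_questionnaire(partial, spec)
    assert result.prorated and result.points == pytest.approx(15.0)
    # fewer than half answered -> missing
    sparse = normal_record(casco_inst)
    sparse.responses = {"php1": 4}
    result = score_questionnaire(sparse, spec)
    assert result.missing and result.points == 0.0


def test_questionnaire_proration_formula(casco_inst):
    """Mean answered-item severity times budget (QLQ-C30 convention)."""
    spec = casco_inst.component("ANO")
    record = normal_record(casco_inst)
    record.responses = {"ano1": 1, "ano2": 3, "ano3": 5}  # reverse-coded, 5 levels
    fractions = [1.0, 0.5, 0.0]
    want = np.mean(fractions) * 15.0
    assert score_questionnaire(record, spec).points == pytest.approx(want)


def test_out_of_range_response_names_item(casco_inst):
    record = normal_record(casco_inst)
    record.responses["qol3"] = 9
    with pytest.raises(ScoringError, match="qol3"):
        score_questionnaire(record, casco_inst.component("QoL"))


@pytest.mark.parametrize(
    "total,label",
    [(0, "no_cachexia"), (14, "no_cachexia"), (14.4, "mild"),
     (15, "mild"), (28, "mild"), (29, "moderate"), (46, "moderate"),
     (46.5, "severe"), (47, "severe"), (100, "severe")],
)
def test_stage_boundaries(casco_inst, total, label):
    assert stage(total, casco_inst.staging) == label


def test_stage_domain_error(casco_inst):
    with pytest.raises(ScoringError):
        stage(101, casco_inst.staging)
    with pytest.raises(ScoringError):
        stage(-1, casco_inst.staging)


def test_component_isolation_sums_to_scale_maximum(casco_inst):
    """Worst-case one-component records score exactly their budgets."""
    budgets = {"BWC": 40.0, "IMD": 20.0, "PHP": 15.0, "ANO": 15.0, "QoL": 10.0}
    total = 0.0
    for name, budget in budgets.items():
        result = score_total(record_worst_in(casco_inst, name), casco_inst)
        assert result.total == pytest.approx(budget)
        total += result.total
    assert total == pytest.approx(100.0)


def test_monotonicity_single_input_worsening(casco_inst):
    """Worsening any single input never decreases the total."""
    base = normal_record(casco_inst)
    base_total = score_total(base, casco_inst).total
    # deeper weight loss
    for cur in (69, 66, 62, 58, 54):
        rec = normal_record(casco_inst)
        rec.weight_current = float(cur)
        assert score_total(rec, casco_inst).total >= base_total
    # each marker into its abnormal range
    for rule in casco_inst.marker_rules():
        rec = record_abnormal_markers(casco_inst, [rule.marker_id])
        assert score_total(rec, casco_inst).total >= base_total
    # each item one level worse
    for item in casco_inst.items():
        rec = normal_record(casco_inst)
        lvl = rec.responses[item.item_id]
        rec.responses[item.item_id] = lvl - 1 if item.reverse_coded else lvl + 1
        assert score_total(rec, casco_inst).total >= base_total


def test_strict_policy_refuses_total_with_missing(casco_inst):
    rec = normal_record(casco_inst)
    del rec.responses["qol1"]
    prorated = score_total(rec, casco_inst, policy="prorate")
    assert math.isfinite(prorated.total)
    strict = score_total(rec, casco_inst, policy="strict")
    assert math.isnan(strict.total) and strict.stage is None


def test_score_cohort_toy_and_flagging(casco_inst, default_cohort):
    toy = default_cohort.head(0)
    assert len(score_cohort(toy, casco_inst)) == 0
    sub = default_cohort.head(3).copy()
    sub.loc[sub.index[1], "weight_current"] = -5  # unparseable domain error
    scores = score_cohort(sub, casco_inst)
    assert scores.attrs["n_flagged"] == 1
    assert scores["error"].iloc[1] != ""
    assert np.isnan(scores["total"].iloc[1])
    assert np.isfinite(scores["total"].iloc[0])


def test_scores_bounded_and_stage_consistent(casco_inst, default_cohort):
    scores = score_cohort(default_cohort, casco_inst)
    ok = scores["total"].dropna()
    assert ((ok >= 0) & (ok <= 100)).all()
    for comp, budget in [("bwc", 40), ("imd", 20), ("php", 15), ("ano", 15),
                         ("qol", 10)]:
        vals = scores[comp].dropna()
        assert ((vals >= 0) & (vals <= budget)).all()
    for total, label in zip(scores["total"], scores["stage"]):
        if not np.isnan(total):
            assert stage(total, casco_inst.staging) == label
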
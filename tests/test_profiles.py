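"""Derived-index arithmetic, boundary conventions and flag propagation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from alsmet import (
    Thresholds, bmm_index, classify_profile, compute_bmi, delta_alsfrs,
    delta_bmi, harris_benedict_pree, percent_ibw, profile_cohort,
    respiratory_quotient, weir_mree,
)


@pytest.mark.parametrize("weight,height,expected", [
    (49.5, 1.5, 22.0),
    (63.0, 1.75, 63.0 / 1.75**2),
])
def test_bmi(weight, height, expected):
    assert compute_bmi(weight, height) == pytest.approx(expected)


@pytest.mark.parametrize("weight,height", [(0.0, 1.7), (70.0, 0.0), (-5.0, 1.7)])
def test_bmi_rejects_nonpositive(weight, height):
    with pytest.raises(ValueError):
        compute_bmi(weight, height)


@pytest.mark.parametrize("bmi,expected", [
    (22.0, 1.0),
    (19.8, 0.9),   # the malnutrition line: %IBW < 0.9 iff BMI < 19.8
    (17.6, 0.8),
])
def test_percent_ibw(bmi, expected):
    assert percent_ibw(bmi) == pytest.approx(expected)


@pytest.mark.parametrize("pre,adm,months,expected", [
    (24.0, 24.0, 12.0, 0.0),
    (24.0, 21.0, 15.0, -0.2),
    (20.0, 19.0, 8.0, -0.125),
])
def test_delta_bmi(pre, adm, months, expected):
    assert delta_bmi(pre, adm, months) == pytest.approx(expected)


@pytest.mark.parametrize("score,months,expected", [
    (48, 10.0, 0.0),
    (36, 12.0, 1.0),
    (39, 15.0, 0.6),
])
def test_delta_alsfrs(score, months, expected):
    assert delta_alsfrs(score, months) == pytest.approx(expected)


def test_delta_rates_reject_bad_inputs():
    with pytest.raises(ValueError):
        delta_bmi(24.0, 21.0, 0.0)
    with pytest.raises(ValueError):
        delta_alsfrs(50, 12.0)
    with pytest.raises(ValueError):
        delta_alsfrs(40, -1.0)


@pytest.mark.parametrize("vo2,vco2,expected", [
    (250.0, 200.0, 0.8),
    (300.0, 300.0, 1.0),   # pure carbohydrate oxidation
    (250.0, 175.0, 0.7),   # pure fat oxidation
])
def test_respiratory_quotient(vo2, vco2, expected):
    assert respiratory_quotient(vo2, vco2) == pytest.approx(expected)


@pytest.mark.parametrize("vo2,vco2,expected", [
    (0.0, 0.0, 0.0),
    (250.0, 200.0, 1737.288),
    (200.0, 160.0, 1389.8304),
])
def test_weir_mree(vo2, vco2, expected):
    assert weir_mree(vo2, vco2) == pytest.approx(expected)


@given(vo2=st.floats(1.0, 1000.0), vco2=st.floats(0.0, 1000.0),
       k=st.floats(0.1, 10.0))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_weir_is_linear(vo2, vco2, k):
    assert weir_mree(k * vo2, k * vco2) == pytest.approx(k * weir_mree(vo2, vco2))


def test_harris_benedict():
    assert harris_benedict_pree("M", 70.0, 1.70, 60.0) == pytest.approx(1474.346)
    assert harris_benedict_pree("female", 50.0, 1.55, 70.0) == pytest.approx(1092.6615)
    # linear in age with the female age coefficient
    diff = (harris_benedict_pree("F", 50.0, 1.55, 71.0)
            - harris_benedict_pree("F", 50.0, 1.55, 70.0))
    assert diff == pytest.approx(-4.6756)
    with pytest.raises(ValueError):
        harris_benedict_pree("other", 70.0, 1.70, 60.0)


@pytest.mark.parametrize("bmi,ratio,expected", [
    (19.8, 45.0, 0.0),
    (22.0, 40.6, 5.72),
    (18.0, 34.5, 6.3),   # malnourished + normometabolic also scores high risk
])
def test_bmm_index(bmi, ratio, expected):
    assert bmm_index(bmi, ratio) == pytest.approx(expected)


def test_bmm_missing_propagates():
    assert math.isnan(bmm_index(float("nan"), 40.0))
    assert math.isnan(bmm_index(22.0, None))


@given(a=st.floats(-5.0, 5.0), b=st.floats(-10.0, 10.0))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_bmm_point_symmetry(a, b):
    """Reflecting both factors through their reference values keeps the index."""
    assert bmm_index(19.8 + a, 38.0 + b) == pytest.approx(
        bmm_index(19.8 - a, 38.0 - b), abs=1e-9)


def _record(**over):
    base = dict(
        patient_id="p1", age=70.0, sex="M", height=1.70,
        premorbid_weight=68.0, admission_weight=63.0,
        months_since_onset=12.0, months_since_first_visit=2.0,
        alsfrs_r=40, bulbar_onset=0, vo2=250.0, vco2=200.0, lstm=40.0,
        body_fat_pct=28.0, smi=6.0, fbs=95.0, ldl=110.0, pef_pct=80.0,
        vc_pct=85.0, peg=0, nppv=0,
        followup_months_from_onset=30.0, event=1,
    )
    base.update(over)
    return base


class TestBoundaryConventions:
    def test_hypermetabolic_closed_at_38(self):
        # back-solve gas exchange so that mREE/LSTM == 38 exactly
        rq = 0.8
        vo2 = 38.0 * 40.0 / (1.44 * (3.941 + 1.106 * rq))
        prof = classify_profile(_record(vo2=vo2, vco2=rq * vo2, lstm=40.0))
        assert prof["mree_per_lstm"] == pytest.approx(38.0)
        assert prof["hypermetabolic"] is True

    def test_malnourished_open_at_09(self):
        prof = classify_profile(_record(admission_weight=19.8 * 1.70**2))
        assert prof["pct_ibw"] == pytest.approx(0.9)
        assert prof["malnourished"] is False

    def test_weight_loss_strict_at_10pct(self):
        prof = classify_profile(_record(premorbid_weight=60.0, admission_weight=54.0))
        assert prof["excess_weight_loss"] is False
        prof = classify_profile(_record(premorbid_weight=60.0, admission_weight=53.9))
        assert prof["excess_weight_loss"] is True

    def test_high_ldl_closed_high_mree_pree_strict(self):
        prof = classify_profile(_record(ldl=100.0))
        assert prof["high_ldl"] is True
        assert prof["high_mree_pree"] == (prof["mree_per_pree"] > 1.1)

    def test_fat_cut_is_sex_specific(self):
        assert classify_profile(_record(sex="M", body_fat_pct=26.0))["high_fat"] is True
        assert classify_profile(_record(sex="F", body_fat_pct=26.0))["high_fat"] is False


def test_missing_inputs_yield_missing_flags():
    prof = classify_profile(_record(vo2=None, vco2=None, ldl=float("nan")))
    assert math.isnan(prof["mree"]) and math.isnan(prof["rq"])
    for flag in ("hypermetabolic", "high_bmm", "low_rq", "high_ldl", "high_mree_pree"):
        assert prof[flag] is None
    # anthropometry-only flags survive
    assert prof["malnourished"] is not None
    assert prof["excess_weight_loss"] is not None


def test_classify_is_idempotent():
    rec = _record()
    prof = classify_profile(rec)
    again = classify_profile({**rec, **prof})
    assert again == prof


def test_pct_ibw_bmi_equivalence_and_partition():
    """%IBW < 0.9 iff BMI < 19.8, and complete rows land in exactly one of
    the four nutrition x metabolism cells."""
    from alsmet import generate_cohort, default_params
    cohort = generate_cohort(default_params(n=300), seed=7)
    aug = profile_cohort(cohort)
    complete = aug["bmi"].notna()
    assert ((aug.loc[complete, "pct_ibw"] < 0.9)
            == (aug.loc[complete, "bmi"] < 19.8)).all()
    both = aug["malnourished"].notna() & aug["hypermetabolic"].notna()
    assert both.sum() == (aug["bmi"].notna() & aug["mree_per_lstm"].notna()).sum()


def test_thresholds_validation():
    with pytest.raises(ValueError):
        Thresholds(hypermetabolism_cut=-1.0)
    t = Thresholds()
    assert t.bmm_bmi_reference == pytest.approx(
        t.malnutrition_pct_ibw * t.ibw_bmi_constant)
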
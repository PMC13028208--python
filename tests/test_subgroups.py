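"""GLIM classification, statistical battery, error attribution, review."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from l3muscle import (
    ErrorProfile,
    Region,
    SegmentationPair,
    attribute_errors,
    classify_glim,
    correlation_strength,
    error_class_prevalence_test,
    generate_cohort,
    lowest_quartile_review,
    run_subgroup_battery,
    simulate_model_mask,
)
from l3muscle.subgroups import BATTERY_FACTORS, MUSCLE_GROUP_NAMES, ReviewTable

from conftest import fisher_two_sided_oracle


class TestClassifyGlim:
    @pytest.mark.parametrize(
        "bmi,age,expected",
        [
            (19, 60, True),  # BMI below 20, under 70
            (21, 75, True),  # BMI below 22, over 70
            (21, 60, False),  # 21 is not below 20 for the younger rule
            (19.99, 69, True),
            (20.0, 60, False),  # boundary: "below 20" is strict
            (22.0, 80, False),  # boundary: "below 22" is strict
            (21.5, 70, True),  # age 70 assigned the elder cut-off
            (25, 50, False),
        ],
    )
    def test_rule_cases(self, bmi, age, expected):
        assert classify_glim(bmi, age).underweight is expected

    def test_invalid_bmi_rejected(self):
        with pytest.raises(ValueError):
            classify_glim(0.0, 50)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(10, 60), st.integers(18, 100))
    def test_rule_totality(self, bmi, age):
        status = classify_glim(bmi, age)
        assert status.underweight in (True, False)


def make_results(n=40, seed=0, dsc=None, sse=None):
    subs = generate_cohort(n, seed=seed)
    rng = np.random.default_rng(seed + 1)
    df = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subs],
            "age": [s.age for s in subs],
            "sex": [s.sex for s in subs],
            "bmi": [s.bmi for s in subs],
            "cancer_type": [s.cancer_type for s in subs],
            "cancer_grade": [s.cancer_grade for s in subs],
            "cci": [s.cci for s in subs],
            "arm_position": [s.arm_position for s in subs],
            "iv_contrast": [s.iv_contrast for s in subs],
        }
    )
    df["dsc"] = dsc if dsc is not None else rng.uniform(0.9, 1.0, n)
    df["sse"] = sse if sse is not None else rng.uniform(1, 10, n)
    return df


class TestBattery:
    def test_covers_all_nine_factors_for_both_metrics(self):
        report = run_subgroup_battery(make_results(80, seed=3))
        for metric in ("dsc", "sse"):
            sub = report[report["metric"] == metric]
            assert set(BATTERY_FACTORS).issubset(set(sub["factor"]))
        # pairwise follow-up: all 6 cancer-type pairs per metric
        pairwise = report[report["factor"].str.startswith("cancer_type:")]
        assert len(pairwise) == 12

    def test_perfect_monotone_correlation_is_strong(self):
        df = make_results(30, seed=4)
        df["dsc"] = df["bmi"].rank() / 30.0  # strictly increasing in bmi
        report = run_subgroup_battery(df, metrics=("dsc",))
        row = report[(report["factor"] == "bmi") & (report["metric"] == "dsc")].iloc[0]
        assert row["statistic"] == pytest.approx(1.0)
        assert row["strength"] == "strong" and row["significant"]

    def test_constant_metric_yields_no_significance(self):
        df = make_results(60, seed=5, dsc=np.full(60, 0.97), sse=np.full(60, 3.0))
        report = run_subgroup_battery(df)
        mw = report[report["test"] == "mann_whitney"]
        assert not mw["significant"].any()

    def test_small_levels_flagged_insufficient(self):
        df = make_results(12, seed=6)
        df["cancer_type"] = ["melanoma"] * 11 + ["hnc"]  # hnc level has n=1
        report = run_subgroup_battery(df, metrics=("dsc",))
        row = report[(report["factor"] == "cancer_type")].iloc[0]
        assert row["note"] == "insufficient"

    def test_duplicate_subjects_rejected(self):
        df = make_results(10, seed=7)
        df.loc[1, "subject_id"] = df.loc[0, "subject_id"]
        with pytest.raises(ValueError, match="duplicated"):
            run_subgroup_battery(df)

    def test_spearman_sign_flip(self):
        df = make_results(30, seed=8)
        df["dsc"] = df["bmi"]
        r1 = run_subgroup_battery(df, metrics=("dsc",))
        df["dsc"] = -df["bmi"]
        r2 = run_subgroup_battery(df, metrics=("dsc",))
        a = r1[(r1["factor"] == "bmi")].iloc[0]["statistic"]
        b = r2[(r2["factor"] == "bmi")].iloc[0]["statistic"]
        assert a == pytest.approx(1.0) and b == pytest.approx(-1.0)

    def test_strength_bands(self):
        assert correlation_strength(0.39) == "weak"
        assert correlation_strength(0.40) == "moderate"
        assert correlation_strength(0.69) == "moderate"
        assert correlation_strength(-0.70) == "strong"


class TestAttributeErrors:
    def test_perfect_prediction_all_zero(self, default_cohort):
        ph, _ = default_cohort[0]
        p = SegmentationPair(ph.reference_mask, ph.reference_mask, ph.slice.pixel_area_cm2)
        bd = attribute_errors(p, ph.region_labels)
        assert bd.total_error_pixels == 0
        assert not bd.nonmuscle_anatomy and not bd.ill_defined_boundary
        assert all(v == 0 for v in bd.group_fractions.values())

    def test_fp_blob_on_organ_sets_nonmuscle_flag(self, default_cohort):
        ph, _ = default_cohort[0]
        pred = ph.reference_mask.copy()
        organ = np.argwhere(ph.region_labels == Region.OTHER_ORGAN)
        y, x = organ[len(organ) // 2]
        pred[y, x] = True
        bd = attribute_errors(SegmentationPair(ph.reference_mask, pred, 0.0225), ph.region_labels)
        assert bd.nonmuscle_anatomy

    def test_fringe_only_error_flags_boundary_and_wall(self, default_cohort):
        from scipy import ndimage

        ph, _ = default_cohort[0]
        wall = ph.region_labels == Region.ABDOMINAL_WALL
        rim = ndimage.binary_dilation(wall, iterations=2) & ~ph.reference_mask
        rim &= ph.region_labels == Region.ADIPOSE
        pred = ph.reference_mask | rim
        bd = attribute_errors(SegmentationPair(ph.reference_mask, pred, 0.0225), ph.region_labels)
        assert bd.ill_defined_boundary
        fr = bd.group_fractions
        assert fr["abdominal_wall"] == max(fr.values()) > 0

    def test_remote_fp_is_unattributed(self, default_cohort):
        ph, _ = default_cohort[0]
        pred = ph.reference_mask.copy()
        pred[0:3, 0:3] = True  # corner, far from any muscle
        bd = attribute_errors(SegmentationPair(ph.reference_mask, pred, 0.0225), ph.region_labels)
        assert bd.unattributed_fraction == 1.0


class TestQuartileReview:
    @staticmethod
    def _breakdowns(df):
        from l3muscle.subgroups import ErrorBreakdown

        fr = {v: 0.0 for v in MUSCLE_GROUP_NAMES.values()}
        return {
            sid: ErrorBreakdown(dict(fr), 0.0, False, True, 10) for sid in df["subject_id"]
        }

    def test_uniform_ranks_select_exactly_quarter(self):
        df = make_results(100, seed=9, dsc=np.linspace(0.5, 0.99, 100))
        review = lowest_quartile_review(df, self._breakdowns(df))
        assert len(review.subjects) == 25

    def test_study_size_selects_58(self):
        df = make_results(232, seed=10, dsc=np.linspace(0.8, 0.999, 232))
        review = lowest_quartile_review(df, self._breakdowns(df))
        assert len(review.subjects) == 58

    def test_identical_dsc_selects_none_under_strict_rule(self):
        df = make_results(20, seed=11, dsc=np.full(20, 0.95))
        review = lowest_quartile_review(df, self._breakdowns(df))
        assert len(review.subjects) == 0


class TestFisher:
    def test_equal_prevalence_gives_p_one(self):
        table = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(20)],
                "nonmuscle_anatomy": [True] * 5 + [False] * 5 + [True] * 5 + [False] * 5,
                "ill_defined_boundary": [False] * 20,
            }
        )
        uw = {f"S{i}": i < 10 for i in range(20)}
        r_nm, r_b = error_class_prevalence_test(table, uw)
        assert r_nm.p_value == pytest.approx(1.0)
        assert r_b.degenerate  # boundary flag never fires: zero margin

    def test_extreme_table_matches_hypergeometric_oracle(self):
        # [[10, 0], [0, 10]]
        table = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(20)],
                "nonmuscle_anatomy": [True] * 10 + [False] * 10,
                "ill_defined_boundary": [True] * 10 + [False] * 10,
            }
        )
        uw = {f"S{i}": i < 10 for i in range(20)}
        r_nm, _ = error_class_prevalence_test(table, uw)
        assert r_nm.p_value == pytest.approx(fisher_two_sided_oracle(10, 0, 0, 10), rel=1e-9)
        # closed form: 2 / C(20, 10)
        from math import comb

        assert r_nm.p_value == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_symmetry_under_group_swap(self):
        flags = [True] * 7 + [False] * 5 + [True] * 2 + [False] * 9
        table = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(23)],
                "nonmuscle_anatomy": flags,
                "ill_defined_boundary": flags,
            }
        )
        uw_a = {f"S{i}": i < 12 for i in range(23)}
        uw_b = {f"S{i}": i >= 12 for i in range(23)}  # swapped rows
        ra, _ = error_class_prevalence_test(table, uw_a)
        rb, _ = error_class_prevalence_test(table, uw_b)
        assert ra.p_value == pytest.approx(rb.p_value, rel=1e-12)


def test_simulated_cohort_direction_matches_coupling():
    """Positive BMI coupling: DSC rises with BMI; underweight score worse."""
    from l3muscle import generate_phantom
    from l3muscle.metrics import evaluate_pair
    from l3muscle.postprocess import postprocess

    subs = generate_cohort(120, seed=30)
    rows = []
    for i, s in enumerate(subs):
        ph = generate_phantom(s, seed=5000 + i)
        raw = simulate_model_mask(ph, ErrorProfile(bmi_coupling=1.0), seed=6000 + i)
        pred = postprocess(raw, ph.slice, threshold=-29)
        m = evaluate_pair(SegmentationPair(ph.reference_mask, pred, ph.slice.pixel_area_cm2))
        rows.append(
            dict(subject_id=s.subject_id, age=s.age, sex=s.sex, bmi=s.bmi,
                 cancer_type=s.cancer_type, cancer_grade=s.cancer_grade, cci=s.cci,
                 arm_position=s.arm_position, iv_contrast=s.iv_contrast,
                 dsc=m.dsc, sse=m.sse)
        )
    report = run_subgroup_battery(pd.DataFrame(rows))
    row = report[(report["factor"] == "bmi") & (report["metric"] == "dsc")].iloc[0]
    assert row["statistic"] > 0 and row["significant"]
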
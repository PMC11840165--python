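"""Segmentation, ROI aggregation and the group-statistics battery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from noemri.phantom import (
    LABEL_CODES,
    PhantomSpec,
    SubjectRecord,
    draw_subject,
    draw_tissue_means,
)
from noemri.roi_stats import (
    adjusted_group_regression,
    cohort_stats,
    covariate_regression,
    pairwise_bonferroni,
    percent_change,
    roi_mean,
    segment_from_t1,
    subject_roi_table,
    two_sample_ttest,
)

from conftest import desk_spec


def welch_oracle(a, b):
    """Independent closed-form Welch t-test (statistic, df, two-sided p)."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t_stat = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    p = 2.0 * tdist.sf(abs(t_stat), df)
    return t_stat, p


class TestSegmentation:
    def test_noiseless_phantom_labels_recovered_exactly(self):
        spec = desk_spec(noise_sd=0.0, jitter_sd=0.0, t1_noise_sd=0.0)
        rng = np.random.default_rng(4)
        from noemri.phantom import build_volume

        vol = build_volume(spec, draw_subject(spec, "MS", rng, "m"), rng)
        lesion = vol.labels == LABEL_CODES["lesion"]
        mask = segment_from_t1(vol.t1, brain_mask=vol.labels > 0, lesion_mask=lesion)
        np.testing.assert_array_equal(mask.labels, vol.labels)

    def test_noisy_t1_agreement_above_99_percent(self):
        spec = desk_spec(noise_sd=0.0, jitter_sd=0.0, t1_noise_sd=30.0)
        rng = np.random.default_rng(5)
        from noemri.phantom import build_volume

        vol = build_volume(spec, draw_subject(spec, "MS", rng, "m"), rng)
        lesion = vol.labels == LABEL_CODES["lesion"]
        mask = segment_from_t1(vol.t1, brain_mask=vol.labels > 0, lesion_mask=lesion)
        brain = vol.labels > 0
        agree = (mask.labels[brain] == vol.labels[brain]).mean()
        assert agree >= 0.99

    def test_all_csf_t1_warns_of_empty_classes(self):
        t1 = np.full((4, 4, 2), 4000.0)
        with pytest.warns(UserWarning, match="empty"):
            mask = segment_from_t1(t1)
        assert (mask.labels == LABEL_CODES["CSF"]).all()

    def test_lesion_mask_shape_checked(self):
        with pytest.raises(ValueError, match="lesion mask"):
            segment_from_t1(np.full((4, 4, 2), 1000.0), lesion_mask=np.zeros((2, 2, 2), bool))


class TestRoiMean:
    def test_constant_map(self):
        roi = np.ones((3, 3), bool)
        mean, sd, n = roi_mean(np.full((3, 3), 2.5), roi)
        assert (mean, sd, n) == (2.5, 0.0, 9)

    def test_two_voxel_mean(self):
        vals = np.array([0.1, 0.3, 99.0])
        roi = np.array([True, True, False])
        mean, _, n = roi_mean(vals, roi)
        assert mean == pytest.approx(0.2) and n == 2

    def test_empty_roi_returns_nan(self):
        mean, sd, n = roi_mean(np.ones((2, 2)), np.zeros((2, 2), bool))
        assert np.isnan(mean) and n == 0

    def test_qc_mask_excludes_voxels(self):
        vals = np.array([1.0, 100.0])
        roi = np.ones(2, bool)
        mean, _, n = roi_mean(vals, roi, qc_mask=np.array([True, False]))
        assert mean == 1.0 and n == 1

    def test_phantom_wm_roi_tracks_subject_draw(self, noiseless_vol):
        spec, vol = noiseless_vol
        wm = vol.labels == LABEL_CODES["WM"]
        mean, sd, n = roi_mean(vol.true_amplitudes["rNOE"], wm)
        # noiseless + zero jitter: ROI mean is exactly the subject tissue draw
        assert mean == pytest.approx(vol.tissue_means["WM"]["rNOE"], abs=1e-12)


class TestTwoSampleT:
    def test_identical_groups_degenerate(self):
        res = two_sample_ttest([1.0, 1.0, 1.0], [1.0, 1.0])
        assert res.t_value == 0.0 and res.p_value == 1.0

    def test_large_shift_is_significant(self):
        # closed-form Welch on {1,2,3} vs {11,12,13}: t = -12.247, df = 4
        res = two_sample_ttest([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        t_exp, p_exp = welch_oracle([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert res.p_value == pytest.approx(p_exp, abs=1e-12)
        assert res.p_value < 1e-3

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = rng.normal(0.1, 0.02, rng.integers(3, 12))
            b = rng.normal(0.12, 0.03, rng.integers(3, 12))
            res = two_sample_ttest(a, b)
            t_exp, p_exp = welch_oracle(a, b)
            assert res.t_value == pytest.approx(t_exp, abs=1e-10)
            assert res.p_value == pytest.approx(p_exp, abs=1e-10)

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=8), rng.normal(size=6)
        ab = two_sample_ttest(a, b)
        ba = two_sample_ttest(b, a)
        assert ab.t_value == pytest.approx(-ba.t_value, abs=1e-12)
        assert ab.p_value == pytest.approx(ba.p_value, abs=1e-12)

    def test_minimum_group_size_enforced(self):
        with pytest.raises(ValueError):
            two_sample_ttest([1.0], [1.0, 2.0])

    def test_power_against_simulation_oracle(self):
        """15-vs-10 draws from the NAWM / control-WM rNOE priors: the
        package's rejection decisions agree with an independent Welch
        implementation on the same simulated datasets (rates within 2%)."""
        rng = np.random.default_rng(11)
        reps = 2000
        rejections_pkg = 0
        rejections_oracle = 0
        for _ in range(reps):
            ctrl = rng.normal(0.114, 0.014, 10)
            nawm = rng.normal(0.101, 0.007, 15)
            rejections_pkg += two_sample_ttest(ctrl, nawm).p_value < 0.05
            rejections_oracle += welch_oracle(ctrl, nawm)[1] < 0.05
        rate_pkg = rejections_pkg / reps
        rate_oracle = rejections_oracle / reps
        assert abs(rate_pkg - rate_oracle) < 0.02
        assert 0.2 < rate_pkg < 1.0  # the printed effect size is detectable


class TestAdjustedRegression:
    def test_outcome_independent_of_predictors(self):
        group = ["MS"] * 4 + ["control"] * 4
        age = [30, 40, 50, 60, 35, 45, 55, 65]
        sex = ["F", "M"] * 4
        res = adjusted_group_regression([1.0, 1.0, 1.0, 1.0] * 2, group, age, sex)
        assert res.estimate == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_construction_recovered(self):
        rng = np.random.default_rng(3)
        n = 30
        group = ["MS" if i < 15 else "control" for i in range(n)]
        age = rng.uniform(20, 70, n)
        sex = ["F" if rng.random() < 0.5 else "M" for _ in range(n)]
        g = np.array([1.0 if x == "MS" else 0.0 for x in group])
        y = 2.0 * g + 0.01 * age
        res = adjusted_group_regression(y, group, age, sex)
        assert res.estimate == pytest.approx(2.0, abs=1e-10)

    def test_noisy_group_effect_within_3_se(self):
        rng = np.random.default_rng(21)
        n = 400
        group = ["MS"] * 200 + ["control"] * 200
        age = rng.uniform(20, 70, n)
        sex = ["F" if v < 0.5 else "M" for v in rng.random(n)]
        g = np.array([1.0 if x == "MS" else 0.0 for x in group])
        y = 2.0 * g + rng.normal(0, 1.0, n)
        res = adjusted_group_regression(y, group, age, sex)
        se = abs(res.estimate / res.t_value)
        assert abs(res.estimate - 2.0) < 3 * se

    def test_collinear_design_named(self):
        group = ["MS"] * 3 + ["control"] * 3
        age = [50.0] * 6  # constant → collinear with the intercept
        sex = ["F", "M"] * 3
        with pytest.raises(ValueError, match="collinear"):
            adjusted_group_regression([1, 2, 3, 4, 5, 6], group, age, sex)


class TestBonferroni:
    def test_three_way_adjustment_arithmetic(self):
        rng = np.random.default_rng(2)
        groups = {
            "control WM": rng.normal(0.114, 0.014, 10),
            "NAWM": rng.normal(0.101, 0.007, 15),
            "lesion": rng.normal(0.076, 0.019, 15),
        }
        results = pairwise_bonferroni(groups)
        assert len(results) == 3
        for r in results:
            assert r.adjusted_p == pytest.approx(min(1.0, 3 * r.p_value), abs=1e-12)
            assert r.adjusted_p >= r.p_value

    def test_identical_groups_all_adjusted_to_one(self):
        g = {k: np.array([1.0, 1.0, 1.0]) for k in ("a", "b", "c")}
        for r in pairwise_bonferroni(g):
            assert r.adjusted_p == 1.0

    @settings(max_examples=50, derandomize=True)
    @given(p=st.floats(1e-12, 1.0))
    def test_adjustment_dominates_and_caps(self, p):
        assert min(1.0, 3 * p) >= p
        assert min(1.0, 3 * p) <= 1.0


class TestCovariateRegression:
    def test_constant_outcome_zero_slope(self):
        res = covariate_regression([2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0])
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_exact_line_recovers_printed_lesion_t1_slope(self):
        """y = 24.34·x + c is recovered with R² = 1 (noiseless identity)."""
        x = np.array([0.5, 2.0, 4.0, 7.5, 11.0, 16.0])
        y = 24.34 * x + 1400.0
        res = covariate_regression(y, x, covariate_name="disease_duration")
        assert res.slope == pytest.approx(24.34, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_covariate_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            covariate_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_duration_coupling_slope_recovered_from_subject_draws(self):
        """150 MS subjects with lesion-T1/duration coupling enabled: the
        regression recovers the generative 24.34 ms/y slope within 3 SE."""
        spec = desk_spec(duration_coupling=True)
        rng = np.random.default_rng(33)
        durations, t1s = [], []
        for _ in range(150):
            s = draw_subject(spec, "MS", rng)
            m = draw_tissue_means(spec, s, rng)
            durations.append(s.disease_duration)
            t1s.append(m["lesion"]["T1"])
        res = covariate_regression(t1s, durations, covariate_name="disease_duration")
        se = abs(res.slope / res.t_value)
        assert abs(res.slope - spec.lesion_t1_slope) < 3 * se


class TestPercentChange:
    @pytest.mark.parametrize(
        "ref, cmp_, expected, tol",
        [
            (0.114, 0.101, -11.4, 0.15),  # control WM → NAWM rNOE
            (0.099, 0.083, -16.1, 0.15),  # whole-brain rNOE
            (1.0, 1.0, 0.0, 1e-12),
        ],
    )
    def test_reported_decreases(self, ref, cmp_, expected, tol):
        assert percent_change(ref, cmp_) == pytest.approx(expected, abs=tol)

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percent_change(0.0, 1.0)


class TestCohortAssembly:
    def _toy_roi_table(self):
        rng = np.random.default_rng(17)
        rows = []
        for gi, (group, n) in enumerate((("control", 6), ("MS", 8))):
            for i in range(n):
                subject = SubjectRecord(
                    f"{group}-{i}", group, 40.0 + rng.uniform(-10, 10),
                    "F" if i % 2 else "M",
                    disease_duration=float(i) if group == "MS" else 0.0,
                    lesion_volume=0.5 * i if group == "MS" else 0.0,
                )
                for tissue in ("whole_brain", "GM", "WM", "lesion"):
                    if tissue == "lesion" and group == "control":
                        mean = np.nan
                    else:
                        mean = rng.normal(0.1 - 0.01 * gi, 0.01)
                    rows.append(
                        dict(
                            subject_id=subject.subject_id, group=group,
                            age=subject.age, sex=subject.sex,
                            disease_duration=subject.disease_duration,
                            lesion_volume=subject.lesion_volume,
                            tissue=tissue, contrast="rNOE", mean=mean,
                            sd=0.01, n_voxels=100,
                        )
                    )
        return pd.DataFrame(rows)

    def test_cohort_stats_produces_expected_families(self):
        table = cohort_stats(self._toy_roi_table())
        kinds = set(table["kind"])
        assert {"two_sample_t", "adjusted_regression", "pairwise_bonferroni",
                "covariate_regression"} <= kinds
        pw = table[table["kind"] == "pairwise_bonferroni"]
        assert set(pw["comparison"]) == {
            "control WM vs NAWM", "control WM vs lesion", "NAWM vs lesion"
        }
        assert ((table["p_value"] >= 0) & (table["p_value"] <= 1)).all()

    def test_subject_roi_table_layout(self, noiseless_vol):
        spec, vol = noiseless_vol
        from noemri.roi_stats import TissueMask

        mask = TissueMask(vol.labels)
        maps = {"rNOE": vol.true_amplitudes["rNOE"], "T1": vol.t1}
        table = subject_roi_table(vol.subject, maps, mask)
        assert set(table["tissue"]) == {"whole_brain", "GM", "WM", "lesion"}
        assert len(table) == 8
        wm_row = table[(table.tissue == "WM") & (table.contrast == "rNOE")].iloc[0]
        assert wm_row["mean"] == pytest.approx(vol.tissue_means["WM"]["rNOE"], abs=1e-12)
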
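"""Validation-statistics tests: ROI extraction, accuracy regression,
repeatability, block construction and the Friedman/Dunn rank tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from mrfpipe.dictionary import ParameterMaps
from mrfpipe.synthetic_data import STRUCTURES, DEFAULT_STRUCTURE_PARAMS, generate_cohort
from mrfpipe.validation_stats import (
    BlockError,
    build_blocks,
    dunn_posthoc,
    extract_roi_stats,
    friedman_test,
    linear_accuracy,
    repeatability,
    table1,
)

from oracles import (
    friedman_exact_permutation_p,
    friedman_statistic_plain,
    ols_closed_form,
)


def _maps_from(t1, t2=None):
    t1 = np.asarray(t1, float)
    t2 = t1 / 10.0 if t2 is None else np.asarray(t2, float)
    return ParameterMaps(t1, t2, np.ones_like(t1), np.ones_like(t1))


class TestRoiExtraction:
    def test_uniform_region(self):
        t1 = np.full((6, 6), 850.0)
        labels = np.ones((6, 6), int)
        out = extract_roi_stats(_maps_from(t1), labels)
        assert out.loc[1, "t1_mean"] == 850.0
        assert out.loc[1, "t1_sd"] == 0.0
        assert out.loc[1, "n_voxels"] == 36

    def test_two_labels_match_hand_computation(self):
        t1 = np.zeros((4, 4))
        labels = np.zeros((4, 4), int)
        t1[0, :2], labels[0, :2] = [100.0, 200.0], 1
        t1[1, :3], labels[1, :3] = [10.0, 20.0, 60.0], 2
        out = extract_roi_stats(_maps_from(t1), labels)
        assert out.loc[1, "t1_mean"] == pytest.approx(150.0)
        assert out.loc[2, "t1_mean"] == pytest.approx(30.0)
        assert out.loc[2, "t1_sd"] == pytest.approx(np.std([10, 20, 60], ddof=1))

    def test_no_labels_raises(self):
        with pytest.raises(ValueError):
            extract_roi_stats(_maps_from(np.ones((3, 3))), np.zeros((3, 3), int))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            extract_roi_stats(_maps_from(np.ones((3, 3))), np.ones((4, 4), int))


class TestLinearAccuracy:
    def test_identity_fit(self):
        ref = np.array([100.0, 400.0, 900.0, 1600.0])
        rep = linear_accuracy(ref, ref)
        assert rep.slope == pytest.approx(1.0)
        assert rep.intercept == pytest.approx(0.0, abs=1e-9)
        assert rep.r_squared == pytest.approx(1.0)
        assert rep.mape_percent == pytest.approx(0.0, abs=1e-12)

    def test_scaling_gives_ten_percent_mape(self):
        ref = np.array([100.0, 200.0, 300.0])
        rep = linear_accuracy(1.1 * ref, ref)
        assert rep.mape_percent == pytest.approx(10.0)

    def test_toy_set_matches_closed_form_ols(self):
        ref = np.array([100.0, 200.0, 300.0, 400.0])
        meas = np.array([110.0, 190.0, 310.0, 390.0])
        rep = linear_accuracy(meas, ref)
        slope, intercept, r2 = ols_closed_form(ref, meas)
        assert rep.slope == pytest.approx(slope)
        assert rep.intercept == pytest.approx(intercept)
        assert rep.r_squared == pytest.approx(r2)

    def test_range_filter_restricts_points(self):
        ref = np.array([10.0, 50.0, 150.0, 500.0])
        meas = ref + 1.0
        rep = linear_accuracy(meas, ref, range_filter=(40.0, 200.0))
        assert rep.n_points == 2
        assert rep.range_filter == (40.0, 200.0)

    def test_insufficient_points_raise(self):
        with pytest.raises(ValueError):
            linear_accuracy([1.0], [1.0])
        with pytest.raises(ValueError):
            linear_accuracy([1.0, 2.0, 3.0], [5.0, 50.0, 500.0], range_filter=(0, 10))


class TestRepeatability:
    def test_identical_repeats_have_zero_sd(self):
        m = np.tile(np.arange(5.0), (4, 1))
        rep = repeatability(m)
        assert np.all(rep.per_vial_sd == 0.0)
        assert rep.min_sd == rep.max_sd == 0.0

    def test_two_point_sd(self):
        rep = repeatability(np.array([[10.0], [14.0]]))
        assert rep.per_vial_sd[0] == pytest.approx(2.0 * np.sqrt(2.0))

    def test_random_matrix_matches_textbook_sd(self):
        rng = np.random.default_rng(2)
        m = rng.normal(100.0, 5.0, size=(7, 14))
        rep = repeatability(m)
        for j in range(14):
            col = m[:, j]
            sd = np.sqrt(np.sum((col - col.mean()) ** 2) / 6.0)
            assert rep.per_vial_sd[j] == pytest.approx(sd)
        assert rep.n_repeats == 7

    def test_single_repeat_rejected(self):
        with pytest.raises(ValueError):
            repeatability(np.ones((1, 5)))


class TestBuildBlocks:
    def test_default_cohort_shape(self):
        c = generate_cohort(seed=0)
        b = build_blocks(c, "t1_ms")
        assert b.shape == (25, 5)

    def test_single_patient_single_tumor(self):
        params = {s: (m1, 0.0, m2, 0.0, 1) for s, (m1, _, m2, _, _) in DEFAULT_STRUCTURE_PARAMS.items()}
        c = generate_cohort(structure_params=params, multi_tumor_plan=(1,), seed=0)
        b = build_blocks(c, "t2_ms")
        assert b.shape == (1, 5)
        assert b[0, 0] == 69.0  # meningioma column first

    def test_multi_tumor_blocks_share_normal_rows(self):
        c = generate_cohort(seed=5)
        b = build_blocks(c, "t1_ms")
        men = c.records[c.records.structure == "meningioma"].reset_index()
        triple = men.patient_id.value_counts().idxmax()
        rows = np.where(men.patient_id == triple)[0]
        assert rows.size == 3
        for r in rows[1:]:
            assert np.array_equal(b[r, 1:], b[rows[0], 1:])

    def test_missing_structure_raises(self):
        c = generate_cohort(seed=0)
        broken = c.records[
            ~((c.records.structure == "thalamus") & (c.records.patient_id == "P01"))
        ]
        from mrfpipe.synthetic_data import CohortTable

        with pytest.raises(BlockError):
            build_blocks(CohortTable(broken, 0, {}), "t1_ms")


class TestFriedman:
    def test_identical_conditions_null(self):
        b = np.tile([3.0, 3.0, 3.0], (5, 1))
        res = friedman_test(b)
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert res.df == 2

    def test_statistic_matches_plain_oracle_and_scipy(self):
        rng = np.random.default_rng(8)
        b = rng.standard_normal((12, 4))
        res = friedman_test(b)
        assert res.statistic == pytest.approx(friedman_statistic_plain(b))
        sp = ss.friedmanchisquare(*[b[:, j] for j in range(4)])
        assert res.statistic == pytest.approx(sp.statistic)
        assert res.p_value == pytest.approx(sp.pvalue)
        assert res.rank_sums.sum() == pytest.approx(12 * (1 + 2 + 3 + 4))

    def test_consistently_ordered_3x3_reaches_q6(self):
        b = np.array([[1.0, 2.0, 3.0], [1.5, 2.5, 3.5], [0.0, 5.0, 9.0]])
        res = friedman_test(b)
        assert res.statistic == pytest.approx(6.0)
        # 6.0 is the enumeration maximum: only identically ordered
        # arrangements reach it (exact permutation p = 6/6^3)
        assert friedman_exact_permutation_p(b) == pytest.approx(1.0 / 36.0)

    def test_two_condition_p_tracks_exact_sign_test(self):
        """For k=2 the permutation null is the sign-test distribution; the
        chi-square tail reproduces its ordering and tracks it within the
        approximation envelope at n=8."""
        n = 8
        chi2_p, exact_p = [], []
        for m in range(n + 1):
            b = np.array([[2.0, 1.0]] * m + [[1.0, 2.0]] * (n - m))
            chi2_p.append(friedman_test(b).p_value)
            d = abs(2 * m - n)
            exact_p.append(
                sum(
                    ss.binom.pmf(j, n, 0.5)
                    for j in range(n + 1)
                    if abs(2 * j - n) >= d
                )
            )
        chi2_p, exact_p = np.array(chi2_p), np.array(exact_p)
        assert np.array_equal(np.argsort(chi2_p), np.argsort(exact_p))
        assert np.max(np.abs(chi2_p - exact_p)) < 0.25
        assert chi2_p[n // 2] == pytest.approx(exact_p[n // 2])  # both 1 under balance

    def test_missing_cells_rejected(self):
        b = np.ones((4, 3))
        b[1, 2] = np.nan
        with pytest.raises(ValueError):
            friedman_test(b)

    def test_tie_correction_reduces_statistic_denominator(self):
        # heavy ties: corrected statistic exceeds the uncorrected one
        b = np.array([[1.0, 1.0, 2.0], [1.0, 2.0, 2.0], [1.0, 1.0, 2.0], [3.0, 1.0, 1.0]])
        res = friedman_test(b)
        assert res.statistic == pytest.approx(friedman_statistic_plain(b))


class TestDunn:
    def test_identical_conditions_all_null(self):
        b = np.tile([2.0, 2.0, 2.0, 2.0], (6, 1))
        res = dunn_posthoc(b)
        assert np.allclose(res.comparisons.z, 0.0)
        assert np.allclose(res.comparisons.p_adjusted, 1.0)

    def test_column_swap_flips_z_sign(self):
        rng = np.random.default_rng(1)
        b = rng.standard_normal((10, 3))
        res = dunn_posthoc(b, condition_names=["a", "b", "c"])
        swapped = dunn_posthoc(b[:, [1, 0, 2]], condition_names=["b", "a", "c"])
        z_ab = res.comparisons.query("condition_a=='a' & condition_b=='b'").z.iloc[0]
        z_ba = swapped.comparisons.query("condition_a=='b' & condition_b=='a'").z.iloc[0]
        assert z_ab == pytest.approx(-z_ba)
        assert res.p_adjusted("a", "b") == pytest.approx(swapped.p_adjusted("b", "a"))

    def test_z_matches_direct_formula_evaluation(self):
        """5-condition toy matrix: z for one pair recomputed from scratch
        (explicit sort-based ranks, printed formula)."""
        rng = np.random.default_rng(6)
        b = rng.standard_normal((9, 5))
        res = dunn_posthoc(b, condition_names=list("ABCDE"))
        # independent mean ranks via argsort (no ties in continuous draws)
        ranks = np.empty_like(b)
        for i in range(9):
            order = np.argsort(b[i])
            ranks[i, order] = np.arange(1, 6)
        se = np.sqrt(5 * 6 / (6.0 * 9))
        z_expected = (ranks[:, 0].mean() - ranks[:, 3].mean()) / se
        row = res.comparisons.query("condition_a=='A' & condition_b=='D'")
        assert row.z.iloc[0] == pytest.approx(z_expected)
        assert row.p_unadjusted.iloc[0] == pytest.approx(2 * ss.norm.sf(abs(z_expected)))

    def test_bonferroni_and_holm_adjustments(self):
        rng = np.random.default_rng(9)
        b = rng.standard_normal((15, 4))
        b[:, 0] += 2.0
        bon = dunn_posthoc(b, adjustment="bonferroni")
        raw = dunn_posthoc(b, adjustment="none")
        assert np.allclose(
            bon.comparisons.p_adjusted,
            np.minimum(1.0, raw.comparisons.p_unadjusted * 6),
        )
        from statsmodels.stats.multitest import multipletests

        holm = dunn_posthoc(b, adjustment="holm")
        _, p_sm, _, _ = multipletests(raw.comparisons.p_unadjusted, method="holm")
        assert np.allclose(holm.comparisons.p_adjusted, p_sm)


class TestTable1Renderer:
    def test_zero_sd_cohort_reproduces_configured_means(self):
        params = {s: (m1, 0.0, m2, 0.0, n) for s, (m1, _, m2, _, n) in DEFAULT_STRUCTURE_PARAMS.items()}
        tab = table1(generate_cohort(structure_params=params, seed=0))
        assert tab.loc["meningioma", "t1_mean_ms"] == 1429.0
        assert tab.loc["meningioma", "t2_mean_ms"] == 69.0
        assert tab.loc["thalamus", "t1_mean_ms"] == 1054.0
        assert np.isnan(tab.loc["meningioma", "t1_p_vs_meningioma"])

    def test_default_cohort_table_layout(self):
        tab = table1(generate_cohort(seed=2))
        assert list(tab.index) == list(STRUCTURES)
        assert tab.loc["meningioma", "n"] == 25
        assert tab.loc["thalamus", "n"] == 20
        assert (tab.drop(index="meningioma")["t1_p_vs_meningioma"] <= 1.0).all()
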
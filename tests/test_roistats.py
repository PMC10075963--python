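"""ROI-level statistics: slopes, FDR, gradients, indices, contrasts."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wordpatch import (
    Predictor,
    define_rois,
    dominance_score,
    fdr_bh,
    frontal_axis_correlation,
    gradient_test,
    make_dominance_fixture,
    paired_gradient_test,
    region_dominance_correlation,
    selectivity_index,
    voxel_overlap,
    word_similarity_slope,
)
from wordpatch.roistats import contrast_battery, contrast_weights, slope_table


class TestPredictor:
    def test_en_fr_weights(self):
        p = Predictor.en_fr()
        assert len(p.labels) == 14
        assert p.array.max() == 1.0
        # the two language variants of each cell share a rank
        w = dict(zip(p.labels, p.weights))
        assert w["LE"] == w["LF"] and w["QE"] == w["QF"] and w["WE"] == w["WF"]
        assert w["L-"] == 0.1 and w["WE"] == 1.0

    def test_five_level(self):
        p = Predictor.five_level(["S", "SG", "RI", "RP", "CP"])
        assert p.weights == (0.2, 0.4, 0.6, 0.8, 1.0)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            Predictor("bad", ("a", "b"), (0.5, 0.7))


class TestWordSimilaritySlope:
    def test_identity_fit(self):
        p = Predictor.en_fr()
        res = word_similarity_slope(np.asarray(p.weights), p)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_betas_zero_slope(self):
        p = Predictor.en_fr()
        res = word_similarity_slope(np.full(14, 0.7), p)
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations(self):
        p = Predictor.en_fr()
        rng = np.random.default_rng(3)
        perturb = rng.normal(0, 0.05, 14)
        betas = 0.3 + 2.0 * p.array + perturb
        res = word_similarity_slope(betas, p)
        # independent closed-form OLS via the normal equations
        X = np.column_stack([np.ones(14), p.array])
        coef = np.linalg.solve(X.T @ X, X.T @ betas)
        assert res.intercept == pytest.approx(coef[0], abs=1e-10)
        assert res.slope == pytest.approx(coef[1], abs=1e-10)

    def test_constant_predictor_rejected(self):
        p = Predictor("flat", ("a", "b", "c"), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="constant"):
            word_similarity_slope([1.0, 2.0, 3.0], p)

    def test_series_input_reordered_by_label(self):
        p = Predictor.en_fr()
        betas = pd.Series(p.array, index=p.labels).sample(frac=1, random_state=0)
        assert word_similarity_slope(betas, p).slope == pytest.approx(1.0)


def brute_force_bh(p, q):
    """Step-up definition applied literally."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, bool)
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k = i
    if k:
        reject[order[:k]] = True
    qvals = np.empty(m)
    prev = 1.0
    for i in range(m, 0, -1):
        prev = min(prev, p[order[i - 1]] * m / i)
        qvals[order[i - 1]] = prev
    return qvals, reject


class TestFdrBH:
    def test_all_rejected_example(self):
        qvals, reject = fdr_bh([0.001, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()

    def test_all_ones_none_rejected(self):
        _, reject = fdr_bh([1.0, 1.0, 1.0], q=0.05)
        assert not reject.any()

    def test_single_p_identity(self):
        qvals, reject = fdr_bh([0.04], q=0.05)
        assert reject[0]
        assert qvals[0] == pytest.approx(0.04)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])

    def test_q_never_below_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        qvals, _ = fdr_bh(p)
        assert (qvals >= p - 1e-12).all()

    @pytest.mark.parametrize("m", [1, 2, 3, 5, 8, 10])
    def test_matches_brute_force(self, m):
        rng = np.random.default_rng(m)
        for _ in range(20):
            p = np.round(rng.uniform(size=m), 3)
            qvals, reject = fdr_bh(p, q=0.05)
            q_ref, rej_ref = brute_force_bh(p, 0.05)
            np.testing.assert_allclose(qvals, q_ref, atol=1e-12)
            np.testing.assert_array_equal(reject, rej_ref)


class TestGradientTest:
    def _table(self, coeff, n_part=5, n_rois=6, noise=0.0, seed=0, hemi="L"):
        rng = np.random.default_rng(seed)
        rows = []
        for p in range(n_part):
            intercept = rng.normal(0, 0.1)
            for _ in range(n_rois):
                y = rng.uniform(-75, -25)
                rows.append(
                    {
                        "participant": f"s{p}",
                        "hemisphere": hemi,
                        "tal_y": y,
                        "slope": intercept + coeff * y + rng.normal(0, noise),
                    }
                )
        return pd.DataFrame(rows)

    def test_noise_free_recovers_exactly(self):
        table = self._table(0.0443)
        res = gradient_test(table, hemisphere="L")
        assert res.df == 4
        for c in res.coefficients:
            assert c == pytest.approx(0.0443, abs=1e-10)

    def test_translation_invariance_in_y(self):
        table = self._table(0.03, noise=0.01)
        shifted = table.assign(tal_y=table["tal_y"] + 100.0)
        r1 = gradient_test(table)
        r2 = gradient_test(shifted)
        np.testing.assert_allclose(
            r1.coefficients.to_numpy(), r2.coefficients.to_numpy(), atol=1e-10
        )

    def test_single_roi_participant_skipped_with_warning(self):
        table = self._table(0.02, n_part=3)
        lone = pd.DataFrame(
            [{"participant": "lone", "hemisphere": "L", "tal_y": -50.0, "slope": 1.0}]
        )
        with pytest.warns(UserWarning, match="lone"):
            res = gradient_test(pd.concat([table, lone]), hemisphere="L")
        assert "lone" not in res.coefficients.index
        assert res.excluded == ("lone",)

    def test_paired_test_respects_rh_minimum(self):
        left = self._table(0.05, n_part=4, seed=1)
        right = self._table(0.02, n_part=4, n_rois=2, seed=2, hemi="R")
        both = pd.concat([left, right])
        # nobody has >= 3 right-hemisphere ROIs
        with pytest.raises(ValueError, match="right-hemisphere"):
            paired_gradient_test(both, min_rois_rh=3)
        res = paired_gradient_test(both, min_rois_rh=2)
        assert res["n"] == 4
        assert res["mean_left"] > res["mean_right"]


class TestFrontalAxis:
    def test_colinear_rois_give_perfect_correlation(self):
        y = np.array([-10.0, -5.0, 0.0, 5.0, 10.0])
        z = np.zeros(5)
        res = frontal_axis_correlation(y, z, 2.0 * y)
        assert abs(res["r"]) == pytest.approx(1.0)

    def test_constant_slopes_error(self):
        with pytest.raises(ValueError, match="undefined"):
            frontal_axis_correlation([0, 1, 2], [0, 1, 2], [1.0, 1.0, 1.0])

    def test_fewer_than_three_rois_error(self):
        with pytest.raises(ValueError):
            frontal_axis_correlation([0, 1], [0, 1], [0.1, 0.2])

    def test_matches_hand_pca(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=5)
        z = rng.normal(size=5)
        slopes = rng.normal(size=5)
        res = frontal_axis_correlation(y, z, slopes)
        # independent PCA via the eigendecomposition of the 2x2 covariance
        coords = np.column_stack([y, z])
        centered = coords - coords.mean(axis=0)
        evals, evecs = np.linalg.eigh(centered.T @ centered)
        axis = evecs[:, np.argmax(evals)]
        scores = centered @ axis
        r_ref = np.corrcoef(scores, slopes)[0, 1]
        assert abs(res["r"]) == pytest.approx(abs(r_ref), abs=1e-10)


class TestSelectivityIndex:
    def test_direct_formula(self):
        betas = {"w1": 0.5, "w2": 0.5, "o1": 0.25, "o2": 0.25}
        idx = selectivity_index(betas, ["w1", "w2"], ["o1", "o2"])
        assert idx == pytest.approx(1 / 3)

    def test_padding_rule_hand_computed(self):
        # corrected hand example: pad by 0.2, means become 0.5 and 0.25
        betas = {"w1": 0.2, "w2": 0.4, "o1": -0.2, "o2": 0.1, "o3": 0.1, "o4": 0.2}
        idx = selectivity_index(betas, ["w1", "w2"], ["o1", "o2", "o3", "o4"])
        assert idx == pytest.approx(1 / 3)
        # variant with a 0.0 in the other set: padded means 0.5 and 0.2
        betas["o4"] = 0.0
        idx = selectivity_index(betas, ["w1", "w2"], ["o1", "o2", "o3", "o4"])
        assert idx == pytest.approx((0.5 - 0.2) / (0.5 + 0.2))

    def test_equal_means_give_zero(self):
        betas = {"w": 0.4, "o": 0.4}
        assert selectivity_index(betas, ["w"], ["o"]) == 0.0

    def test_zero_denominator_warns(self):
        betas = {"w": 0.0, "o": 0.0}
        with pytest.warns(UserWarning):
            assert selectivity_index(betas, ["w"], ["o"]) == 0.0

    def test_overlapping_label_sets_rejected(self):
        with pytest.raises(ValueError):
            selectivity_index({"a": 1.0}, ["a"], ["a"])

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(-10, 10), min_size=1, max_size=5),
        st.lists(st.floats(-10, 10), min_size=1, max_size=5),
    )
    def test_bounded_in_unit_interval(self, words, others):
        betas = {f"w{i}": v for i, v in enumerate(words)}
        betas.update({f"o{i}": v for i, v in enumerate(others)})
        idx = selectivity_index(
            betas, [f"w{i}" for i in range(len(words))],
            [f"o{i}" for i in range(len(others))],
        )
        assert -1.0 - 1e-12 <= idx <= 1.0 + 1e-12

    def test_padding_noop_when_all_nonnegative(self):
        betas = {"w1": 0.5, "w2": 0.1, "o1": 0.2, "o2": 0.0}
        idx = selectivity_index(betas, ["w1", "w2"], ["o1", "o2"])
        assert idx == pytest.approx((0.3 - 0.1) / (0.3 + 0.1))


class TestDominanceScore:
    @pytest.mark.parametrize(
        "a,b,expected", [(120, 80, 0.2), (100, 100, 0.0), (100, 0, 1.0)]
    )
    def test_formula(self, a, b, expected):
        assert dominance_score(a, b) == pytest.approx(expected)

    def test_both_zero_errors(self):
        with pytest.raises(ValueError):
            dominance_score(0, 0)


class TestRegionDominance:
    def test_planted_correlation_recovered_exactly(self):
        fix = make_dominance_fixture(target_r=-0.550, seed=3)
        out = region_dominance_correlation(fix, regions=["fusiform"])
        row = out[out["pair"] == "words_main"].iloc[0]
        assert row["r"] == pytest.approx(-0.550, abs=1e-12)
        assert row["n"] == 21
        assert len(out) == 5  # the five-comparison family

    def test_fdr_within_region(self):
        fix = make_dominance_fixture(target_r=-0.9, seed=4)
        out = region_dominance_correlation(fix, regions=["fusiform"])
        row = out[out["pair"] == "words_main"].iloc[0]
        assert row["significant"]
        assert row["q"] >= row["p"]

    def test_missing_region_errors(self):
        fix = make_dominance_fixture(seed=3)
        with pytest.raises(ValueError, match="absent"):
            region_dominance_correlation(fix, regions=["cerebellum"])

    def test_constant_dominance_flagged(self):
        fix = make_dominance_fixture(seed=3)
        for p in fix.participants:
            p.dominance = 0.0
        with pytest.warns(UserWarning, match="undefined"):
            out = region_dominance_correlation(fix, regions=["fusiform"])
        assert out["r"].isna().all()


class TestDefineRois:
    def _grid(self, shape=(12, 12, 12), background=0.5):
        return np.full(shape, background)

    def test_single_blob_centroid(self):
        grid = self._grid()
        grid[2:4, 3:6, 4:6] = 1e-4  # 2*3*2 = 12 voxels
        rois = define_rois(grid, threshold=0.001, min_cluster=4)
        assert len(rois) == 1
        assert rois[0].size == 12
        np.testing.assert_allclose(rois[0].centroid_mm, (2.5, 4.0, 4.5))

    def test_cluster_size_strictly_greater(self):
        grid = self._grid()
        grid[0, 0, :4] = 1e-4  # exactly 4 voxels
        assert define_rois(grid, min_cluster=4) == []
        grid[0, 0, 4] = 1e-4  # now 5
        assert len(define_rois(grid, min_cluster=4)) == 1

    def test_no_suprathreshold_voxels(self):
        assert define_rois(self._grid()) == []

    def test_affine_maps_centroid_to_mm(self):
        grid = self._grid()
        grid[5, 5, 5:10] = 1e-4
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        affine[:3, 3] = [-10, -20, -30]
        rois = define_rois(grid, affine=affine)
        np.testing.assert_allclose(rois[0].centroid_mm, (0.0, -10.0, -16.0))

    def test_connectivity_6_vs_26(self):
        grid = self._grid()
        grid[2:4, 2:4, 2:4] = 1e-4  # 8-voxel cube
        grid[4:6, 4:6, 4:6] = 1e-4  # diagonal neighbor cube
        assert len(define_rois(grid, connectivity=6)) == 2
        assert len(define_rois(grid, connectivity=26)) == 1

    def test_t_map_thresholding(self):
        grid = np.zeros((8, 8, 8))
        grid[1:3, 1:4, 1] = 5.0
        rois = define_rois(grid, threshold=3.0, stat="t")
        assert len(rois) == 1 and rois[0].size == 6


class TestContrastBattery:
    def test_lexicality_only(self):
        p = Predictor.en_fr()
        betas = {lab: 0.0 for lab in p.labels}
        betas["WE"] = betas["WF"] = 1.0
        out = contrast_battery(betas, "enfr").set_index("contrast")["estimate"]
        assert out["lexicality"] == pytest.approx(2.0)
        for name in ("letter_freq", "bigram_freq", "quadrigram_freq"):
            assert out[name] == pytest.approx(0.0)

    def test_linear_predictor_zeroes_level_differences(self):
        p = Predictor.en_fr()
        betas = dict(zip(p.labels, p.weights))
        out = contrast_battery(betas, "enfr").set_index("contrast")["estimate"]
        for name in (
            "bigram_vs_letter", "quadrigram_vs_bigram", "lexicality_vs_quadrigram"
        ):
            assert out[name] == pytest.approx(0.0, abs=1e-12)
        # language pairs are also flat under the shared-rank predictor
        assert out["letter_lang"] == pytest.approx(0.0, abs=1e-12)

    def test_encn_planted_step(self):
        labels = ("L-", "L+", "B-", "B+", "Q-", "Q+", "WE",
                  "S", "SG", "RI", "RP", "CP", "WL", "WH")
        betas = {lab: 0.2 for lab in labels}
        betas["CP"] = betas["RP"] + 0.4
        out = contrast_battery(betas, "encn").set_index("contrast")["estimate"]
        assert out["characters"] == pytest.approx(0.4)
        assert out["radicals_possible"] == pytest.approx(0.0)

    def test_unknown_design_rejected(self):
        with pytest.raises(ValueError, match="unknown design"):
            contrast_weights("enkr")

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            contrast_battery({"WE": 1.0}, "enfr")


class TestVoxelOverlap:
    def test_subset_full_overlap(self):
        assert voxel_overlap({1, 2, 3}, {1, 2, 3, 4}) == 100.0

    def test_disjoint(self):
        assert voxel_overlap({1, 2}, {3, 4}) == 0.0

    def test_partial(self):
        a = set(range(8))
        b = set(range(6)) | {100, 101}
        assert voxel_overlap(a, b) == pytest.approx(75.0)

    def test_empty_a_errors(self):
        with pytest.raises(ValueError):
            voxel_overlap(set(), {1})

    def test_coordinate_tuples(self):
        a = [(0, 0, 0), (1, 1, 1)]
        b = [(1, 1, 1)]
        assert voxel_overlap(a, b) == 50.0


class TestSlopeTable:
    def test_q_and_mask_consistent(self):
        p = Predictor.en_fr()
        rng = np.random.default_rng(0)
        betas = pd.DataFrame(
            [0.3 + s * p.array + rng.normal(0, 0.02, 14) for s in (0.0, 0.5, 1.0, 2.0)],
            columns=p.labels,
        )
        out = slope_table(betas, p, q=0.05)
        assert set(out.columns) >= {"slope", "p", "q", "significant"}
        assert (out["q"] >= out["p"] - 1e-12).all()
        assert out.loc[3, "significant"]
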
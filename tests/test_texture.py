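import numpy as np
import pytest

from tomotex.errors import DegenerateInputError, ParameterError
from tomotex.texture import (
    ANGLES,
    FEATURE_NAMES,
    QuantizedROI,
    compute_glcm,
    compute_ngtdm,
    compute_rlm,
    condition_feature_table,
    feature_vector,
    glcm_features,
    lattice_rois,
    ngtdm_features,
    quantize,
    rlm_features,
    roi_physical_side_mm,
)
from conftest import make_roi, make_slab
import oracles


class TestQuantize:
    def test_identity_on_full_range_bytes(self, rng):
        img = rng.integers(0, 256, (20, 20)).astype(float)
        img[0, 0], img[0, 1] = 0.0, 255.0  # pin the range
        np.testing.assert_array_equal(quantize(img, 256), img.astype(int))

    def test_linear_ramp_equal_bins(self):
        img = np.linspace(0.0, 1.0, 400, endpoint=False).reshape(20, 20)
        q = quantize(img, 4)
        counts = np.bincount(q.ravel(), minlength=4)
        np.testing.assert_array_equal(counts, [100, 100, 100, 100])

    def test_affine_invariance(self, rng):
        img = rng.normal(0, 1, (30, 30))
        np.testing.assert_array_equal(quantize(img, 64), quantize(3.5 * img + 11.0, 64))

    def test_monotone(self, rng):
        img = rng.normal(0, 1, (15, 15))
        q = quantize(img, 16)
        order = np.argsort(img.ravel())
        assert np.all(np.diff(q.ravel()[order]) >= 0)

    def test_constant_image_all_zero(self):
        np.testing.assert_array_equal(quantize(np.full((8, 8), 3.0), 256), 0)

    def test_mask_drives_range(self):
        img = np.zeros((10, 10))
        img[0, 0] = 1000.0  # outside the mask
        img[5, 5] = 1.0
        mask = np.ones((10, 10), dtype=bool)
        mask[0, 0] = False
        q = quantize(img, 2, mask=mask)
        assert q[5, 5] == 1
        assert q[0, 0] == 1  # clipped into range

    def test_robust_range_ignores_outliers(self, rng):
        img = rng.normal(0, 1, (50, 50))
        spiked = img.copy()
        spiked[0, 0] = 1e6
        q_plain = quantize(img, 32, range_quantiles=(1, 99))
        q_spiked = quantize(spiked, 32, range_quantiles=(1, 99))
        assert (q_plain != q_spiked).mean() < 0.01

    def test_too_few_levels(self):
        with pytest.raises(ParameterError):
            quantize(np.zeros((5, 5)), 1)


class TestLatticeRois:
    def test_physical_side_default(self):
        assert roi_physical_side_mm(35, 0.27) == pytest.approx(9.45)

    def test_full_mask_70x70_four_rois(self):
        slab = make_slab(np.zeros((70, 70)))
        rois = lattice_rois(slab, side=35)
        assert len(rois) == 4
        assert {r.origin for r in rois} == {(0, 0), (0, 35), (35, 0), (35, 35)}

    def test_single_corner_roi(self):
        mask = np.zeros((80, 80), dtype=bool)
        mask[3:38, 5:40] = True  # exactly one 35x35 tile
        slab = make_slab(np.zeros((80, 80)), mask=mask)
        rois = lattice_rois(slab, side=35)
        assert len(rois) == 1
        assert rois[0].origin == (3, 5)

    def test_partial_tiles_discarded(self):
        slab = make_slab(np.zeros((50, 50)))
        rois = lattice_rois(slab, side=35)
        assert len(rois) == 1

    def test_no_tile_warns_and_empty(self):
        slab = make_slab(np.zeros((10, 10)))
        with pytest.warns(UserWarning):
            assert lattice_rois(slab, side=35) == []

    def test_empty_mask_raises(self):
        slab = make_slab(np.zeros((40, 40)), mask=np.zeros((40, 40), dtype=bool))
        with pytest.raises(DegenerateInputError):
            lattice_rois(slab)

    def test_roi_side_mm_attached(self):
        slab = make_slab(np.zeros((40, 40)))
        rois = lattice_rois(slab, side=35)
        assert rois[0].side_mm == pytest.approx(9.45)


class TestGLCM:
    def test_constant_roi_single_cell(self):
        roi = make_roi(np.full((8, 8), 3), levels=8)
        g = compute_glcm(roi, d=1, angle=0)
        assert g.matrix[3, 3] == pytest.approx(1.0)
        assert g.matrix.sum() == pytest.approx(1.0)

    def test_checkerboard_offdiagonal(self):
        board = np.indices((8, 8)).sum(axis=0) % 2
        roi = make_roi(board, levels=2)
        g = compute_glcm(roi, d=1, angle=0)
        assert g.matrix[0, 1] == pytest.approx(0.5)
        assert g.matrix[1, 0] == pytest.approx(0.5)

    @pytest.mark.parametrize("angle", ANGLES)
    def test_matches_bruteforce(self, rng, angle):
        pixels = rng.integers(0, 8, (8, 8))
        roi = make_roi(pixels, levels=8)
        g = compute_glcm(roi, d=1, angle=angle)
        oracle = oracles.glcm_bruteforce(pixels, 8, 1, angle)
        np.testing.assert_allclose(g.matrix, oracle, atol=1e-15)

    def test_symmetry_and_normalization(self, rng):
        pixels = rng.integers(0, 16, (12, 12))
        for angle in ANGLES:
            g = compute_glcm(make_roi(pixels, 16), d=2, angle=angle)
            np.testing.assert_allclose(g.matrix, g.matrix.T, atol=1e-15)
            assert g.matrix.sum() == pytest.approx(1.0, abs=1e-9)

    def test_d_too_large(self):
        with pytest.raises(ParameterError):
            compute_glcm(make_roi(np.zeros((4, 4), dtype=int), 4), d=4, angle=0)


class TestGLCMFeatures:
    def test_constant_roi(self):
        g = compute_glcm(make_roi(np.full((6, 6), 2), 4), d=1, angle=0)
        feats = glcm_features(g)
        assert feats["glcm_energy"] == pytest.approx(1.0)
        assert feats["glcm_entropy"] == pytest.approx(0.0)
        assert feats["glcm_homogeneity"] == pytest.approx(1.0)
        assert np.isnan(feats["glcm_correlation"])

    def test_checkerboard_features(self):
        board = np.indices((8, 8)).sum(axis=0) % 2
        g = compute_glcm(make_roi(board, 2), d=1, angle=0)
        feats = glcm_features(g)
        assert feats["glcm_energy"] == pytest.approx(0.5)
        assert feats["glcm_entropy"] == pytest.approx(1.0)
        assert feats["glcm_homogeneity"] == pytest.approx(0.5)

    def test_matches_bruteforce_formulas(self, rng):
        pixels = rng.integers(0, 6, (10, 10))
        g = compute_glcm(make_roi(pixels, 6), d=1, angle=45)
        mine = glcm_features(g)
        ref = oracles.glcm_features_bruteforce(g.matrix)
        for name, val in ref.items():
            assert mine[name] == pytest.approx(val, rel=1e-12), name

    def test_direction_average_excludes_undefined_correlation(self):
        # vertical stripes: 90-degree GLCM is diagonal with zero variance in
        # one direction only when the ROI is single-valued; use a mix
        pixels = np.tile([0, 1], (6, 3))
        glcms = [compute_glcm(make_roi(pixels, 2), 1, a) for a in ANGLES]
        feats = glcm_features(glcms)
        assert np.isfinite(feats["glcm_homogeneity"])


class TestNGTDM:
    def test_constant_roi_zero_d(self):
        res = compute_ngtdm(make_roi(np.full((7, 7), 4), 8), n=1)
        np.testing.assert_allclose(res.D, 0.0)
        assert res.p.sum() == pytest.approx(1.0)

    def test_single_bright_pixel_hand_case(self):
        pixels = np.zeros((5, 5), dtype=int)
        L = 6
        pixels[2, 2] = L
        res = compute_ngtdm(make_roi(pixels, 8), n=1)
        # center pixel of level L deviates from its 8 zero neighbors by L
        assert res.D[L] == pytest.approx(L)
        # each of the 8 surrounding centers sees the bright pixel once: L/8 each
        assert res.D[0] == pytest.approx(8 * (L / 8.0))
        assert res.n_centers == 9

    def test_matches_bruteforce(self, rng):
        pixels = rng.integers(0, 8, (9, 9))
        res = compute_ngtdm(make_roi(pixels, 8), n=1)
        d_ref, p_ref, n_ref = oracles.ngtdm_bruteforce(pixels, 8, 1)
        np.testing.assert_allclose(res.D, d_ref, atol=1e-12)
        np.testing.assert_allclose(res.p, p_ref, atol=1e-15)
        assert res.n_centers == n_ref

    def test_n2_neighborhood(self, rng):
        pixels = rng.integers(0, 4, (9, 9))
        res = compute_ngtdm(make_roi(pixels, 4), n=2)
        d_ref, p_ref, n_ref = oracles.ngtdm_bruteforce(pixels, 4, 2)
        np.testing.assert_allclose(res.D, d_ref, atol=1e-12)
        assert res.n_centers == n_ref == 25

    def test_roi_too_small(self):
        with pytest.raises(ParameterError):
            compute_ngtdm(make_roi(np.zeros((3, 3), dtype=int), 2), n=2)


class TestNGTDMFeatures:
    def test_constant_roi(self):
        res = compute_ngtdm(make_roi(np.full((7, 7), 2), 4), n=1)
        feats = ngtdm_features(res)
        assert feats["ngtdm_contrast"] == 0.0
        assert feats["ngtdm_complexity"] == 0.0
        assert feats["ngtdm_coarseness"] == pytest.approx(1e12)

    def test_half_half_split(self):
        pixels = np.zeros((6, 6), dtype=int)
        pixels[:, 3:] = 3
        res = compute_ngtdm(make_roi(pixels, 4), n=1)
        mine = ngtdm_features(res)
        d_ref, p_ref, n_ref = oracles.ngtdm_bruteforce(pixels, 4, 1)
        ref = oracles.ngtdm_features_bruteforce(d_ref, p_ref, n_ref)
        for name, val in ref.items():
            assert mine[name] == pytest.approx(val, rel=1e-12), name

    def test_matches_bruteforce(self, rng):
        pixels = rng.integers(0, 8, (10, 10))
        res = compute_ngtdm(make_roi(pixels, 8), n=1)
        mine = ngtdm_features(res)
        ref = oracles.ngtdm_features_bruteforce(*oracles.ngtdm_bruteforce(pixels, 8, 1))
        for name, val in ref.items():
            assert mine[name] == pytest.approx(val, rel=1e-12), name


class TestRLM:
    def test_constant_roi_one_run_per_row(self):
        roi = make_roi(np.full((35, 35), 5), 8)
        rlm = compute_rlm(roi, angle=0)
        assert rlm.matrix[5, 34] == 35
        assert rlm.matrix.sum() == 35
        assert rlm.n_runs == 35

    def test_alternating_row(self):
        pixels = np.tile([0, 1, 0, 1, 0, 1], (2, 1))
        rlm = compute_rlm(make_roi(pixels, 2), angle=0)
        assert rlm.matrix[:, 0].sum() == 12  # twelve runs of length 1
        assert rlm.matrix[:, 1:].sum() == 0

    @pytest.mark.parametrize("angle", ANGLES)
    def test_matches_bruteforce(self, rng, angle):
        pixels = rng.integers(0, 6, (9, 12))
        rlm = compute_rlm(make_roi(pixels, 6), angle=angle)
        ref = oracles.rlm_bruteforce(pixels, 6, angle)
        # pad to common width before comparing
        w = max(rlm.matrix.shape[1], ref.shape[1])
        mine = np.zeros((6, w), dtype=int)
        mine[:, : rlm.matrix.shape[1]] = rlm.matrix
        other = np.zeros((6, w), dtype=int)
        other[:, : ref.shape[1]] = ref
        np.testing.assert_array_equal(mine, other)

    @pytest.mark.parametrize("angle", ANGLES)
    def test_pixel_conservation(self, rng, angle):
        pixels = rng.integers(0, 4, (11, 11))
        rlm = compute_rlm(make_roi(pixels, 4), angle=angle)
        j = np.arange(1, rlm.matrix.shape[1] + 1)
        assert (rlm.matrix * j[None, :]).sum() == pixels.size


class TestRLMFeatures:
    def test_constant_35x35_closed_form(self):
        roi = make_roi(np.full((35, 35), 1), 4)
        feats = oracles.rlm_features_bruteforce(compute_rlm(roi, 0).matrix, 35 * 35)
        mine = rlm_features([compute_rlm(roi, 0)])
        assert mine["rlm_sre"] == pytest.approx(1.0 / 35**2)
        assert mine["rlm_lre"] == pytest.approx(35.0**2)
        assert mine["rlm_gln"] == pytest.approx(35.0)
        assert mine["rlm_rln"] == pytest.approx(35.0)
        assert mine["rlm_rp"] == pytest.approx(35.0 / 1225.0)
        for name, val in feats.items():
            assert mine[name] == pytest.approx(val, rel=1e-12)

    def test_maximally_busy_roi(self):
        board = np.indices((8, 8)).sum(axis=0) % 2
        feats = rlm_features([compute_rlm(make_roi(board, 2), 0)])
        assert feats["rlm_sre"] == pytest.approx(1.0)
        assert feats["rlm_rp"] == pytest.approx(1.0)

    def test_matches_bruteforce(self, rng):
        pixels = rng.integers(0, 8, (10, 10))
        roi = make_roi(pixels, 8)
        rlms = [compute_rlm(roi, a) for a in ANGLES]
        mine = rlm_features(rlms)
        per_dir = [
            oracles.rlm_features_bruteforce(oracles.rlm_bruteforce(pixels, 8, a), pixels.size)
            for a in ANGLES
        ]
        for name in mine:
            ref = np.mean([d[name] for d in per_dir])
            assert mine[name] == pytest.approx(ref, rel=1e-12), name

    def test_empty_roi_raises(self):
        from tomotex.texture import RLM

        with pytest.raises(DegenerateInputError):
            rlm_features([RLM(matrix=np.zeros((4, 4), dtype=int), angle=0, n_pixels=16)])


class TestFeatureVector:
    def test_thirteen_named_features(self, rng):
        roi = make_roi(rng.integers(0, 8, (12, 12)), 8)
        fv = feature_vector(roi)
        assert tuple(fv.keys()) == FEATURE_NAMES
        assert len(fv) == 13

    def test_invariant_ranges(self, rng):
        for _ in range(20):
            roi = make_roi(rng.integers(0, 8, (10, 10)), 8)
            fv = feature_vector(roi)
            assert 0 < fv["glcm_energy"] <= 1
            assert fv["glcm_entropy"] >= 0
            assert 0 < fv["glcm_homogeneity"] <= 1
            assert 0 < fv["rlm_sre"] <= 1
            assert 0 < fv["rlm_rp"] <= 1
            assert fv["rlm_lre"] >= 1

    def test_oracle_equivalence_small_batch(self, rng):
        # 20 ROIs here; the full 200-ROI sweep lives in the acceptance suite
        for _ in range(20):
            pixels = rng.integers(0, 8, (12, 12))
            roi = make_roi(pixels, 8)
            fv = feature_vector(roi)
            ref = {}
            glcms = [oracles.glcm_bruteforce(pixels, 8, 1, a) for a in ANGLES]
            per_dir = [oracles.glcm_features_bruteforce(g) for g in glcms]
            for name in per_dir[0]:
                vals = [d[name] for d in per_dir if np.isfinite(d[name])]
                ref[name] = np.mean(vals) if vals else float("nan")
            ref.update(oracles.ngtdm_features_bruteforce(*oracles.ngtdm_bruteforce(pixels, 8, 1)))
            rl = [
                oracles.rlm_features_bruteforce(oracles.rlm_bruteforce(pixels, 8, a), pixels.size)
                for a in ANGLES
            ]
            for name in rl[0]:
                ref[name] = np.mean([d[name] for d in rl])
            for name in FEATURE_NAMES:
                if np.isnan(ref[name]):
                    assert np.isnan(fv[name]), name
                else:
                    assert fv[name] == pytest.approx(ref[name], rel=1e-12), name


class TestNoiseResponseDirections:
    # Busyness and GLN are excluded here: their decrease in the full pipeline
    # comes from the band-limited, heavy-tailed reconstruction noise, not from
    # additive white noise (under which both can rise); the pipeline-level
    # trend test covers them.
    INCREASING = ("glcm_entropy", "ngtdm_contrast", "ngtdm_complexity", "rlm_sre", "rlm_rp", "rlm_rln")
    DECREASING = ("glcm_homogeneity", "glcm_energy", "rlm_lre")

    def test_additive_noise_direction(self):
        # smoothed random-field background + increasing white noise; 20-seed
        # means, three noise levels, tiled 16-px ROIs
        from scipy import ndimage

        noise_levels = (0.15, 0.5, 1.5)
        base = ndimage.gaussian_filter(np.random.default_rng(99).normal(0, 1, (48, 48)), 2.0)
        base /= base.std()
        means = {name: [] for name in FEATURE_NAMES}
        for sigma in noise_levels:
            vals = {name: [] for name in FEATURE_NAMES}
            for seed in range(20):
                rng = np.random.default_rng(seed)
                img = base + rng.normal(0, sigma, base.shape)
                q = quantize(img, 16)
                for r in range(0, 48, 16):
                    for c in range(0, 48, 16):
                        fv = feature_vector(QuantizedROI(q[r : r + 16, c : c + 16], levels=16))
                        for name in FEATURE_NAMES:
                            vals[name].append(fv[name])
            for name in FEATURE_NAMES:
                means[name].append(np.nanmean(vals[name]))
        for name in self.INCREASING:
            assert means[name][0] < means[name][1] < means[name][2], name
        for name in self.DECREASING:
            assert means[name][0] > means[name][1] > means[name][2], name


class TestConditionTable:
    def test_single_constant_slab(self):
        slab = make_slab(np.zeros((40, 40)), condition={"P": 3, "arm": "noisy"})
        table = condition_feature_table({"c1": [slab]}, side=35, levels=8)
        row = table.iloc[0]
        assert row["n_roi"] == 1
        assert row["glcm_energy_mean"] == pytest.approx(1.0)
        assert row["glcm_energy_sd"] == 0.0

    def test_identical_conditions_identical_rows(self, rng):
        img = rng.normal(0, 1, (40, 40))
        t = condition_feature_table(
            {"a": [make_slab(img)], "b": [make_slab(img.copy())]}, side=35, levels=16
        )
        a = t[t.condition == "a"].iloc[0]
        b = t[t.condition == "b"].iloc[0]
        for name in FEATURE_NAMES:
            assert a[f"{name}_mean"] == pytest.approx(b[f"{name}_mean"], rel=1e-12)

    def test_mean_sd_match_flat_recomputation(self, rng):
        slabs = [make_slab(rng.normal(0, 1, (36, 72))) for _ in range(3)]
        from tomotex.texture import roi_feature_frame

        table = condition_feature_table({"c": slabs}, side=35, levels=16)
        df = roi_feature_frame(slabs, side=35, levels=16)
        row = table.iloc[0]
        assert row["n_roi"] == len(df)
        for name in FEATURE_NAMES:
            assert row[f"{name}_mean"] == pytest.approx(df[name].mean(), rel=1e-12)
            assert row[f"{name}_sd"] == pytest.approx(df[name].std(ddof=1), rel=1e-12)

    def test_empty_condition_reported_missing(self):
        slab = make_slab(np.zeros((10, 10)))  # too small for any 35-px tile
        table = condition_feature_table({"tiny": [slab]}, side=35, levels=8)
        row = table.iloc[0]
        assert row["n_roi"] == 0
        assert np.isnan(row["glcm_energy_mean"])

    def test_lesion_roi_exclusion(self):
        slab = make_slab(
            np.zeros((70, 70)),
            truth_present=True,
            truth_center=(17.0, 17.0),
        )
        from tomotex.texture import roi_feature_frame

        with_lesion = roi_feature_frame([slab], side=35, levels=8)
        without = roi_feature_frame([slab], side=35, levels=8, exclude_lesion_rois=True)
        assert len(with_lesion) == 4
        assert len(without) == 3
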
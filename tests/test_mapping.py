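"""Home-range cropping, probability rasters, 3-class maps, landscape metrics."""

import numpy as np
import pandas as pd
import pytest

from canopyn.habitat import HabitatForestClassifier
from canopyn.indices import compute_feature_stack
from canopyn.mapping import (FAVORABLE, NON_HABITAT, UNFAVORABLE,
                             bitterlich_expansion, classify_map, clumpiness,
                             crop_home_range, mask_non_canopy,
                             predict_probability_raster, summarize_habitat)
from canopyn.raster import REFLECTANCE_BANDS, BandStack, CanopyHeightModel


def wide_stack(n=1600, pixel=0.25, seed=0) -> BandStack:
    rng = np.random.default_rng(seed)
    return BandStack({b: rng.uniform(0.05, 0.6, (n, n))
                      for b in REFLECTANCE_BANDS}, pixel)


class TestCropHomeRange:
    def test_200m_at_quarter_meter_pixels_is_800_square(self):
        stack = wide_stack()
        chm = CanopyHeightModel(np.zeros((1600, 1600)), 0.25)
        crop, chm_crop = crop_home_range(stack, chm, (200.0, 200.0), 200.0)
        assert crop.shape == (800, 800)
        assert chm_crop.shape == (800, 800)

    def test_center_on_corner_rejected(self):
        stack = wide_stack()
        chm = CanopyHeightModel(np.zeros((1600, 1600)), 0.25)
        with pytest.raises(ValueError, match="exceeds"):
            crop_home_range(stack, chm, (0.0, 0.0), 200.0)

    def test_index_computation_commutes_with_cropping(self):
        stack = wide_stack(n=64, pixel=1.0, seed=1)
        chm = CanopyHeightModel(np.zeros((64, 64)), 1.0)
        crop_then_index = compute_feature_stack(
            crop_home_range(stack, chm, (32.0, 32.0), 20.0)[0])
        index_then_crop = crop_home_range(
            compute_feature_stack(stack), chm, (32.0, 32.0), 20.0)[0]
        for name in crop_then_index.band_names:
            np.testing.assert_allclose(crop_then_index[name],
                                       index_then_crop[name], equal_nan=True)

    def test_coarser_chm_resampled_to_feature_grid(self):
        stack = wide_stack(n=100, pixel=0.5)
        chm = CanopyHeightModel(np.arange(625, dtype=float).reshape(25, 25),
                                2.0)
        _, chm_crop = crop_home_range(stack, chm, (25.0, 25.0), 20.0)
        assert chm_crop.pixel_size_m == 0.5
        assert chm_crop.shape == (40, 40)


def trained_toy_classifier(seed=0):
    rng = np.random.default_rng(seed)
    n = 400
    y = rng.integers(0, 2, n)
    X = pd.DataFrame({"nir": 0.3 + 0.2 * y + rng.uniform(0, 0.05, n),
                      "gdvi": 0.1 + 0.2 * y + rng.uniform(0, 0.05, n)})
    return HabitatForestClassifier(n_estimators=50, random_state=0).fit(X, y)


class TestPredictProbabilityRaster:
    def test_constant_features_give_constant_probability(self):
        clf = trained_toy_classifier()
        stack = BandStack({"nir": np.full((5, 5), 0.45),
                           "gdvi": np.full((5, 5), 0.25)}, 1.0)
        proba = predict_probability_raster(clf, stack)
        assert np.ptp(proba) == 0.0

    def test_raster_prediction_equals_flattened_tabular_prediction(self):
        clf = trained_toy_classifier()
        rng = np.random.default_rng(2)
        nir = rng.uniform(0.3, 0.55, (6, 7))
        gdvi = rng.uniform(0.1, 0.35, (6, 7))
        stack = BandStack({"nir": nir, "gdvi": gdvi}, 1.0)
        raster = predict_probability_raster(clf, stack)
        tabular = clf.predict_score(pd.DataFrame({"nir": nir.ravel(),
                                                  "gdvi": gdvi.ravel()}))
        np.testing.assert_array_equal(raster.ravel(), tabular)

    def test_missing_features_propagate_to_missing_probability(self):
        clf = trained_toy_classifier()
        nir = np.full((3, 3), 0.4)
        nir[1, 1] = np.nan
        stack = BandStack({"nir": nir, "gdvi": np.full((3, 3), 0.2)}, 1.0)
        proba = predict_probability_raster(clf, stack)
        assert np.isnan(proba[1, 1]) and np.isfinite(proba[0, 0])
        assert np.nanmin(proba) >= 0.0 and np.nanmax(proba) <= 1.0

    def test_missing_layer_named_in_error(self):
        clf = trained_toy_classifier()
        stack = BandStack({"nir": np.full((3, 3), 0.4)}, 1.0)
        with pytest.raises(KeyError, match="gdvi"):
            predict_probability_raster(clf, stack)


class TestMaskNonCanopy:
    def test_zero_chm_masks_everything(self):
        proba = np.full((4, 4), 0.7)
        chm = CanopyHeightModel(np.zeros((4, 4)), 1.0)
        assert np.isnan(mask_non_canopy(proba, chm, 5.0)).all()

    def test_zero_threshold_masks_nothing(self):
        proba = np.full((4, 4), 0.7)
        chm = CanopyHeightModel(np.random.default_rng(0).uniform(0, 30, (4, 4)),
                                1.0)
        assert np.isfinite(mask_non_canopy(proba, chm, 0.0)).all()

    def test_masked_count_matches_brute_force(self):
        rng = np.random.default_rng(3)
        proba = rng.uniform(size=(10, 10))
        heights = rng.uniform(0, 30, (10, 10))
        chm = CanopyHeightModel(heights, 1.0)
        out = mask_non_canopy(proba, chm, 12.0)
        assert np.isnan(out).sum() == (heights < 12.0).sum()

    def test_misaligned_grids_rejected(self):
        chm = CanopyHeightModel(np.zeros((5, 5)), 1.0)
        with pytest.raises(ValueError, match="misaligned"):
            mask_non_canopy(np.zeros((4, 4)), chm, 1.0)


class TestClassifyAndSummarize:
    def test_zero_threshold_makes_all_canopy_favorable(self):
        proba = np.array([[0.1, np.nan], [0.9, 0.0]])
        hmap = classify_map(proba, 0.0, 1.0)
        assert (hmap.classes[np.isfinite(proba)] == FAVORABLE).all()
        assert hmap.classes[0, 1] == NON_HABITAT

    def test_classes_match_elementwise_threshold_comparison(self):
        rng = np.random.default_rng(4)
        proba = rng.uniform(size=(12, 12))
        proba[rng.uniform(size=(12, 12)) < 0.2] = np.nan
        hmap = classify_map(proba, 0.49, 1.0)
        for i in range(12):
            for j in range(12):
                v = proba[i, j]
                want = (NON_HABITAT if np.isnan(v)
                        else FAVORABLE if v >= 0.49 else UNFAVORABLE)
                assert hmap.classes[i, j] == want

    def test_class_counts_partition_total(self):
        rng = np.random.default_rng(5)
        proba = rng.uniform(size=(20, 20))
        hmap = classify_map(proba, 0.5, 1.0)
        s = summarize_habitat(hmap)
        assert (s.favorable_fraction_pct + s.unfavorable_fraction_pct
                + s.non_habitat_fraction_pct) == pytest.approx(100.0, abs=1e-9)

    def test_fraction_arithmetic(self):
        proba = np.full((800, 800), np.nan)
        proba[:200, :] = 0.9        # 160,000 favorable of 640,000
        hmap = classify_map(proba, 0.5, 0.25)
        s = summarize_habitat(hmap)
        assert s.favorable_fraction_pct == pytest.approx(25.0)
        assert s.area_m2["favorable"] == pytest.approx(160_000 * 0.0625)

    def test_constant_probability_summary(self):
        proba = np.full((10, 10), 0.7)
        s = summarize_habitat(classify_map(proba, 0.5, 1.0))
        assert s.mean_likelihood == pytest.approx(0.7)
        assert s.sd_likelihood == pytest.approx(0.0)

    def test_summary_matches_recomputation_from_raster(self):
        rng = np.random.default_rng(6)
        proba = rng.uniform(size=(15, 15))
        proba[rng.uniform(size=(15, 15)) < 0.3] = np.nan
        hmap = classify_map(proba, 0.49, 1.0)
        s = summarize_habitat(hmap)
        canopy_vals = proba[np.isfinite(proba)]
        assert s.mean_likelihood == pytest.approx(canopy_vals.mean())
        assert s.sd_likelihood == pytest.approx(canopy_vals.std())
        assert s.n_canopy_pixels == canopy_vals.size

    def test_all_masked_map_warns_and_reports_missing(self):
        proba = np.full((5, 5), np.nan)
        with pytest.warns(UserWarning, match="no canopy"):
            s = summarize_habitat(classify_map(proba, 0.5, 1.0))
        assert np.isnan(s.mean_likelihood)
        assert s.non_habitat_fraction_pct == 100.0

    def test_out_of_range_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify_map(np.zeros((2, 2)), 1.5, 1.0)


def clumpiness_brute_force(raster: np.ndarray, class_id: int) -> float:
    """Independent oracle: explicit loop over ordered rook adjacencies."""
    member = raster == class_id
    n_class = member.sum()
    if n_class == 0:
        return float("nan")
    if n_class == raster.size:
        return 1.0
    like = involving = 0
    ny, nx = raster.shape
    for i in range(ny):
        for j in range(nx):
            if not member[i, j]:
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                r, c = i + di, j + dj
                if 0 <= r < ny and 0 <= c < nx:
                    involving += 1
                    like += bool(member[r, c])
    if involving == 0:
        return float("nan")
    g = like / involving
    p = n_class / raster.size
    return (g - p) / (1 - p) if (g >= p or p >= 0.5) else (g - p) / p


class TestClumpiness:
    def test_checkerboard_is_maximally_disaggregated(self):
        board = np.indices((4, 4)).sum(axis=0) % 2
        assert clumpiness(board, 0) == pytest.approx(-1.0)
        assert clumpiness(board, 1) == pytest.approx(-1.0)

    def test_solid_block_on_large_raster_is_highly_aggregated(self):
        big = np.zeros((50, 50), dtype=int)
        big[5:45, 5:45] = 1
        assert clumpiness(big, 1) > 0.9

    def test_full_landscape_class_is_one_by_convention(self):
        assert clumpiness(np.ones((6, 6), dtype=int), 1) == 1.0

    def test_absent_class_is_missing(self):
        assert np.isnan(clumpiness(np.zeros((3, 3), dtype=int), 7))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_adjacency_brute_force_on_small_rasters(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(2, 9, 2))
        raster = rng.integers(0, 3, shape)
        for cls in (0, 1, 2):
            got = clumpiness(raster, cls)
            want = clumpiness_brute_force(raster, cls)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want), (shape, cls)


class TestBitterlich:
    def test_closed_form_hand_values(self):
        assert bitterlich_expansion(0.2, c=25) == pytest.approx(127.3, abs=0.05)
        assert bitterlich_expansion(0.564, c=25) == pytest.approx(16.0,
                                                                  abs=0.05)

    def test_doubling_diameter_quarters_the_density(self):
        assert bitterlich_expansion(0.4) == pytest.approx(
            bitterlich_expansion(0.2) / 4)

    def test_strictly_decreasing_in_diameter_and_gauge(self):
        d = np.linspace(0.1, 1.0, 10)
        vals = bitterlich_expansion(d)
        assert (np.diff(vals) < 0).all()
        assert bitterlich_expansion(0.3, c=30) < bitterlich_expansion(0.3, c=25)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bitterlich_expansion(0.0)
        with pytest.raises(ValueError):
            bitterlich_expansion(0.3, c=0.0)
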
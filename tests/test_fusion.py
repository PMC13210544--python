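import datetime as dt

import numpy as np
import pytest

from casafuse.fusion import (
    FusionParams,
    ReferencePair,
    conversion_coefficient,
    fuse_series,
    predict_single_pair,
    predict_two_pair,
    select_similar_pixels,
    similar_pixel_weights,
)
from casafuse.grids import GridSpec, RasterGrid, RasterSeries

from conftest import make_series
from oracle_estarfm import naive_predict


def _grid(arr):
    arr = np.asarray(arr, float)
    return RasterGrid(GridSpec(*arr.shape), arr)


def _pair(fine, coarse, day=1):
    return ReferencePair(_grid(fine), _grid(coarse), dt.date(2025, 6, day))


class TestSimilarPixels:
    def test_homogeneous_window_selects_everything(self):
        window = np.full((5, 5), 0.4)
        sel = select_similar_pixels(window, (2, 2), n_classes=3)
        assert len(sel) == 25

    def test_two_separated_classes(self):
        window = np.full((4, 4), 0.2)
        window[:, 2:] = 0.8
        # sigma = 0.3, threshold = 2*0.3/3 = 0.2 -> only the 0.2 class
        sel = select_similar_pixels(window, (0, 0), n_classes=3)
        assert sel == [tuple(p) for p in np.argwhere(window == 0.2)]

    def test_unique_center_with_tiny_threshold(self):
        window = np.linspace(0, 1, 25).reshape(5, 5)
        sel = select_similar_pixels(window, (2, 2), n_classes=1000)
        assert sel == [(2, 2)]

    def test_nodata_never_selected(self):
        window = np.full((3, 3), 0.4)
        window[0, 0] = np.nan
        sel = select_similar_pixels(window, (1, 1), n_classes=3)
        assert (0, 0) not in sel and len(sel) == 8


class TestWeights:
    def test_single_pixel_gets_weight_one(self):
        w = similar_pixel_weights([(1, 1)], (1, 1), np.full((3, 3), 0.5),
                                  np.full((3, 3), 0.5), window_half_size=1)
        assert w[0] == pytest.approx(1.0)

    def test_symmetric_pixels_share_weight(self):
        fine = np.full((3, 3), 0.5)
        w = similar_pixel_weights([(1, 0), (1, 2)], (1, 1), fine, fine,
                                  window_half_size=1)
        np.testing.assert_allclose(w, [0.5, 0.5])

    def test_inverse_product_normalization(self):
        # engineer D*S products 1, 2, 4 -> weights 4/7, 2/7, 1/7
        fine = np.zeros((1, 5))
        coarse = np.zeros((1, 5))
        h = 2
        coarse[0, 2] = 0.0          # center: D=1, S=1 -> 1
        coarse[0, 3] = -0.5 / 1.5   # D=1.5, S=1+1/3 -> 2
        coarse[0, 0] = -1.0         # D=2, S=2 -> 4
        w = similar_pixel_weights([(0, 2), (0, 3), (0, 0)], (0, 2), fine,
                                  coarse, window_half_size=h)
        np.testing.assert_allclose(w, [4 / 7, 2 / 7, 1 / 7])

    def test_weights_always_sum_to_one(self, rng):
        fine = rng.random((7, 7))
        coarse = rng.random((7, 7))
        sel = select_similar_pixels(fine, (3, 3), 2)
        w = similar_pixel_weights(sel, (3, 3), fine, coarse, 3)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(w > 0)


class TestConversionCoefficient:
    def test_identity_relation(self):
        vals = np.linspace(0.1, 0.9, 16).reshape(4, 4)
        sim = [(i, j) for i in range(4) for j in range(4)]
        v = conversion_coefficient(sim, [(vals, vals)], regression_min_points=4)
        assert v == pytest.approx(1.0)

    def test_exact_linear_relation_recovered(self):
        coarse = np.linspace(0.1, 0.4, 16).reshape(4, 4)
        fine = 2.0 * coarse + 0.1
        sim = [(i, j) for i in range(4) for j in range(4)]
        v = conversion_coefficient(sim, [(fine, coarse)], regression_min_points=4)
        assert v == pytest.approx(2.0)

    def test_zero_coarse_variance_falls_back(self):
        fine = np.linspace(0, 1, 16).reshape(4, 4)
        coarse = np.full((4, 4), 0.5)
        sim = [(i, j) for i in range(4) for j in range(4)]
        assert conversion_coefficient(sim, [(fine, coarse)], 4) == 1.0

    def test_too_few_points_falls_back(self):
        coarse = np.linspace(0.1, 0.4, 16).reshape(4, 4)
        fine = 2.0 * coarse
        assert conversion_coefficient([(0, 0), (1, 1)], [(fine, coarse)], 10) == 1.0

    def test_uncorrelated_noise_falls_back(self, rng):
        coarse = rng.random((6, 6))
        fine = np.full((6, 6), 0.5) + rng.normal(0, 1e-3, (6, 6))
        sim = [(i, j) for i in range(6) for j in range(6)]
        assert conversion_coefficient(sim, [(fine, coarse)], 4) == 1.0


class TestPredictLaws:
    def test_identity_when_coarse_unchanged(self, rng):
        fine = rng.uniform(0.1, 0.9, (12, 12))
        coarse = fine + rng.normal(0, 0.01, fine.shape)
        pair = _pair(fine, coarse)
        out = predict_single_pair(pair, _grid(coarse.copy()),
                                  FusionParams(window_half_size=3))
        np.testing.assert_array_equal(out.values, fine)

    def test_uniform_offset_on_homogeneous_scene(self):
        fine = np.full((10, 10), 0.4)
        coarse = np.full((10, 10), 0.4)
        out = predict_single_pair(_pair(fine, coarse), _grid(coarse + 0.1),
                                  FusionParams(window_half_size=3))
        np.testing.assert_allclose(out.values, 0.5, atol=1e-8)

    def test_nodata_center_stays_nodata(self):
        fine = np.full((8, 8), 0.4)
        fine[4, 4] = np.nan
        coarse = np.full((8, 8), 0.4)
        out = predict_single_pair(_pair(fine, coarse), _grid(coarse + 0.1),
                                  FusionParams(window_half_size=2))
        assert np.isnan(out.values[4, 4])
        assert np.isfinite(out.values[0, 0])

    def test_output_bounded(self, rng):
        fine = rng.uniform(-1, 1, (10, 10))
        coarse = rng.uniform(-1, 1, (10, 10))
        coarse2 = rng.uniform(-1, 1, (10, 10))
        out = predict_single_pair(_pair(fine, coarse), _grid(coarse2),
                                  FusionParams(window_half_size=3))
        valid = out.values[out.valid_mask]
        assert np.all(valid >= -1) and np.all(valid <= 1)


class TestOracleEquivalence:
    def test_kernel_matches_naive_evaluation_on_random_windows(self):
        """The fast predictor must agree with a direct loop evaluation of
        the weighted-sum prediction on small randomized scenes."""
        params = FusionParams(window_half_size=3, n_classes=2,
                              min_similar=1, regression_min_points=4)
        rng = np.random.default_rng(2024)
        n_scenes = 40  # 40 scenes x 49 pixels > 100 windows by far
        for k in range(n_scenes):
            fine = rng.uniform(0, 1, (7, 7))
            coarse = fine + rng.normal(0, 0.05, (7, 7))
            coarse2 = coarse + rng.normal(0.1, 0.1, (7, 7))
            if k % 2:  # half the scenes carry nodata holes
                holes = rng.random((7, 7)) < 0.1
                fine[holes] = np.nan
            got = predict_single_pair(
                _pair(fine, coarse), _grid(coarse2), params
            ).values
            want = naive_predict(fine, coarse, coarse2, 3, 2, 1, 4,
                                 params.min_correlation)
            np.testing.assert_allclose(got, want, atol=1e-10, equal_nan=True)


class TestTwoPair:
    def test_duplicate_pair_equals_single(self, rng):
        fine = rng.uniform(0.2, 0.8, (10, 10))
        coarse = fine + 0.01
        coarse2 = coarse + rng.normal(0, 0.05, fine.shape)
        p = FusionParams(window_half_size=3)
        pair = _pair(fine, coarse, 1)
        single = predict_single_pair(pair, _grid(coarse2), p,
                                     aux_pair=_pair(fine, coarse, 1))
        double = predict_two_pair(pair, _pair(fine, coarse, 17), _grid(coarse2), p)
        np.testing.assert_allclose(double.values, single.values, atol=1e-10)

    def test_weight_collapses_to_matching_pair(self, rng):
        fine_a = rng.uniform(0.2, 0.8, (10, 10))
        coarse_a = fine_a + 0.01
        fine_b = fine_a + 0.3
        coarse_b = fine_b + 0.01
        coarse2 = coarse_a.copy()  # equals pair a's coarse
        p = FusionParams(window_half_size=3)
        out = predict_two_pair(_pair(fine_a, coarse_a, 1),
                               _pair(fine_b, coarse_b, 17), _grid(coarse2), p)
        # pair a sees zero coarse change -> its prediction (= fine_a) wins
        np.testing.assert_allclose(out.values, fine_a, atol=1e-6)

    def test_equal_references_average_the_fine_images(self):
        fine_a = np.full((8, 8), 0.3)
        fine_b = np.full((8, 8), 0.5)
        coarse = np.full((8, 8), 0.4)
        out = predict_two_pair(_pair(fine_a, coarse, 1), _pair(fine_b, coarse, 17),
                               _grid(coarse.copy()), FusionParams(window_half_size=3))
        np.testing.assert_allclose(out.values, 0.4, atol=1e-8)


def _series_with_gaps(gap_dates, n=24, n_dates=5, seed=5):
    rng = np.random.default_rng(seed)
    spec = GridSpec(n, n)
    dates = [dt.date(2025, 6, 1) + dt.timedelta(days=16 * i) for i in range(n_dates)]
    base = rng.uniform(0.2, 0.6, (n, n))
    fine, coarse = [], []
    for k, date in enumerate(dates):
        vals = np.clip(base + 0.08 * k + rng.normal(0, 0.01, (n, n)), -1, 1)
        c = vals + 0.01
        if date in gap_dates:
            vals = vals.copy()
            vals[5:15, 5:15] = np.nan
        fine.append(RasterGrid(spec, vals))
        coarse.append(RasterGrid(spec, c))
    return RasterSeries(dates, fine), RasterSeries(dates, coarse), dates


class TestFuseSeries:
    def test_no_gaps_is_identity(self):
        fine, coarse, dates = _series_with_gaps([])
        fused, report = fuse_series(fine, coarse, FusionParams(window_half_size=4))
        for (_, a), (_, b) in zip(fused, fine):
            np.testing.assert_array_equal(a.values, b.values)
        assert (report["mode"] == "clear").all()
        assert report["n_filled"].sum() == 0

    def test_bracketed_cloudy_date_fully_filled(self):
        fine, coarse, dates = _series_with_gaps([dates_mid := dt.date(2025, 7, 3)])
        fused, report = fuse_series(fine, coarse, FusionParams(window_half_size=4))
        row = report[report["date"] == dates_mid].iloc[0]
        assert row["mode"] == "two-pair"
        assert row["n_filled"] == 100
        assert fused.grid_for(dates_mid).count_nodata() == 0

    def test_trailing_gap_uses_single_pair(self):
        # last date of the series has the gap: no later reference exists
        fine, coarse, dates = _series_with_gaps([dt.date(2025, 8, 4)])
        fused, report = fuse_series(fine, coarse, FusionParams(window_half_size=4))
        row = report[report["date"] == dt.date(2025, 8, 4)].iloc[0]
        assert row["mode"] == "single-pair"
        assert fused.grid_for(dt.date(2025, 8, 4)).count_nodata() == 0

    def test_no_usable_reference_errors(self):
        fine, coarse, dates = _series_with_gaps([])
        # cloud every date beyond the acceptance threshold
        for g in fine.grids:
            g.values[:20, :] = np.nan
        with pytest.raises(ValueError, match="no reference date"):
            fuse_series(fine, coarse, FusionParams(window_half_size=4))

    def test_clear_pixels_kept_verbatim(self):
        gap_date = dt.date(2025, 7, 3)
        fine, coarse, dates = _series_with_gaps([gap_date])
        original = fine.grid_for(gap_date).values.copy()
        fused, _ = fuse_series(fine, coarse, FusionParams(window_half_size=4))
        clear = ~np.isnan(original)
        np.testing.assert_array_equal(
            fused.grid_for(gap_date).values[clear], original[clear]
        )
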
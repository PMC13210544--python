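import datetime as dt

import numpy as np
import pytest

from casafuse.grids import GridSpec
from casafuse.stress import MAIZE, OTHER, RICE
from casafuse.synthetic import (
    CloudSpec,
    CropPhenology,
    MeteoSpec,
    SceneSpec,
    apply_cloud_mask,
    default_phenology,
    degrade_to_coarse,
    forward_truth_npp,
    make_fields,
    make_landscape,
    make_meteo,
    phenology_ndvi,
    render_fine_series,
)


def small_scene(seed=7, n=60, **kw):
    grid = GridSpec(n, n, origin_x=500000, origin_y=4540000,
                    pixel_size_x=10, pixel_size_y=-10)
    kw.setdefault("n_fields", 16)
    return SceneSpec(grid=grid, scale_factor=6, seed=seed, **kw)


class TestLandscape:
    def test_codes_and_fraction_tolerance(self):
        spec = small_scene(n=100, n_fields=24)
        crop = make_landscape(spec)
        codes = set(np.unique(crop.values).astype(int))
        assert codes <= {OTHER, MAIZE, RICE}
        total = crop.values.size
        for code, target in ((MAIZE, 0.40), (RICE, 0.35), (OTHER, 0.25)):
            realized = (crop.values == code).mean()
            assert abs(realized - target) <= 0.10, (code, realized)

    def test_single_crop_request(self):
        spec = small_scene(crop_fractions=(1.0, 0.0, 0.0))
        crop = make_landscape(spec)
        assert np.all(crop.values == MAIZE)

    def test_deterministic_given_seed(self):
        a = make_landscape(small_scene(seed=3)).values
        b = make_landscape(small_scene(seed=3)).values
        np.testing.assert_array_equal(a, b)
        c = make_landscape(small_scene(seed=4)).values
        assert not np.array_equal(a, c)

    def test_too_many_fields_rejected(self):
        with pytest.raises(ValueError, match="capacity"):
            make_landscape(small_scene(n=20, n_fields=500))

    def test_fields_are_contiguous_rectangles(self):
        spec = small_scene()
        fields = make_fields(spec)
        for k, (r0, r1, c0, c1) in enumerate(fields.rects):
            block = fields.field_ids[r0:r1, c0:c1]
            assert np.all(block == k)


class TestPhenology:
    def test_tails_approach_base_and_peak(self):
        params = {MAIZE: CropPhenology(0.1, 0.8, 150, 250, 0.3, 0.3)}
        assert phenology_ndvi(MAIZE, 100, params) == pytest.approx(0.1, abs=0.01)
        assert phenology_ndvi(MAIZE, 200, params) == pytest.approx(0.8, abs=0.01)

    def test_value_at_green_up_day_matches_closed_form(self):
        p = CropPhenology(0.15, 0.85, 170, 260, 0.09, 0.08)
        got = phenology_ndvi(MAIZE, 170, {MAIZE: p})
        up = 0.5
        down = 1 / (1 + np.exp(-p.senescence_rate * (170 - p.senescence_day)))
        assert got == pytest.approx(p.base_ndvi + 0.7 * (up - down))

    def test_unknown_crop_code(self):
        with pytest.raises(ValueError, match="unknown crop"):
            phenology_ndvi(9, 180, default_phenology())

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            CropPhenology(0.5, 0.4, 150, 250, 0.1, 0.1)  # base >= peak
        with pytest.raises(ValueError):
            CropPhenology(0.1, 0.8, 250, 150, 0.1, 0.1)  # reversed days


class TestRenderSeries:
    def test_zero_noise_makes_crop_pixels_identical(self):
        spec = small_scene()
        crop = make_landscape(spec)
        series = render_fine_series(crop, default_phenology(), spec, noise_sd=0.0)
        maize = crop.values == MAIZE
        for _, grid in series:
            vals = grid.values[maize]
            assert np.ptp(vals) == 0.0

    def test_deterministic_given_seed(self):
        spec = small_scene()
        crop = make_landscape(spec)
        a = render_fine_series(crop, default_phenology(), spec, 0.02)
        b = render_fine_series(crop, default_phenology(), spec, 0.02)
        for (_, ga), (_, gb) in zip(a, b):
            np.testing.assert_array_equal(ga.values, gb.values)

    def test_values_bounded(self):
        spec = small_scene()
        crop = make_landscape(spec)
        series = render_fine_series(crop, default_phenology(), spec, 0.3)
        for _, grid in series:
            assert np.all(grid.values >= -1) and np.all(grid.values <= 1)

    def test_noise_mean_near_curve_at_peak(self):
        spec = small_scene(n=100, n_fields=24)
        crop = make_landscape(spec)
        sd = 0.02
        series = render_fine_series(crop, default_phenology(), spec, sd)
        maize = crop.values == MAIZE
        n = maize.sum()
        peak_date = dt.date(2025, 8, 13)
        doy = peak_date.timetuple().tm_yday
        expected = phenology_ndvi(MAIZE, doy, default_phenology())
        got = series.grid_for(peak_date).values[maize].mean()
        assert abs(got - expected) < 3 * sd / np.sqrt(n) + 1e-3

    def test_missing_crop_parameters_error(self):
        spec = small_scene()
        crop = make_landscape(spec)
        with pytest.raises(ValueError, match="phenology"):
            render_fine_series(crop, {MAIZE: default_phenology()[MAIZE]}, spec)


class TestDegradeToCoarse:
    def test_exact_block_means_without_noise(self):
        spec = small_scene()
        crop = make_landscape(spec)
        series = render_fine_series(crop, default_phenology(), spec, 0.0)
        coarse = degrade_to_coarse(series, 6, bias=0.0, noise_sd=0.0)
        from casafuse.geo_io import aggregate_to_coarse

        for (_, c), (_, f) in zip(coarse, series):
            np.testing.assert_allclose(
                c.values, aggregate_to_coarse(f, 6).values, atol=1e-12
            )

    def test_additive_bias(self):
        spec = small_scene()
        crop = make_landscape(spec)
        series = render_fine_series(crop, default_phenology(), spec, 0.0)
        plain = degrade_to_coarse(series, 6, bias=0.0, noise_sd=0.0)
        biased = degrade_to_coarse(series, 6, bias=0.05, noise_sd=0.0)
        for (_, a), (_, b) in zip(plain, biased):
            assert (b.values - a.values).mean() == pytest.approx(0.05, abs=1e-9)

    def test_deterministic_given_seed(self):
        spec = small_scene()
        crop = make_landscape(spec)
        series = render_fine_series(crop, default_phenology(), spec, 0.02)
        a = degrade_to_coarse(series, 6, seed=11)
        b = degrade_to_coarse(series, 6, seed=11)
        for (_, ga), (_, gb) in zip(a, b):
            np.testing.assert_array_equal(ga.values, gb.values)


class TestCloudMask:
    def _series(self):
        spec = small_scene(n=200, n_fields=30)
        crop = make_landscape(spec)
        return spec, render_fine_series(crop, default_phenology(), spec, 0.0)

    def test_zero_probability_changes_nothing(self):
        _, series = self._series()
        gapped, masks = apply_cloud_mask(series, CloudSpec(jul_aug_gap=0, other_gap=0))
        for (_, a), (_, b) in zip(gapped, series):
            np.testing.assert_array_equal(a.values, b.values)
        for _, m in masks:
            assert m.values.sum() == 0

    def test_probability_one_blanks_the_date(self):
        _, series = self._series()
        date = series.dates[0]
        gapped, _ = apply_cloud_mask(
            series, CloudSpec(per_date={date: 1.0}, other_gap=0, jul_aug_gap=0)
        )
        assert gapped.grid_for(date).count_nodata() == series.spec.n_rows ** 2

    def test_realized_fraction_tracks_target(self):
        _, series = self._series()
        gapped, masks = apply_cloud_mask(series, CloudSpec(jul_aug_gap=0.3,
                                                           other_gap=0.3))
        for _, m in masks:
            frac = m.values.mean()
            assert 0.15 <= frac <= 0.45

    def test_deterministic_given_seed(self):
        _, series = self._series()
        a = apply_cloud_mask(series, CloudSpec(seed=9))[0]
        b = apply_cloud_mask(series, CloudSpec(seed=9))[0]
        for (_, ga), (_, gb) in zip(a, b):
            np.testing.assert_array_equal(ga.values, gb.values)


class TestMeteo:
    def test_zero_gradients_give_constant_fields(self):
        spec = MeteoSpec(t_gradient=0.0, rel_gradient=0.0)
        grid = GridSpec(20, 20)
        for m in make_meteo(spec, [6, 7, 8], grid):
            for g in (m.t_mean, m.sol, m.e_actual, m.e_potential):
                assert np.ptp(g.values) == pytest.approx(0.0)

    def test_july_warmer_than_october_everywhere(self):
        months = make_meteo(MeteoSpec(), [7, 10], GridSpec(20, 20))
        july, october = months[0], months[1]
        assert np.all(july.t_mean.values > october.t_mean.values)

    def test_actual_et_never_exceeds_potential(self):
        for m in make_meteo(MeteoSpec(), range(6, 11), GridSpec(30, 30)):
            ratio = m.e_actual.values / m.e_potential.values
            assert np.all(ratio > 0) and np.all(ratio <= 1)

    def test_radiation_nonnegative(self):
        for m in make_meteo(MeteoSpec(), range(6, 11), GridSpec(10, 10)):
            assert np.all(m.sol.values >= 0)


class TestForwardTruth:
    def _setup(self):
        spec = small_scene(n=80, n_fields=20)
        crop = make_landscape(spec)
        fields = make_fields(spec)
        series = render_fine_series(crop, default_phenology(), spec, 0.02, fields)
        meteo = make_meteo(MeteoSpec(), range(6, 11), spec.grid)
        return crop, series, meteo

    def test_linear_in_solar_radiation(self):
        crop, series, meteo = self._setup()
        _, base = forward_truth_npp(series, crop, meteo)
        doubled = []
        for m in meteo:
            m2 = type(m)(month=m.month, t_mean=m.t_mean,
                         sol=m.sol.with_values(2 * m.sol.values),
                         e_actual=m.e_actual, e_potential=m.e_potential)
            doubled.append(m2)
        _, twice = forward_truth_npp(series, crop, doubled)
        np.testing.assert_allclose(twice.values, 2 * base.values, rtol=1e-10,
                                   equal_nan=True)

    def test_linear_in_epsilon_max(self):
        from casafuse.stress import CropParams

        crop, series, meteo = self._setup()
        _, base = forward_truth_npp(series, crop, meteo,
                                    CropParams(epsilon_max={MAIZE: 1.1, RICE: 0.9}))
        _, scaled = forward_truth_npp(series, crop, meteo,
                                      CropParams(epsilon_max={MAIZE: 2.2, RICE: 1.8}))
        np.testing.assert_allclose(scaled.values, 2 * base.values, rtol=1e-10,
                                   equal_nan=True)

    def test_matches_manual_chain_on_probed_pixel(self):
        from casafuse.fpar import build_extrema_table, fpar_linear
        from casafuse.geo_io import monthly_composite
        from casafuse.stress import (
            optimum_temperature, t_stress_high, t_stress_low, w_stress,
        )

        crop, series, meteo = self._setup()
        monthly, seasonal = forward_truth_npp(series, crop, meteo)
        months = [m.month for m in meteo]
        table = build_extrema_table(series, crop, months)

        # probe one maize pixel in July
        i, j = map(int, np.argwhere(crop.values == MAIZE)[0])
        month = 7
        met = {m.month: m for m in meteo}[month]
        composite = monthly_composite(series, month, "max")
        x = composite.values[i, j]
        nmin, nmax, smin, smax = table.get(MAIZE, month)
        sr = (1 + x) / (1 - x)
        fpar = 0.5 * (fpar_linear(x, nmin, nmax) + fpar_linear(sr, smin, smax))
        composites = [monthly_composite(series, m, "max") for m in months]
        topt = optimum_temperature(composites, [met2.t_mean for met2 in meteo])
        lue = (
            t_stress_low(topt.values[i, j])
            * t_stress_high(topt.values[i, j], met.t_mean.values[i, j])
            * w_stress(met.e_actual.values[i, j], met.e_potential.values[i, j])
            * 1.1
        )
        expected = 0.5 * met.sol.values[i, j] * fpar * lue
        got = [m for m in monthly if m.month == month][0].npp.values[i, j]
        assert got == pytest.approx(expected, rel=1e-10)

    def test_all_other_crop_map_has_no_crop_npp(self):
        spec = small_scene(crop_fractions=(0.0, 0.0, 1.0))
        crop = make_landscape(spec)
        series = render_fine_series(crop, default_phenology(), spec, 0.0)
        meteo = make_meteo(MeteoSpec(), range(6, 11), spec.grid)
        _, seasonal = forward_truth_npp(series, crop, meteo)
        assert seasonal.count_nodata() == seasonal.values.size
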
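import numpy as np
import pytest
from scipy import stats

from droughtnpp.casa import (CasaParams, apar, benchmark_regression,
                             estimated_evapotranspiration, fpar, npp_annual,
                             npp_monthly, optimal_temperature, run_casa,
                             temperature_stress, water_stress)
from droughtnpp.grids import GridError, LandCoverMap, GRASSLAND, WATER
from droughtnpp.indices import pet_thornthwaite
from conftest import make_cube, constant_cube

BOUNDS = {GRASSLAND: (0.1, 0.9)}


def grass_params(**kw):
    kw.setdefault("ndvi_bounds", BOUNDS)
    return CasaParams(**kw)


def ndvi_cube(meta, value, n=12):
    return constant_cube(meta, value, n_months=n)


class TestFpar:
    def _fpar_value(self, meta, uniform_landcover, ndvi, alpha=0.5):
        params = grass_params(fpar_mix_alpha=alpha)
        cube = fpar(ndvi_cube(meta, ndvi), uniform_landcover(meta), params)
        return cube.values[0, 0, 0]

    def test_ramp_endpoints(self, meta, uniform_landcover):
        lo, hi = CasaParams().fpar_bounds
        assert self._fpar_value(meta, uniform_landcover, 0.1) == pytest.approx(lo)
        assert self._fpar_value(meta, uniform_landcover, 0.9) == pytest.approx(hi)

    def test_mixed_estimate_matches_hand_formula(self, meta, uniform_landcover):
        # independent scalar evaluation of both ramp estimates
        n, (n_lo, n_hi) = 0.5, BOUNDS[GRASSLAND]
        f_lo, f_hi = CasaParams().fpar_bounds
        ramp = (n - n_lo) / (n_hi - n_lo) * (f_hi - f_lo) + f_lo
        sr = (1 + n) / (1 - n)
        sr_lo, sr_hi = (1 + n_lo) / (1 - n_lo), (1 + n_hi) / (1 - n_hi)
        srest = (sr - sr_lo) / (sr_hi - sr_lo) * (f_hi - f_lo) + f_lo
        expected = 0.5 * ramp + 0.5 * srest
        assert self._fpar_value(meta, uniform_landcover, 0.5) == \
            pytest.approx(expected, rel=1e-12)

    def test_monotone_in_ndvi(self, meta, uniform_landcover):
        vals = [self._fpar_value(meta, uniform_landcover, v)
                for v in np.linspace(-0.2, 0.99, 25)]
        assert np.all(np.diff(vals) >= 0)

    def test_ndvi_one_is_clamped_not_nan(self, meta, uniform_landcover):
        v = self._fpar_value(meta, uniform_landcover, 1.0)
        assert np.isfinite(v)

    def test_nonvegetated_masked(self, meta, uniform_landcover):
        cube = fpar(ndvi_cube(meta, 0.5), uniform_landcover(meta, WATER),
                    grass_params())
        assert not cube.valid_mask.any()


class TestOptimalTemperature:
    def test_peak_month_temperature_selected(self, meta):
        ndvi = np.full((24, *meta.shape), 0.2)
        temp = np.zeros((24, *meta.shape))
        for i in range(24):
            month = i % 12 + 1
            if month == 7:
                ndvi[i] = 0.8
                temp[i] = 20.0
        topt = optimal_temperature(make_cube(meta, ndvi), make_cube(meta, temp))
        np.testing.assert_allclose(topt, 20.0)

    def test_tie_breaks_to_earliest_month(self, meta):
        ndvi = np.full((12, *meta.shape), 0.2)
        temp = np.arange(12, dtype=float)[:, None, None] * np.ones(meta.shape)
        ndvi[3] = ndvi[8] = 0.8  # April and September tie
        topt = optimal_temperature(make_cube(meta, ndvi), make_cube(meta, temp))
        np.testing.assert_allclose(topt, 3.0)  # April's temperature

    def test_recovers_forced_argmax_everywhere(self, meta, rng):
        # brute-force oracle: per pixel the forced peak month must win
        n_years = 3
        forced = rng.integers(1, 13, size=meta.shape)
        ndvi = rng.uniform(0.1, 0.5, size=(12 * n_years, *meta.shape))
        temp = rng.normal(10, 5, size=(12 * n_years, *meta.shape))
        for i in range(12 * n_years):
            month = i % 12 + 1
            ndvi[i][forced == month] = 0.9
        nc, tc = make_cube(meta, ndvi), make_cube(meta, temp)
        topt = optimal_temperature(nc, tc)
        tvals = tc.values
        for r in range(meta.n_rows):
            for c in range(meta.n_cols):
                idx = nc.calendar_month_indices(int(forced[r, c]))
                assert topt[r, c] == pytest.approx(tvals[idx, r, c].mean())


class TestTemperatureStress:
    def test_t1_quadratic_at_20(self, meta):
        temp = constant_cube(meta, 20.0)
        t1, _ = temperature_stress(temp, np.full(meta.shape, 20.0))
        np.testing.assert_allclose(t1.values, 0.8 + 0.4 - 0.2)

    def test_t2_scalar_substitution_at_topt(self, meta):
        topt, t = 18.0, 18.0
        expected = 1.1814 / (1 + np.exp(0.2 * (topt - 10 - t))) \
            / (1 + np.exp(0.3 * (-topt - 10 + t)))
        _, t2 = temperature_stress(constant_cube(meta, t),
                                   np.full(meta.shape, topt))
        np.testing.assert_allclose(t2.values, expected, rtol=1e-12)

    def test_t2_vanishes_far_below_optimum(self, meta):
        _, t2 = temperature_stress(constant_cube(meta, -40.0),
                                   np.full(meta.shape, 25.0))
        assert t2.values.max() < 1e-3

    def test_nonnegative_and_bounded(self, meta, rng):
        temp = make_cube(meta, rng.uniform(-30, 40, size=(12, *meta.shape)))
        t1, t2 = temperature_stress(temp, rng.uniform(0, 30, size=meta.shape))
        for c in (t1, t2):
            assert c.values.min() >= 0
            assert c.values.max() <= 1.25


class TestWaterStress:
    def test_coupling_formula_matches_hand_value(self):
        p, rn = 50.0, 40.0
        expected = p * rn * (p**2 + rn**2 + p * rn) / ((p + rn) * (p**2 + rn**2))
        assert estimated_evapotranspiration(p, rn) == pytest.approx(expected)

    def test_w_bounds(self, meta, rng):
        precip = make_cube(meta, rng.uniform(0, 200, size=(12, *meta.shape)))
        pet = make_cube(meta, rng.uniform(1, 150, size=(12, *meta.shape)))
        w = water_stress(precip, pet)
        assert w.values.min() >= 0.5
        assert w.values.max() <= 1.0

    def test_zero_pet_floors_at_half(self, meta):
        w = water_stress(constant_cube(meta, 50.0), constant_cube(meta, 0.0))
        np.testing.assert_allclose(w.values, 0.5)

    def test_abundant_water_saturates(self, meta):
        w = water_stress(constant_cube(meta, 5000.0), constant_cube(meta, 10.0))
        np.testing.assert_allclose(w.values, 1.0, atol=1e-3)

    def test_soil_moisture_mode(self, meta, rng):
        sm = make_cube(meta, rng.uniform(0.05, 0.4, size=(24, *meta.shape)))
        w = water_stress(sm, sm, sm=sm, mode="soil_moisture")
        assert w.values.min() >= 0.5
        assert w.values.max() <= 1.0
        # month at the per-pixel p95 reaches W = 1
        p95 = np.percentile(sm.values, 95, axis=0)
        high = sm.values >= p95[None]
        np.testing.assert_allclose(w.values[high], 1.0, atol=1e-9)


class TestAparAndNpp:
    def test_apar_arithmetic(self, meta):
        a = apar(constant_cube(meta, 100.0), constant_cube(meta, 0.4))
        np.testing.assert_allclose(a.values, 20.0)

    def test_zero_fpar_zero_apar(self, meta):
        a = apar(constant_cube(meta, 100.0), constant_cube(meta, 0.0))
        np.testing.assert_allclose(a.values, 0.0)

    def test_negative_sol_rejected(self, meta):
        with pytest.raises(GridError):
            apar(constant_cube(meta, -1.0), constant_cube(meta, 0.4))

    def test_apar_equals_elementwise_oracle(self, meta, rng):
        sol = make_cube(meta, rng.uniform(0, 700, size=(12, *meta.shape)))
        f = make_cube(meta, rng.uniform(0, 1, size=(12, *meta.shape)))
        a = apar(sol, f)
        for i in range(12):
            for r in range(meta.n_rows):
                for c in range(meta.n_cols):
                    assert a.values[i, r, c] == \
                        0.5 * sol.values[i, r, c] * f.values[i, r, c]

    def test_npp_arithmetic(self, meta, uniform_landcover):
        ones = constant_cube(meta, 1.0)
        npp = npp_monthly(constant_cube(meta, 20.0), ones, ones, ones,
                          uniform_landcover(meta), grass_params())
        np.testing.assert_allclose(npp.values, 20.0 * 0.542)

    def test_npp_linear_in_each_stress(self, meta, uniform_landcover):
        ones = constant_cube(meta, 1.0)
        half = constant_cube(meta, 0.5)
        lc, params = uniform_landcover(meta), grass_params()
        full = npp_monthly(constant_cube(meta, 20.0), ones, ones, ones, lc, params)
        halved = npp_monthly(constant_cube(meta, 20.0), ones, ones, half, lc, params)
        np.testing.assert_allclose(halved.values, 0.5 * full.values)

    def test_npp_homogeneous_in_sol(self, meta, uniform_landcover, rng):
        lc, params = uniform_landcover(meta), grass_params()
        f = make_cube(meta, rng.uniform(0.1, 0.9, size=(12, *meta.shape)))
        ones = constant_cube(meta, 1.0)
        sol1 = make_cube(meta, rng.uniform(10, 700, size=(12, *meta.shape)))
        sol2 = sol1.copy_with(values=2 * sol1.values)
        n1 = npp_monthly(apar(sol1, f), ones, ones, ones, lc, params)
        n2 = npp_monthly(apar(sol2, f), ones, ones, ones, lc, params)
        np.testing.assert_allclose(n2.values, 2 * n1.values)

    def test_missing_eps_max_is_hard_error(self, meta, uniform_landcover):
        ones = constant_cube(meta, 1.0)
        with pytest.raises(GridError, match="eps_max"):
            npp_monthly(constant_cube(meta, 20.0), ones, ones, ones,
                        uniform_landcover(meta),
                        grass_params(eps_max={1: 0.542}))

    def test_nonvegetated_masked(self, meta, uniform_landcover):
        ones = constant_cube(meta, 1.0)
        npp = npp_monthly(constant_cube(meta, 20.0), ones, ones, ones,
                          uniform_landcover(meta, WATER), grass_params())
        assert not npp.valid_mask.any()


class TestAnnual:
    def test_constant_month_sums_to_twelvefold(self, meta):
        npp = constant_cube(meta, 10.0)
        np.testing.assert_allclose(npp_annual(npp, 2001), 120.0)

    def test_masked_month_masks_pixel(self, meta):
        vals = np.full((12, *meta.shape), 10.0)
        mask = np.ones_like(vals, dtype=bool)
        mask[4, 0, 0] = False
        cube = make_cube(meta, vals)
        cube.valid_mask = mask
        annual = npp_annual(cube, 2001)
        assert np.isnan(annual[0, 0])
        assert annual[1, 1] == pytest.approx(120.0)

    def test_incomplete_year_is_error(self, meta):
        cube = constant_cube(meta, 10.0, n_months=10)
        with pytest.raises(GridError, match="incomplete"):
            npp_annual(cube, 2001)

    def test_matches_explicit_sum_oracle(self, meta, rng):
        cube = make_cube(meta, rng.uniform(0, 50, size=(12, *meta.shape)))
        annual = npp_annual(cube, 2001)
        for r in range(meta.n_rows):
            for c in range(meta.n_cols):
                assert annual[r, c] == pytest.approx(
                    sum(cube.values[i, r, c] for i in range(12)))


def test_full_chain_equals_factorized_oracle(meta, uniform_landcover, rng):
    """NPP factorisation: the op chain equals 0.5*SOL*FPAR*T1*T2*W*eps_max
    computed element-wise."""
    lc = uniform_landcover(meta)
    params = grass_params()
    shape = (12, *meta.shape)
    ndvi = make_cube(meta, rng.uniform(0.1, 0.9, size=shape))
    temp = make_cube(meta, rng.uniform(0, 30, size=shape))
    sol = make_cube(meta, rng.uniform(50, 700, size=shape))
    precip = make_cube(meta, rng.uniform(0, 200, size=shape))
    pet = pet_thornthwaite(temp)
    npp = run_casa(ndvi, temp, sol, precip, pet, lc, params)
    f = fpar(ndvi, lc, params)
    topt = optimal_temperature(ndvi, temp)
    t1, t2 = temperature_stress(temp, topt)
    w = water_stress(precip, pet)
    expected = (0.5 * sol.values * f.values * t1.values * t2.values
                * w.values * 0.542)
    np.testing.assert_allclose(npp.values, expected, rtol=1e-12)
    # energy bound: NPP <= 0.5*SOL*eps_max with FPAR,T,W <= ~1.19
    assert np.all(npp.values <= 0.5 * sol.values * 0.542 * 1.19)


def test_benchmark_regression_self_consistency(meta, uniform_landcover, rng):
    npp = make_cube(meta, rng.uniform(10, 80, size=(36, *meta.shape)))
    res = benchmark_regression(npp, npp, uniform_landcover(meta))
    assert res["r2"] == pytest.approx(1.0)
    assert res["slope"] == pytest.approx(1.0)
    assert res["p"] < 0.01
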
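import itertools

import numpy as np
import pandas as pd
import pytest

from droughtnpp.grids import (GridCube, GridError, GridMeta, LandCoverMap,
                              GRASSLAND, month_range)
from droughtnpp.impact import (SkillScores, catalog_months, delta_npp,
                               aggregate_delta_table, non_drought_baseline,
                               regional_drought_flags, seasonal_anomaly_profile,
                               skill_scores)
from droughtnpp.indices import DroughtIndexCube, SeverityCube
from droughtnpp.synthetic import SynthConfig, npp_drought_scenario
from conftest import make_cube, constant_cube


def severity_cube_from(npp_like, codes):
    return SeverityCube(cube=npp_like.copy_with(
        values=np.asarray(codes, dtype=float), units="severity"),
        scheme="spei_table1")


class TestBaseline:
    def test_no_drought_gives_climatological_mean(self, meta, rng,
                                                  uniform_landcover):
        npp = make_cube(meta, rng.uniform(10, 60, size=(24, *meta.shape)))
        sev = severity_cube_from(npp, np.zeros((24, *meta.shape)))
        base = non_drought_baseline(npp, sev, uniform_landcover(meta))
        assert len(base) == 12
        for row in base.itertuples():
            steps = npp.calendar_month_indices(row.month)
            assert row.baseline == pytest.approx(npp.values[steps].mean())

    def test_all_drought_class_has_no_baseline(self, meta, rng,
                                               uniform_landcover):
        npp = make_cube(meta, rng.uniform(10, 60, size=(12, *meta.shape)))
        sev = severity_cube_from(npp, np.full((12, *meta.shape), 2.0))
        base = non_drought_baseline(npp, sev, uniform_landcover(meta))
        assert base.empty

    def test_two_pixel_toy_matches_hand_average(self):
        meta = GridMeta(n_rows=1, n_cols=2, cell_size=1.0, origin_y=40.0)
        # two years of january: pixel values (10, 20) and (30, 40); the
        # second january at pixel 0 is a drought month
        vals = np.zeros((24, 1, 2))
        vals[0] = [[10.0, 20.0]]
        vals[12] = [[30.0, 40.0]]
        codes = np.zeros((24, 1, 2))
        codes[12, 0, 0] = 2.0
        npp = make_cube(meta, vals)
        lc = LandCoverMap(meta=meta, classes=np.full((1, 2), GRASSLAND,
                                                     dtype=np.int16))
        base = non_drought_baseline(npp, severity_cube_from(npp, codes), lc)
        jan = base[base.month == 1].iloc[0]
        assert jan.baseline == pytest.approx((10 + 20 + 40) / 3)
        assert jan.n == 3


class TestDeltaNpp:
    def make_toy(self, meta, rng, uniform_landcover, factor):
        """Half the record drought-free; drought months at NPP*factor."""
        base_vals = rng.uniform(20, 60, size=(12, *meta.shape))
        vals = np.concatenate([base_vals, base_vals * factor])
        codes = np.concatenate([np.zeros((12, *meta.shape)),
                                np.full((12, *meta.shape), 3.0)])
        npp = make_cube(meta, vals)
        return npp, severity_cube_from(npp, codes), uniform_landcover(meta)

    def test_npp_equal_to_baseline_gives_zero(self, meta, rng,
                                              uniform_landcover):
        npp, sev, lc = self.make_toy(meta, rng, uniform_landcover, 1.0)
        table = delta_npp(npp, sev, lc, by_month=False)
        np.testing.assert_allclose(table.delta_npp_pct, 0.0, atol=1e-9)

    def test_twenty_percent_surplus(self, meta, rng, uniform_landcover):
        npp, sev, lc = self.make_toy(meta, rng, uniform_landcover, 1.2)
        table = delta_npp(npp, sev, lc, by_month=False)
        np.testing.assert_allclose(table.delta_npp_pct, 20.0, rtol=1e-9)

    def test_rows_with_no_samples_absent(self, meta, rng, uniform_landcover):
        npp, sev, lc = self.make_toy(meta, rng, uniform_landcover, 0.8)
        table = delta_npp(npp, sev, lc, by_month=False)
        assert set(table.severity_code) == {3}

    def test_imposed_grassland_reduction_recovered(self):
        sc = npp_drought_scenario(
            SynthConfig(n_rows=20, n_cols=20, years=(2001, 2020), seed=8),
            seed=8)
        table = delta_npp(sc["npp"], sc["severity"], sc["landcover"],
                          by_month=False)
        row = table[(table["class"] == "grassland")
                    & (table.severity == "severe")].iloc[0]
        assert -33 < row.delta_npp_pct < -27

    def test_severity_monotonic_scenario_gives_monotonic_table(self):
        sc = npp_drought_scenario(
            SynthConfig(n_rows=20, n_cols=20, years=(2001, 2020), seed=3),
            seed=3)
        table = delta_npp(sc["npp"], sc["severity"], sc["landcover"],
                          by_month=False)
        for cls in ("farmland", "woodland", "grassland"):
            sub = table[table["class"] == cls].sort_values("severity_code")
            deltas = sub.delta_npp_pct.to_numpy()
            assert np.all(np.diff(deltas) < 0), cls

    def test_weighted_mean_consistency(self, meta, rng, uniform_landcover):
        """Severity means recombine (n-weighted) to the pooled drought mean."""
        vals = rng.uniform(20, 60, size=(48, *meta.shape))
        codes = rng.integers(0, 5, size=(48, *meta.shape)).astype(float)
        npp = make_cube(meta, vals)
        sev = severity_cube_from(npp, codes)
        lc = uniform_landcover(meta)
        base = non_drought_baseline(npp, sev, lc)
        monthly = delta_npp(npp, sev, lc, base, by_month=True)
        table = aggregate_delta_table(monthly)
        pooled = np.average(table.delta_npp_pct, weights=table.n)
        # oracle: direct mean over every drought pixel-month
        lut = {(r.class_code, r.month): r.baseline for r in base.itertuples()}
        acc = []
        for i, (_, m) in enumerate(npp.times):
            b = lut[(GRASSLAND, m)]
            sel = codes[i] >= 1
            acc.extend(100 * (vals[i][sel] - b) / b)
        assert pooled == pytest.approx(np.mean(acc), rel=1e-9)


class TestSeasonalProfile:
    def make_table(self, deltas_by_month):
        rows = []
        for m, d in deltas_by_month.items():
            rows.append({"class_code": 3, "class": "grassland",
                         "severity_code": 3, "severity": "severe",
                         "month": m, "delta_npp_pct": d, "n": 10})
        return pd.DataFrame(rows)

    def test_uniform_deltas_equal_windows(self):
        table = self.make_table({m: -10.0 for m in range(1, 13)})
        prof = seasonal_anomaly_profile(table)
        row = prof.iloc[0]
        assert row.early_mean_delta_pct == pytest.approx(-10.0)
        assert row.peak_mean_delta_pct == pytest.approx(-10.0)

    def test_deeper_summer_deficit_detected(self):
        table = self.make_table({3: -5.0, 4: -6.0, 5: -7.0,
                                 6: -15.0, 7: -18.0, 8: -20.0})
        prof = seasonal_anomaly_profile(table)
        row = prof.iloc[0]
        assert row.peak_mean_delta_pct < row.early_mean_delta_pct
        assert row.more_negative_window == "peak"

    def test_missing_window_absent(self):
        table = self.make_table({3: -5.0})
        prof = seasonal_anomaly_profile(table)
        row = prof.iloc[0]
        assert np.isnan(row.peak_mean_delta_pct)
        assert row.more_negative_window == ""


def make_index(meta, values, times=None, k=1):
    n = len(values)
    times = times or month_range((2001, 1), (2001 + (n - 1) // 12,
                                             (n - 1) % 12 + 1))
    vals = np.asarray(values, dtype=float)[:, None, None] * np.ones(meta.shape)
    cube = GridCube(meta=meta, times=times, values=vals, units="1")
    return DroughtIndexCube(cube=cube, scale_k=k, index_kind="spei")


class TestRegionalFlags:
    def test_deep_drought_flags_under_both_rules(self, meta):
        idx = make_index(meta, np.full(12, -2.0))
        for rule in ("mean_index", "area_fraction"):
            flags = regional_drought_flags(idx, rule=rule)
            assert flags.all()

    def test_wet_month_not_flagged(self, meta):
        idx = make_index(meta, np.ones(12))
        for rule in ("mean_index", "area_fraction"):
            assert not regional_drought_flags(idx, rule=rule).any()

    def test_area_fraction_matches_counting_oracle(self, meta, rng):
        n = 24
        vals = rng.standard_normal((n, *meta.shape))
        cube = GridCube(meta=meta, times=month_range((2001, 1), (2002, 12)),
                        values=vals, units="1")
        idx = DroughtIndexCube(cube=cube, scale_k=1, index_kind="spei")
        flags = regional_drought_flags(idx, rule="area_fraction", phi=0.3,
                                       severity_threshold=-0.5)
        for i in range(n):
            frac = np.mean(vals[i] <= -0.5)
            assert flags.iloc[i] == (frac >= 0.3)


class TestSkillScores:
    def catalog(self, spans):
        return pd.DataFrame(
            [{"start_year": a[0], "start_month": a[1], "end_year": b[0],
              "end_month": b[1], "label": "ev"} for a, b in spans])

    def flags(self, months_true, years=(2001, 2002)):
        times = month_range((years[0], 1), (years[1], 12))
        idx = pd.MultiIndex.from_tuples(times, names=["year", "month"])
        return pd.Series([t in months_true for t in times], index=idx)

    def test_perfect_forecast(self):
        cat = self.catalog([((2001, 3), (2001, 5))])
        flags = self.flags({(2001, 3), (2001, 4), (2001, 5)})
        sc = skill_scores(flags, cat)
        assert (sc.pod, sc.far, sc.csi) == (1.0, 0.0, 1.0)

    def test_printed_count_triple(self):
        sc = SkillScores(hits=16, misses=7, false_alarms=3)
        assert sc.pod == pytest.approx(0.6957, abs=5e-5)
        assert sc.far == pytest.approx(0.1579, abs=5e-5)
        assert sc.csi == pytest.approx(16 / 26, abs=1e-9)

    def test_no_flags_pod_zero_far_absent(self):
        cat = self.catalog([((2001, 3), (2001, 5))])
        sc = skill_scores(self.flags(set()), cat)
        assert sc.pod == 0.0
        assert sc.far is None

    def test_empty_catalog_far_computable(self):
        sc = skill_scores(self.flags({(2001, 3)}), self.catalog([]))
        assert sc.pod is None
        assert sc.far == 1.0

    def test_catalog_outside_range_is_error(self):
        cat = self.catalog([((2005, 1), (2005, 2))])
        with pytest.raises(GridError):
            skill_scores(self.flags(set()), cat)

    def test_multi_year_event_expands_months(self):
        cat = self.catalog([((2001, 11), (2002, 2))])
        assert catalog_months(cat) == {(2001, 11), (2001, 12), (2002, 1),
                                       (2002, 2)}

    def test_random_pairs_match_brute_force_and_csi_bound(self, rng):
        times = month_range((2001, 1), (2002, 12))
        for _ in range(60):
            flagged = set(t for t in times if rng.random() < 0.4)
            n_ev = rng.integers(0, 3)
            spans = []
            for _ in range(n_ev):
                i = int(rng.integers(0, 20))
                j = int(rng.integers(i, min(i + 5, 23)))
                spans.append((times[i], times[j]))
            cat = self.catalog(spans)
            flags = self.flags(flagged)
            sc = skill_scores(flags, cat)
            ev = catalog_months(cat)
            h = len([t for t in times if t in flagged and t in ev])
            m = len([t for t in ev if t not in flagged])
            f = len([t for t in times if t in flagged and t not in ev])
            assert (sc.hits, sc.misses, sc.false_alarms) == (h, m, f)
            if sc.csi is not None and sc.pod is not None:
                assert sc.csi <= sc.pod + 1e-12
                if sc.far is not None:
                    assert sc.csi <= 1 - sc.far + 1e-12
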
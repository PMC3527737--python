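import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import birchphen as bp
from birchphen.phenology import daily_mean, interpolate_thresholds
from birchphen.synthetic import snap_thresholds


def temp_series(values, start="2006-03-01"):
    return pd.Series(
        np.asarray(values, float), index=pd.date_range(start, periods=len(values))
    )


class TestDailyMean:
    def test_constant_day(self, grid):
        times = pd.date_range("2006-03-01", "2006-06-01", freq="3h")
        vals = np.full((len(times), grid.n_lat, grid.n_lon), 10.0)
        temps = bp.GriddedTemperature.from_array(grid, times, vals)
        out = daily_mean(temps)
        assert out.is_daily
        np.testing.assert_allclose(out.data.values, 10.0)

    def test_arithmetic_mean_of_eight_steps(self, grid):
        times = pd.date_range("2006-03-01", periods=16, freq="3h")
        day_cycle = np.array([0, 2, 4, 6, 8, 10, 12, 14], dtype=float)
        vals = np.tile(day_cycle, 2)[:, None, None] * np.ones((16, grid.n_lat, grid.n_lon))
        temps = bp.GriddedTemperature.from_array(grid, times, vals)
        out = daily_mean(temps)
        np.testing.assert_allclose(out.data.values, 7.0)

    def test_daily_input_idempotent(self, clean_temps):
        out = daily_mean(clean_temps)
        assert out is clean_temps


class TestHeatSum:
    def test_constant_series(self):
        s = temp_series([10.0] * 10)
        assert bp.heat_sum(s) == pytest.approx(65.0)  # (10 - 3.5) * 10

    def test_below_cutoff_contributes_nothing(self):
        s = temp_series([3.0] * 10)
        assert bp.heat_sum(s) == 0.0

    def test_constant_bias_propagates_linearly(self):
        # +0.5 degC on 60 above-cutoff days shifts the sum by exactly 30 dd
        base = temp_series([10.0] * 60)
        assert bp.heat_sum(base + 0.5) - bp.heat_sum(base) == pytest.approx(30.0)
        assert bp.heat_sum(base - 0.5) - bp.heat_sum(base) == pytest.approx(-30.0)

    def test_non_decreasing_and_non_negative(self):
        rng = np.random.default_rng(0)
        s = temp_series(rng.uniform(-5, 15, 60))
        cum = bp.heat_sum_series(s)
        assert (np.diff(cum.to_numpy()) >= 0).all()
        assert (cum.to_numpy() >= 0).all()

    def test_accumulation_starts_1_march(self):
        s = temp_series([10.0] * 70, start="2006-02-20")
        # 9 February days are ignored
        assert bp.heat_sum(s) == pytest.approx(6.5 * 61)

    def test_window_not_covered_raises(self):
        s = temp_series([10.0] * 10, start="2006-03-05")
        with pytest.raises(ValueError):
            bp.heat_sum(s)
        s2 = temp_series([10.0] * 10)
        with pytest.raises(ValueError):
            bp.heat_sum(s2, until="2006-04-01")


class TestFirstCrossing:
    def test_constant_series_crossing_day(self):
        s = temp_series([10.0] * 20)
        # 6.5 dd/day -> reaches 65 on accumulation day 10
        assert bp.first_crossing(s, threshold=65.0) == pd.Timestamp("2006-03-10")

    def test_unreachable_threshold(self):
        s = temp_series([10.0] * 20)
        assert bp.first_crossing(s, threshold=1e9) is None

    @given(st.floats(min_value=1.0, max_value=120.0), st.floats(min_value=1.0, max_value=120.0))
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_threshold(self, t1, t2):
        s = temp_series([8.0] * 40)
        lo, hi = sorted((t1, t2))
        d_lo, d_hi = bp.first_crossing(s, threshold=lo), bp.first_crossing(s, threshold=hi)
        assert d_lo is not None and d_hi is not None and d_lo <= d_hi


class TestFitThresholdLU:
    def test_heat_sum_at_lu_date(self, grid, dates):
        sc = bp.SimulationScenario(base_temp=10.0, warming_rate=0.0, lat_gradient=0.0, noise_sd=0.0)
        temps = bp.gen_temperature(sc, grid, dates)
        rec = bp.PhenologyRecord("A", 55.0, 15.0, pd.Timestamp("2006-03-10"))
        df = bp.fit_threshold_lu(temps, [rec])
        assert df["threshold"].iloc[0] == pytest.approx(65.0)

    def test_round_trip_with_first_crossing(self, clean_temps, clean_records):
        df = bp.fit_threshold_lu(clean_temps, clean_records)
        for _, row in df.iterrows():
            cell = clean_temps.station_series(row["lat"], row["lon"])
            rec = next(r for r in clean_records if r.station_id == row["station_id"])
            assert bp.first_crossing(cell, threshold=row["threshold"]) == rec.leaf_unfolding_date

    def test_pre_window_date_rejected(self, clean_temps):
        rec = bp.PhenologyRecord("B", 55.0, 15.0, pd.Timestamp("2006-02-28"))
        with pytest.raises(ValueError, match="precedes"):
            bp.fit_threshold_lu(clean_temps, [rec])

    def test_missing_records_skipped(self, clean_temps):
        recs = [bp.PhenologyRecord("C", 55.0, 15.0, None)]
        assert bp.fit_threshold_lu(clean_temps, recs).empty


class TestFitThresholdObs:
    def test_recovers_truth_with_front_loaded_pulse(self, clean_temps, truth_map, clean_scenario, stations):
        # short pulse: its cumulative reaches 2.5% within a day of onset
        sc = clean_scenario.with_(season_length=10)
        pollen = bp.gen_pollen_series(clean_temps, truth_map, sc, stations)
        df = bp.fit_threshold_obs(clean_temps, pollen)
        for _, row in df.iterrows():
            truth = truth_map.at_station(row["lat"], row["lon"])
            cell = clean_temps.station_series(row["lat"], row["lon"])
            cross = bp.first_crossing(cell, threshold=truth)
            one_day = bp.heat_sum(cell, until=cross + pd.Timedelta(days=1)) - truth
            assert truth - 1e-9 <= row["threshold"] <= truth + one_day + 1e-9

    def test_lrt_spikes_bias_threshold_low(self, clean_temps, truth_map, clean_scenario, stations):
        spiky = clean_scenario.with_(lrt_spike_prob=0.5, lrt_spike_conc=500.0, seed=13)
        pollen = bp.gen_pollen_series(clean_temps, truth_map, spiky, stations)
        df = bp.fit_threshold_obs(clean_temps, pollen)
        truths = np.array([truth_map.at_station(r.lat, r.lon) for r in df.itertuples()])
        assert (df["threshold"].to_numpy() <= truths + 1e-9).all()
        assert df["threshold"].mean() < truths.mean()

    def test_higher_q_never_lowers_threshold(self, clean_temps, truth_map, clean_scenario, stations):
        pollen = bp.gen_pollen_series(clean_temps, truth_map, clean_scenario, stations)
        lo = bp.fit_threshold_obs(clean_temps, pollen, q=0.025).set_index("station_id")
        hi = bp.fit_threshold_obs(clean_temps, pollen, q=0.05).set_index("station_id")
        assert (hi["threshold"] >= lo["threshold"] - 1e-9).all()

    def test_all_zero_series_skipped(self, clean_temps):
        n = len(clean_temps.times)
        flat = bp.StationSeries(
            "Z", 55.25, 15.25,
            pd.DatetimeIndex(clean_temps.times).normalize(),
            np.zeros(n), np.ones(n, dtype=bool),
        )
        assert bp.fit_threshold_obs(clean_temps, [flat]).empty


class TestInterpolation:
    def test_single_station_fills_radius(self, grid):
        df = pd.DataFrame({"station_id": ["A"], "lat": [55.25], "lon": [15.25], "threshold": [120.0]})
        tmap = interpolate_thresholds(df, grid, radius_deg=3.0)
        vals = tmap.values[tmap.defined]
        np.testing.assert_allclose(vals, 120.0)
        # distant corner stays undefined
        i, j = grid.nearest_cell(50.25, 10.25)
        assert np.isnan(tmap.values[i, j])

    def test_coincident_station_exact(self, grid):
        df = pd.DataFrame(
            {"station_id": list("AB"), "lat": [55.25, 52.25], "lon": [15.25, 12.25], "threshold": [120.0, 80.0]}
        )
        tmap = interpolate_thresholds(df, grid)
        assert tmap.at_station(55.25, 15.25) == 120.0
        assert tmap.at_station(52.25, 12.25) == 80.0

    def test_values_bounded_by_station_range(self, grid):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "station_id": [f"S{i}" for i in range(12)],
                "lat": rng.uniform(50, 60, 12),
                "lon": rng.uniform(10, 20, 12),
                "threshold": rng.uniform(60, 180, 12),
            }
        )
        tmap = interpolate_thresholds(df, grid, radius_deg=30.0)
        vals = tmap.values[tmap.defined]
        assert vals.min() >= df["threshold"].min() - 1e-9
        assert vals.max() <= df["threshold"].max() + 1e-9

    def test_zero_stations_rejected(self, grid):
        empty = pd.DataFrame(columns=["station_id", "lat", "lon", "threshold"])
        with pytest.raises(ValueError):
            interpolate_thresholds(empty, grid)


class TestCombineMaps:
    @pytest.fixture()
    def maps(self, grid):
        lu = bp.ThresholdMap(grid, np.full((grid.n_lat, grid.n_lon), 100.0), "LU")
        obs_vals = np.full((grid.n_lat, grid.n_lon), 80.0)
        obs_vals[0, 0] = np.nan  # a southern cell without pollen coverage
        obs = bp.ThresholdMap(grid, obs_vals, "OBS")
        mask = bp.RegionMask.latitude_band(grid, 55.0)
        return lu, obs, mask

    def test_north_takes_lu_south_takes_obs(self, maps, grid):
        lu, obs, mask = maps
        comb = bp.combine_maps(lu, obs, mask)
        assert comb.method == "COMB"
        i_n, j = grid.nearest_cell(59.75, 15.25)
        i_s, _ = grid.nearest_cell(50.75, 15.25)
        assert comb.values[i_n, j] == 100.0
        assert comb.values[i_s, j] == 80.0

    def test_south_falls_back_to_lu_where_obs_undefined(self, maps):
        lu, obs, mask = maps
        comb = bp.combine_maps(lu, obs, mask)
        assert comb.values[0, 0] == 100.0

    def test_comb_equals_lu_everywhere_north(self, maps):
        lu, obs, mask = maps
        comb = bp.combine_maps(lu, obs, mask)
        np.testing.assert_array_equal(comb.values[mask.is_north], lu.values[mask.is_north])

    def test_grid_mismatch_rejected(self, maps):
        lu, obs, _ = maps
        other = bp.GridSpec(40.0, 50.0, 10.0, 20.0, 0.5)
        mask = bp.RegionMask.latitude_band(other, 45.0)
        with pytest.raises(ValueError):
            bp.combine_maps(lu, obs, mask)


class TestPredictStartMap:
    def test_uniform_world_uniform_date(self, grid, dates):
        sc = bp.SimulationScenario(base_temp=10.0, warming_rate=0.0, lat_gradient=0.0, noise_sd=0.0)
        temps = bp.gen_temperature(sc, grid, dates)
        tmap = bp.ThresholdMap(grid, np.full((grid.n_lat, grid.n_lon), 65.0), "TRUTH")
        out = bp.predict_start_map(temps, tmap)
        assert (out == np.datetime64("2006-03-10")).all()

    def test_warm_bias_never_delays(self, grid, dates, truth_map):
        sc = bp.SimulationScenario(noise_sd=0.0)
        cold = bp.gen_temperature(sc, grid, dates)
        warm = bp.gen_temperature(sc.with_(bias=1.0), grid, dates)
        d_cold = bp.predict_start_map(cold, truth_map)
        d_warm = bp.predict_start_map(warm, truth_map)
        both = ~(np.isnat(d_cold) | np.isnat(d_warm))
        assert (d_warm[both] <= d_cold[both]).all()

    def test_truth_closure_on_clean_data(self, clean_temps, truth_map, clean_records, stations):
        res = bp.FloweringModel(clean_temps, leaf_unfolding=clean_records).fit("lu")
        pred = res.predict_station_starts(stations)
        for rec in clean_records:
            assert pred[rec.station_id] == rec.leaf_unfolding_date
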
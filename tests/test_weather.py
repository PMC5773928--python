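"""Weather ingestion, cleaning, and synthesis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medpql import weather
from medpql.weather import (
    INTERP_DAY_OVER_DAY,
    INTERP_SMALL_GAP,
    OBSERVED,
    EmptyInputError,
    ParseError,
    SyntheticClimateParams,
    UnfillableGapError,
)

from conftest import make_constant_series, make_raw


def _write(tmp_path, text, name="t.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadHourlyCsv:
    def test_well_formed_identity(self, tmp_path):
        p = _write(
            tmp_path,
            "timestamp,temp_c\n"
            "2001-01-01T00:00:00,10.0\n2001-01-01T01:00:00,11.5\n2001-01-01T02:00:00,12.0\n",
        )
        raw = weather.read_hourly_csv(p)
        assert len(raw) == 3
        assert raw.temps.tolist() == [10.0, 11.5, 12.0]

    def test_out_of_order_rows_sorted(self, tmp_path):
        p = _write(
            tmp_path,
            "timestamp,temp_c\n"
            "2001-01-01T02:00:00,12\n2001-01-01T00:00:00,10\n2001-01-01T01:00:00,11\n",
        )
        raw = weather.read_hourly_csv(p)
        assert raw.times.is_monotonic_increasing
        assert raw.temps.tolist() == [10.0, 11.0, 12.0]

    def test_conflicting_duplicates_resolved_by_mean(self, tmp_path):
        p = _write(
            tmp_path,
            "timestamp,temp_c\n2001-01-01T00:00:00,10\n2001-01-01T00:00:00,12\n",
        )
        raw = weather.read_hourly_csv(p)
        assert len(raw) == 1
        assert raw.temps[0] == pytest.approx(11.0)

    def test_malformed_timestamp_names_line(self, tmp_path):
        p = _write(
            tmp_path, "timestamp,temp_c\n2001-01-01T00:00:00,10\nnot-a-date,11\n"
        )
        with pytest.raises(ParseError, match="line 3"):
            weather.read_hourly_csv(p)

    def test_non_numeric_temperature_names_line(self, tmp_path):
        p = _write(tmp_path, "timestamp,temp_c\n2001-01-01T00:00:00,warm\n")
        with pytest.raises(ParseError, match="line 2"):
            weather.read_hourly_csv(p)

    def test_empty_file_raises(self, tmp_path):
        p = _write(tmp_path, "timestamp,temp_c\n")
        with pytest.raises(EmptyInputError):
            weather.read_hourly_csv(p)


class TestRemoveOutliers:
    def test_gross_spike_removed(self):
        times = pd.date_range("2001-01-01", periods=100, freq="h")
        temps = np.full(100, 20.0)
        temps[50] = 55.0
        out = weather.remove_outliers(make_raw(times, temps), 24, 10.0)
        assert len(out) == 99
        assert np.all(out.temps == 20.0)

    def test_clean_series_unchanged(self):
        times = pd.date_range("2001-01-01", periods=100, freq="h")
        out = weather.remove_outliers(make_raw(times, np.full(100, 20.0)), 24, 10.0)
        assert len(out) == 100

    def test_tiny_series_warns_and_passes_through(self):
        times = pd.date_range("2001-01-01", periods=2, freq="h")
        raw = make_raw(times, [5.0, 6.0])
        with pytest.warns(UserWarning):
            out = weather.remove_outliers(raw)
        assert len(out) == 2

    def test_injected_spikes_all_removed_no_false_positives(self):
        # sinusoidal year (no snaps) with ~50 injected gross spikes
        params = SyntheticClimateParams(seed=42, defect_outlier_rate=50.0,
                                        noise_sigma=1.5, coldsnap_rate=0.0)
        sw = weather.generate_synthetic_weather(params, 1)
        assert len(sw.log.outliers) >= 30  # Poisson(50), sanity
        cleaned = weather.remove_outliers(sw.raw)
        removed = set(sw.raw.times) - set(cleaned.times)
        injected = {t for t, _, _ in sw.log.outliers}
        assert removed == injected


class TestResampleAndFill:
    def _hourly_raw(self, temps, start="2001-01-01", drop=()):
        times = pd.date_range(start, periods=len(temps), freq="h")
        keep = np.ones(len(temps), bool)
        keep[list(drop)] = False
        return make_raw(times[keep], np.asarray(temps, float)[keep])

    def test_small_gap_midpoint(self):
        temps = np.full(72, 10.0)
        temps[31] = 12.0  # neighbours of dropped hour 30: 10 and 12
        temps[29] = 10.0
        raw = self._hourly_raw(temps, drop=[30])
        out = weather.resample_and_fill(raw)
        assert out.temps[30] == pytest.approx((temps[29] + temps[31]) / 2)
        assert out.fill_flag[30] == INTERP_SMALL_GAP
        assert out.fill_flag[29] == OBSERVED

    def test_day_over_day_midpoint_across_days(self):
        # 5 days hourly; drop a 30 h block so hour 14 of day 2 must be filled
        # from hour 14 of days 1 and 3 (20 and 24 C)
        temps = np.full(120, 15.0)
        temps[38] = 20.0  # day 1, hour 14
        temps[62] = 99.0  # day 2, hour 14: inside the dropped block
        temps[86] = 24.0  # day 3, hour 14
        raw = self._hourly_raw(temps, drop=range(48, 78))
        out = weather.resample_and_fill(raw)
        assert out.fill_flag[62] == INTERP_DAY_OVER_DAY
        assert out.temps[62] == pytest.approx((20.0 + 24.0) / 2)

    def test_boundary_gap_is_error(self):
        temps = np.full(120, 15.0)
        # drop hours 1..30 but keep hour 0: the large gap has no earlier
        # day carrying those hours of day, so it cannot be bracketed
        raw = self._hourly_raw(temps, drop=range(1, 31))
        with pytest.raises(UnfillableGapError):
            weather.resample_and_fill(raw)

    def test_injected_gap_matches_independent_fill(self):
        params = SyntheticClimateParams(seed=7, defect_gap_rate=4.0,
                                        defect_gap_hours=12)
        sw = weather.generate_synthetic_weather(params, 1)
        assert sw.log.gaps
        out = weather.resample_and_fill(sw.raw)
        # independent oracle: per hour-of-day linear interpolation over days
        truth = sw.series
        for g0, g1 in sw.log.gaps:
            for t in pd.date_range(g0, g1, freq="h"):
                i = int((t - out.start) / pd.Timedelta(hours=1))
                assert out.fill_flag[i] == INTERP_DAY_OVER_DAY
                prev_t = t - pd.Timedelta(days=1)
                next_t = t + pd.Timedelta(days=1)
                # neighbours may themselves be in a gap; only check clean brackets
                in_gap = lambda x: any(a <= x <= b for a, b in sw.log.gaps)
                if not in_gap(prev_t) and not in_gap(next_t):
                    ip = int((prev_t - truth.start) / pd.Timedelta(hours=1))
                    inx = int((next_t - truth.start) / pd.Timedelta(hours=1))
                    expect = (truth.temps[ip] + truth.temps[inx]) / 2
                    assert out.temps[i] == pytest.approx(expect, abs=1e-9)

    def test_idempotent_on_own_output(self, synthetic_two_years):
        s = synthetic_two_years
        raw = make_raw(s.times, s.temps)
        once = weather.resample_and_fill(raw)
        twice = weather.resample_and_fill(make_raw(once.times, once.temps))
        assert once.start == twice.start
        np.testing.assert_array_equal(once.temps, twice.temps)
        assert np.all(once.fill_flag == OBSERVED)
        assert np.all(twice.fill_flag == OBSERVED)


class TestDailyExtremes:
    def test_constant_day(self):
        s = make_constant_series(15.0, 1)
        (d,) = weather.daily_extremes(s)
        assert (d.tmin, d.tmax) == (15.0, 15.0)

    def test_ramp_day(self):
        s = make_constant_series(0.0, 1)
        s.temps[:] = np.arange(24.0)
        (d,) = weather.daily_extremes(s)
        assert (d.tmin, d.tmax) == (0.0, 23.0)

    def test_partial_boundary_days_excluded(self):
        n = 24 * 3
        s = weather.HourlyTemperatureSeries(
            start=pd.Timestamp("2001-01-01 05:00"),
            temps=np.full(n, 10.0),
            fill_flag=np.zeros(n, np.int8),
        )
        days = weather.daily_extremes(s)
        assert len(days) == 2  # Jan 2 and Jan 3 complete; Jan 1 and 4 partial

    def test_sinusoidal_day_matches_closed_form(self):
        hours = np.arange(24.0)
        temps = 20.0 + 5.0 * np.cos(2 * np.pi * (hours - 15) / 24.0)
        s = make_constant_series(0.0, 1)
        s.temps[:] = temps
        (d,) = weather.daily_extremes(s)
        assert d.tmax == pytest.approx(25.0, abs=0.2)
        assert d.tmin == pytest.approx(15.0, abs=0.2)


class TestSyntheticWeather:
    def test_all_flat_gives_constant_series(self):
        p = SyntheticClimateParams(
            annual_amplitude=0, diurnal_amplitude=0, noise_sigma=0,
            coldsnap_rate=0, seed=1,
        )
        sw = weather.generate_synthetic_weather(p, 1)
        np.testing.assert_allclose(sw.series.temps, p.annual_mean)

    def test_same_seed_identical(self, mid_latitude_params):
        a = weather.generate_synthetic_weather(mid_latitude_params, 1)
        b = weather.generate_synthetic_weather(mid_latitude_params, 1)
        np.testing.assert_array_equal(a.series.temps, b.series.temps)

    def test_defect_free_cleaning_is_identity(self, mid_latitude_params):
        # snap-free: a cold snap deeper than the outlier threshold minus the
        # diurnal offset is indistinguishable from a sensor spike by design
        from dataclasses import replace

        s = weather.generate_synthetic_weather(
            replace(mid_latitude_params, coldsnap_rate=0.0), 2
        ).series
        raw = make_raw(s.times, s.temps)
        cleaned = weather.resample_and_fill(weather.remove_outliers(raw))
        np.testing.assert_array_equal(cleaned.temps, s.temps)
        assert np.all(cleaned.fill_flag == OBSERVED)

    def test_day_of_year_mean_matches_generating_sinusoid(self):
        p = SyntheticClimateParams(
            annual_mean=18.0, annual_amplitude=8.0, coldsnap_rate=0.0, seed=11
        )
        sw = weather.generate_synthetic_weather(p, 30)
        s = sw.series
        df = pd.Series(s.temps, index=s.times)
        daily = df.resample("D").mean()
        doy_mean = daily.groupby(daily.index.dayofyear).mean()
        doy = doy_mean.index.to_numpy(float)
        expect = p.annual_mean + p.annual_amplitude * np.cos(
            2 * np.pi * (doy - p.annual_phase) / 365.25
        )
        # se of a 30-year day mean of AR(1) noise; daily averaging leaves
        # roughly sigma * sqrt((1+rho)/(24(1-rho))) per day
        se_day = p.noise_sigma * np.sqrt((1 + p.noise_rho) / (24 * (1 - p.noise_rho)))
        se = se_day / np.sqrt(30)
        resid = doy_mean.to_numpy() - expect
        assert np.abs(resid).max() < 5 * se  # 366 comparisons; allow wide tail
        assert np.abs(resid.mean()) < 3 * se / np.sqrt(366 / 10)


class TestInjectColdSnap:
    def test_floor_applied(self):
        s = make_constant_series(20.0, 3)
        out = weather.inject_cold_snap(s, "2001-01-02 00:00", 6, 0.0)
        i = 24
        assert np.all(out.temps[i : i + 6] == 0.0)
        assert np.all(out.temps[:i] == 20.0)
        assert np.all(out.temps[i + 6 :] == 20.0)

    def test_floor_above_series_is_noop(self):
        s = make_constant_series(20.0, 2)
        out = weather.inject_cold_snap(s, "2001-01-01 03:00", 6, 30.0)
        np.testing.assert_array_equal(out.temps, s.temps)

    def test_out_of_range_window(self):
        s = make_constant_series(20.0, 2)
        with pytest.raises(IndexError):
            weather.inject_cold_snap(s, "2001-01-02 20:00", 12, 0.0)

    def test_snap_visible_in_daily_extremes(self):
        s = make_constant_series(20.0, 4)
        out = weather.inject_cold_snap(s, "2001-01-02 00:00", 48, -5.0)
        days = weather.daily_extremes(out)
        assert days[1].tmin == -5.0
        assert days[2].tmin == -5.0
        assert days[0].tmin == 20.0


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    st.integers(min_value=0, max_value=2**31 - 1),
    st.floats(min_value=-5, max_value=30),
    st.floats(min_value=0, max_value=12),
)
def test_generator_invariants(seed, mean, amp):
    """Every generated hour is finite, hourly-aligned, flagged exactly once."""
    p = SyntheticClimateParams(annual_mean=mean, annual_amplitude=amp, seed=seed)
    sw = weather.generate_synthetic_weather(p, 1)
    s = sw.series
    assert np.all(np.isfinite(s.temps))
    assert len(s.fill_flag) == len(s.temps)
    assert np.all(s.fill_flag == OBSERVED)
    assert (s.times[1] - s.times[0]) == pd.Timedelta(hours=1)
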
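"""Hourly air-temperature series: ingestion, cleaning, and synthesis.

Quarantine-length models for *Ceratitis capitata* (Medfly) are driven by long
hourly temperature records.  This module provides the plumbing around them:

* a simple CSV dialect for hourly observations (``timestamp,temp_c,fill_flag``),
* cleaning — outlier removal, gap identification, resampling to every hour on
  the hour, and day-over-day filling of large gaps,
* daily tmin/tmax extraction for the single-sine degree-day model, and
* a synthetic-climate generator (annual + diurnal sinusoids, AR(1) weather
  noise, rare brief cold snaps, optional injected data defects) so the whole
  pipeline can run without station downloads.

Timestamps are treated as local standard time with no daylight-saving
transitions; the calendar day is the aggregation unit throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "SiteMeta",
    "RawObservationSeries",
    "HourlyTemperatureSeries",
    "SyntheticClimateParams",
    "DailyExtremes",
    "InjectionLog",
    "SyntheticWeather",
    "ParseError",
    "EmptyInputError",
    "UnfillableGapError",
    "OBSERVED",
    "INTERP_SMALL_GAP",
    "INTERP_DAY_OVER_DAY",
    "FLAG_NAMES",
    "read_hourly_csv",
    "write_hourly_csv",
    "remove_outliers",
    "resample_and_fill",
    "daily_extremes",
    "generate_synthetic_weather",
    "inject_cold_snap",
]

# fill_flag provenance codes (stored as int8, serialised as names)
OBSERVED = 0
INTERP_SMALL_GAP = 1
INTERP_DAY_OVER_DAY = 2
FLAG_NAMES = ("observed", "interpolated_small_gap", "interpolated_day_over_day")
_FLAG_CODES = {name: code for code, name in enumerate(FLAG_NAMES)}

_HOUR = np.timedelta64(1, "h")


class ParseError(ValueError):
    """A CSV row could not be parsed; the message names the 1-based line."""


class EmptyInputError(ValueError):
    """The input file contains no observations."""


class UnfillableGapError(ValueError):
    """A large gap touches the series boundary and cannot be bracketed."""


@dataclass(frozen=True)
class SiteMeta:
    """Weather-station metadata (callsign, position, record start year)."""

    callsign: str
    name: str = ""
    latitude: float = float("nan")
    longitude: float = float("nan")
    elevation: float = float("nan")
    start_year: int | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.latitude) and not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if np.isfinite(self.longitude) and not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")


@dataclass
class RawObservationSeries:
    """Possibly irregular, possibly dirty timestamped temperature records."""

    times: pd.DatetimeIndex
    temps: np.ndarray
    site: SiteMeta | None = None

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.temps = np.asarray(self.temps, dtype=float)
        if len(self.times) != len(self.temps):
            raise ValueError("times and temps must have equal length")
        if not self.times.is_monotonic_increasing:
            order = np.argsort(self.times.values, kind="stable")
            self.times = self.times[order]
            self.temps = self.temps[order]

    def __len__(self) -> int:
        return len(self.temps)


@dataclass
class HourlyTemperatureSeries:
    """Gap-free hourly-aligned temperatures with per-hour fill provenance.

    ``temps[i]`` is the temperature at ``start + i`` hours; ``fill_flag[i]``
    records whether that value was observed or interpolated (and how).
    """

    start: pd.Timestamp
    temps: np.ndarray
    fill_flag: np.ndarray
    site: SiteMeta | None = None

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        if self.start != self.start.floor("h"):
            raise ValueError("start must be on the hour")
        self.temps = np.asarray(self.temps, dtype=float)
        self.fill_flag = np.asarray(self.fill_flag, dtype=np.int8)
        if self.fill_flag.shape != self.temps.shape:
            raise ValueError("fill_flag length must equal temps length")
        if not np.all(np.isfinite(self.temps)):
            raise ValueError("temps must be finite")

    def __len__(self) -> int:
        return len(self.temps)

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=len(self.temps), freq="h")

    @property
    def end(self) -> pd.Timestamp:
        return self.start + pd.Timedelta(hours=len(self.temps) - 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.times,
                "temp_c": self.temps,
                "fill_flag": np.asarray(FLAG_NAMES)[self.fill_flag],
            }
        )

    def day_matrix(self) -> tuple[pd.DatetimeIndex, np.ndarray]:
        """Return (dates, hours) for all complete calendar days.

        ``hours`` has shape (n_days, 24); partial boundary days are dropped.
        """
        first = self.start.ceil("D")
        offset = int((first - self.start) / pd.Timedelta(hours=1))
        n_days = (len(self.temps) - offset) // 24
        if n_days < 1:
            raise ValueError("series does not cover one full calendar day")
        mat = self.temps[offset : offset + 24 * n_days].reshape(n_days, 24)
        dates = pd.date_range(first, periods=n_days, freq="D")
        return dates, mat

    def slice_hours(self, t0: pd.Timestamp, n_hours: int) -> np.ndarray:
        i = int((pd.Timestamp(t0) - self.start) / pd.Timedelta(hours=1))
        if i < 0 or i + n_hours > len(self.temps):
            raise IndexError("requested window outside series")
        return self.temps[i : i + n_hours]


@dataclass(frozen=True)
class SyntheticClimateParams:
    """Controls for the synthetic hourly climate generator.

    The generator is a stylised mid-latitude station: an annual sinusoid
    (``annual_mean`` ± ``annual_amplitude``, warmest on day-of-year
    ``annual_phase``), a diurnal sinusoid peaking at hour ``diurnal_phase``,
    stationary AR(1) noise (marginal sd ``noise_sigma``, hour-to-hour
    correlation ``noise_rho``), Poisson-count cold snaps each subtracting
    ``coldsnap_depth`` °C for ``coldsnap_duration`` hours, and optional data
    defects (gross outliers and record gaps) for exercising the cleaner.
    """

    annual_mean: float = 17.0
    annual_amplitude: float = 8.0
    annual_phase: float = 197.0  # day of year of warmest day (~mid July)
    diurnal_amplitude: float = 5.0
    diurnal_phase: float = 15.0  # hour of daily maximum
    noise_sigma: float = 2.0
    noise_rho: float = 0.95
    coldsnap_rate: float = 3.0  # events / year
    coldsnap_duration: int = 6  # hours
    coldsnap_depth: float = 12.0  # °C below the seasonal curve
    defect_outlier_rate: float = 0.0  # injected spikes / year
    defect_gap_rate: float = 0.0  # injected gaps / year
    defect_gap_hours: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.annual_amplitude < 0 or self.diurnal_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if not 0.0 <= self.noise_rho < 1.0:
            raise ValueError("noise_rho must be in [0, 1)")
        for name in ("coldsnap_rate", "defect_outlier_rate", "defect_gap_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class DailyExtremes:
    """Daily minimum/maximum temperature pair for one calendar date."""

    date: pd.Timestamp
    tmin: float
    tmax: float

    def __post_init__(self) -> None:
        if self.tmin > self.tmax:
            raise ValueError("tmin must be <= tmax")


@dataclass
class InjectionLog:
    """Ground truth for defects injected into a synthetic series."""

    outliers: list[tuple[pd.Timestamp, float, float]] = field(default_factory=list)
    gaps: list[tuple[pd.Timestamp, pd.Timestamp]] = field(default_factory=list)
    cold_snaps: list[tuple[pd.Timestamp, pd.Timestamp, float]] = field(default_factory=list)


@dataclass
class SyntheticWeather:
    """Generator output: clean truth, (optionally) corrupted raw, and log."""

    series: HourlyTemperatureSeries
    raw: RawObservationSeries
    log: InjectionLog


# ---------------------------------------------------------------------------
# Ingestion
# ---------------------------------------------------------------------------

def read_hourly_csv(path, site: SiteMeta | None = None) -> RawObservationSeries:
    """Read the hourly-temperature CSV dialect into a raw series.

    Records are sorted by timestamp.  Exact duplicate rows collapse to one;
    conflicting duplicates (same timestamp, different temperature) resolve to
    their mean.  Malformed rows raise :class:`ParseError` naming the 1-based
    file line; a file with no data rows raises :class:`EmptyInputError`.
    """
    df = pd.read_csv(path, dtype=str, skip_blank_lines=False)
    if "timestamp" not in df.columns or "temp_c" not in df.columns:
        raise ParseError(f"{path}: header must contain 'timestamp' and 'temp_c'")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no observations")
    times = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    temps = pd.to_numeric(df["temp_c"], errors="coerce")
    bad_t = np.flatnonzero(times.isna().to_numpy())
    if bad_t.size:
        raise ParseError(f"{path}: malformed timestamp on line {bad_t[0] + 2}")
    bad_v = np.flatnonzero(temps.isna().to_numpy())
    if bad_v.size:
        raise ParseError(f"{path}: non-numeric temperature on line {bad_v[0] + 2}")
    g = pd.Series(temps.to_numpy(), index=pd.DatetimeIndex(times)).groupby(level=0).mean()
    return RawObservationSeries(times=g.index, temps=g.to_numpy(), site=site)


def write_hourly_csv(series: HourlyTemperatureSeries, path) -> None:
    """Write a cleaned series in the CSV dialect (fill_flag always present)."""
    df = series.to_frame()
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False, float_format="%.4f")


def read_hourly_series_csv(path, site: SiteMeta | None = None) -> HourlyTemperatureSeries:
    """Read a cleaned hourly CSV (as written by :func:`write_hourly_csv`)."""
    df = pd.read_csv(path)
    times = pd.DatetimeIndex(pd.to_datetime(df["timestamp"], format="ISO8601"))
    if "fill_flag" in df.columns:
        flags = np.array([_FLAG_CODES[f] for f in df["fill_flag"]], dtype=np.int8)
    else:
        flags = np.zeros(len(df), dtype=np.int8)
    step = np.diff(times.values)
    if len(step) and not np.all(step == _HOUR):
        raise ParseError(f"{path}: timestamps are not consecutive hours")
    return HourlyTemperatureSeries(
        start=times[0], temps=df["temp_c"].to_numpy(float), fill_flag=flags, site=site
    )


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------

def remove_outliers(
    raw: RawObservationSeries, window_hours: int = 24, threshold_c: float = 15.0
) -> RawObservationSeries:
    """Drop records deviating from a centred rolling median by > threshold.

    The median is taken over all records within ±``window_hours`` of each
    record.  The rule is deliberately parameter-light and robust: an isolated
    sensor spike moves the local median very little, while a multi-day heat
    wave moves it along with the data and is retained.
    """
    if window_hours < 3:
        raise ValueError("window_hours must be >= 3")
    if threshold_c <= 0:
        raise ValueError("threshold_c must be > 0")
    if len(raw) < 3:
        warnings.warn("fewer than 3 records; outlier pass skipped", stacklevel=2)
        return raw
    s = pd.Series(raw.temps, index=raw.times)
    med = s.rolling(f"{2 * window_hours + 1}h", center=True, min_periods=1).median()
    keep = (s - med).abs().to_numpy() <= threshold_c
    return RawObservationSeries(times=raw.times[keep], temps=raw.temps[keep], site=raw.site)


def resample_and_fill(
    raw: RawObservationSeries, large_gap_hours: int = 3
) -> HourlyTemperatureSeries:
    """Resample to every hour on the hour; fill small and large gaps.

    Grid hours bracketed by observations at most ``large_gap_hours`` apart are
    linearly interpolated in time (``interpolated_small_gap``; hours landing
    exactly on an observation are ``observed``).  Hours inside larger gaps are
    filled day-over-day: for the same hour of day, linear interpolation
    between the nearest earlier and later days carrying an observed or
    small-gap value at that hour.  A large gap with no bracketing day on one
    side raises :class:`UnfillableGapError`.
    """
    if len(raw) < 2:
        raise ValueError("need at least 2 observations")
    t = raw.times.values.astype("datetime64[s]")
    if (raw.times[-1] - raw.times[0]) < pd.Timedelta(hours=48):
        raise ValueError("raw series must span at least 48 h")

    t_sec = t.astype("int64")
    start = int(np.ceil(t_sec[0] / 3600.0)) * 3600
    end = int(np.floor(t_sec[-1] / 3600.0)) * 3600
    grid = np.arange(start, end + 1, 3600, dtype="int64")
    temps = np.interp(grid, t_sec, raw.temps)

    # classify every grid hour by its bracketing observation gap
    idx = np.searchsorted(t_sec, grid, side="left")
    exact = t_sec[np.minimum(idx, len(t_sec) - 1)] == grid
    prev_i = np.where(exact, idx, idx - 1)
    next_i = np.where(exact, idx, np.minimum(idx, len(t_sec) - 1))
    gap_sec = t_sec[next_i] - t_sec[prev_i]
    flags = np.where(exact, OBSERVED, INTERP_SMALL_GAP).astype(np.int8)
    large = ~exact & (gap_sec > large_gap_hours * 3600)
    flags[large] = INTERP_DAY_OVER_DAY

    if large.any():
        temps = temps.copy()
        temps[large] = np.nan
        hod = (grid // 3600) % 24
        day = grid // 86400
        for h in range(24):
            col = np.flatnonzero(hod == h)
            if col.size == 0:
                continue
            vals = temps[col]
            known = ~np.isnan(vals)
            missing = ~known
            if not missing.any():
                continue
            if not known.any() or missing[0] or missing[-1]:
                bad = col[missing]
                t0 = pd.Timestamp(grid[bad[0]], unit="s")
                t1 = pd.Timestamp(grid[bad[-1]], unit="s")
                raise UnfillableGapError(
                    f"large gap touching series boundary cannot be filled "
                    f"(hour-of-day {h:02d}, {t0} .. {t1})"
                )
            d = day[col].astype(float)
            temps[col[missing]] = np.interp(d[missing], d[known], vals[known])

    return HourlyTemperatureSeries(
        start=pd.Timestamp(grid[0], unit="s"), temps=temps, fill_flag=flags, site=raw.site
    )


def daily_extremes(series: HourlyTemperatureSeries) -> list[DailyExtremes]:
    """Per-complete-calendar-day tmin/tmax (partial boundary days excluded)."""
    dates, mat = series.day_matrix()
    return [
        DailyExtremes(date=d, tmin=float(row.min()), tmax=float(row.max()))
        for d, row in zip(dates, mat)
    ]


# ---------------------------------------------------------------------------
# Synthesis
# ---------------------------------------------------------------------------

def _seasonal_curve(times: pd.DatetimeIndex, p: SyntheticClimateParams) -> np.ndarray:
    frac_doy = times.dayofyear.to_numpy() + times.hour.to_numpy() / 24.0
    annual = p.annual_mean + p.annual_amplitude * np.cos(
        2.0 * np.pi * (frac_doy - p.annual_phase) / 365.25
    )
    diurnal = p.diurnal_amplitude * np.cos(
        2.0 * np.pi * (times.hour.to_numpy() - p.diurnal_phase) / 24.0
    )
    return annual + diurnal


def generate_synthetic_weather(
    params: SyntheticClimateParams,
    n_years: int,
    start: str | pd.Timestamp = "2000-01-01",
) -> SyntheticWeather:
    """Generate ``n_years`` calendar years of synthetic hourly temperatures.

    Returns the clean truth series, a raw series with any requested defects
    applied (identical to the truth when defect rates are zero), and an
    injection log recording every outlier, gap, and cold snap, so cleaning
    stages can be validated against known ground truth.  Output is fully
    reproducible for a given ``params.seed``.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(params.seed)
    start = pd.Timestamp(start)
    times = pd.date_range(
        start, start + pd.DateOffset(years=n_years), freq="h", inclusive="left"
    )
    n = len(times)
    temps = _seasonal_curve(times, params)

    if params.noise_sigma > 0:
        innov = rng.standard_normal(n) * params.noise_sigma * np.sqrt(
            1.0 - params.noise_rho**2
        )
        innov[0] = rng.standard_normal() * params.noise_sigma
        temps = temps + lfilter([1.0], [1.0, -params.noise_rho], innov)

    log = InjectionLog()
    n_snaps = rng.poisson(params.coldsnap_rate * n_years)
    dur = max(int(params.coldsnap_duration), 1)
    for _ in range(n_snaps):
        i = int(rng.integers(0, max(n - dur, 1)))
        temps[i : i + dur] -= params.coldsnap_depth
        log.cold_snaps.append((times[i], times[min(i + dur, n) - 1], params.coldsnap_depth))

    series = HourlyTemperatureSeries(
        start=start, temps=temps, fill_flag=np.zeros(n, dtype=np.int8)
    )

    raw_temps = temps.copy()
    keep = np.ones(n, dtype=bool)
    n_out = rng.poisson(params.defect_outlier_rate * n_years)
    if n_out:
        pos = rng.choice(n, size=min(n_out, n), replace=False)
        # offsets well past the outlier threshold + diurnal spread, so an
        # injected defect is a gross spike by construction
        mag = rng.uniform(25.0, 40.0, size=len(pos))
        sign = rng.choice([-1.0, 1.0], size=len(pos))
        for j, i in enumerate(pos):
            corrupted = raw_temps[i] + sign[j] * mag[j]
            log.outliers.append((times[i], float(raw_temps[i]), float(corrupted)))
            raw_temps[i] = corrupted
    n_gaps = rng.poisson(params.defect_gap_rate * n_years)
    gap_h = max(int(params.defect_gap_hours), 1)
    for _ in range(n_gaps):
        # keep gaps away from the boundary days so day-over-day fill can bracket
        i = int(rng.integers(48, max(n - gap_h - 48, 49)))
        keep[i : i + gap_h] = False
        log.gaps.append((times[i], times[i + gap_h - 1]))

    raw = RawObservationSeries(times=times[keep], temps=raw_temps[keep])
    return SyntheticWeather(series=series, raw=raw, log=log)


def inject_cold_snap(
    series: HourlyTemperatureSeries,
    start: str | pd.Timestamp,
    duration_h: int,
    floor_c: float,
) -> HourlyTemperatureSeries:
    """Clamp a window to at most ``floor_c``: temps become min(orig, floor)."""
    start = pd.Timestamp(start)
    i = int((start - series.start) / pd.Timedelta(hours=1))
    if i < 0 or i + duration_h > len(series) or duration_h < 1:
        raise IndexError("cold-snap window outside series")
    temps = series.temps.copy()
    temps[i : i + duration_h] = np.minimum(temps[i : i + duration_h], floor_c)
    return replace(series, temps=temps, fill_flag=series.fill_flag.copy())
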
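"""Degree-day accumulation and degree-day predicted quarantine length.

Regulatory Medfly quarantines are extended past the last fly detection by the
time needed for three generations of thermal development: 345.56 Celsius
degree-days (DDc) per generation above a base of 12.39 °C.  Daily degree-days
are computed by the single-sine method — the day's temperature is assumed to
follow a sinusoid between tmin and tmax, and the area above the base
threshold is evaluated in closed form:

    m = (tmin + tmax)/2,  a = (tmax - tmin)/2
    DD = 0                                  if tmax <= base
       = m - base                           if tmin >= base
       = [ (m-base)(pi/2 - theta) + a cos(theta) ] / pi   otherwise,
         theta = arcsin((base - m)/a)

Since gap-free hourly series are available, simple hourly summation
(sum of max(T_h - base, 0)/24) is provided as a comparator.

The degree-day predicted quarantine length (DD PQL) for a start date is the
smallest whole number of days whose accumulated degree-days reach
``n_generations * dd_per_generation``; the start date's own degree-days count
as day 1.  A series that ends before the threshold is reached yields a
censored record carrying the partial accumulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .weather import DailyExtremes, HourlyTemperatureSeries

__all__ = [
    "DegreeDayModel",
    "PQLRecord",
    "single_sine_dd",
    "hourly_sum_dd",
    "daily_dd_from_series",
    "dd_pql",
    "dd_pql_series",
    "pql_records_to_frame",
]

SINGLE_SINE = "single_sine"
HOURLY_SUM = "hourly_sum"


@dataclass(frozen=True)
class DegreeDayModel:
    """Degree-day accumulation model (base temperature and thresholds).

    Defaults follow the regulatory standard for Medfly quarantines:
    base 12.39 °C, 345.56 DDc per generation, 3 generations.  An optional
    upper developmental cutoff hook exists but defaults off (the standard
    specifies only the base).
    """

    base_temp: float = 12.39
    dd_per_generation: float = 345.56
    n_generations: int = 3
    method: str = SINGLE_SINE
    upper_cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.dd_per_generation <= 0:
            raise ValueError("dd_per_generation must be > 0")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.method not in (SINGLE_SINE, HOURLY_SUM):
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def threshold(self) -> float:
        return self.n_generations * self.dd_per_generation


@dataclass(frozen=True)
class PQLRecord:
    """Predicted quarantine length for one start date.

    ``pql_days`` is None when censored (series ended before the threshold);
    ``accumulated`` then carries the partial degree-day sum so callers can
    distinguish "nearly done" from "cold-dead" series.
    """

    start_date: pd.Timestamp
    method: str
    pql_days: int | None
    censored: bool = False
    accumulated: float | None = None

    def __post_init__(self) -> None:
        if not self.censored and (self.pql_days is None or self.pql_days < 1):
            raise ValueError("pql_days must be >= 1 when not censored")


def single_sine_dd(day, base: float = 12.39, upper_cutoff: float | None = None):
    """Single-sine degree-days for one day (or vectorised tmin/tmax arrays).

    Accepts a :class:`DailyExtremes` or a ``(tmin, tmax)`` pair of scalars or
    arrays.  The optional horizontal upper cutoff caps the sinusoid at
    ``upper_cutoff`` before integration (off by default).
    """
    if isinstance(day, DailyExtremes):
        tmin, tmax = day.tmin, day.tmax
    else:
        tmin, tmax = day
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(tmin > tmax):
        raise ValueError("tmin must be <= tmax")
    dd = _sine_area_above(tmin, tmax, base)
    if upper_cutoff is not None:
        dd = dd - _sine_area_above(tmin, tmax, upper_cutoff)
    if dd.ndim == 0:
        return float(dd)
    return dd


def _sine_area_above(tmin, tmax, thresh: float) -> np.ndarray:
    m = (tmin + tmax) / 2.0
    a = (tmax - tmin) / 2.0
    below = tmax <= thresh
    above = tmin >= thresh
    mid = ~below & ~above
    out = np.where(above, m - thresh, 0.0)
    if np.any(mid):
        a_mid = np.where(mid, a, 1.0)  # avoid 0-division off-branch
        ratio = np.clip((thresh - m) / a_mid, -1.0, 1.0)
        theta = np.arcsin(ratio)
        val = ((m - thresh) * (np.pi / 2.0 - theta) + a_mid * np.cos(theta)) / np.pi
        out = np.where(mid, val, out)
    return np.maximum(out, 0.0)


def hourly_sum_dd(hours, base: float = 12.39) -> float:
    """Simple-summation degree-days for one day of 24 hourly temperatures."""
    hours = np.asarray(hours, dtype=float)
    if hours.shape != (24,):
        raise ValueError(f"expected exactly 24 hourly values, got shape {hours.shape}")
    return float(np.clip(hours - base, 0.0, None).sum() / 24.0)


def daily_dd_from_series(
    series: HourlyTemperatureSeries, model: DegreeDayModel
) -> tuple[pd.DatetimeIndex, np.ndarray]:
    """Daily degree-day values for all complete calendar days of a series."""
    dates, mat = series.day_matrix()
    if model.method == SINGLE_SINE:
        dd = single_sine_dd(
            (mat.min(axis=1), mat.max(axis=1)), model.base_temp, model.upper_cutoff
        )
    else:
        dd = np.clip(mat - model.base_temp, 0.0, None).sum(axis=1) / 24.0
    return dates, np.asarray(dd, dtype=float)


def dd_pql(daily_dd, model: DegreeDayModel, start_date=None) -> PQLRecord:
    """PQL from an ordered daily degree-day sequence beginning on the start date.

    Returns the smallest ``d >= 1`` with ``sum(daily_dd[:d]) >= threshold``,
    censored (with the partial accumulation) if the sequence ends first.
    """
    daily_dd = np.asarray(daily_dd, dtype=float)
    if daily_dd.size == 0:
        raise ValueError("daily_dd is empty")
    cs = np.cumsum(daily_dd)
    thr = model.threshold
    j = int(np.searchsorted(cs, thr, side="left"))
    start_date = pd.Timestamp(start_date) if start_date is not None else pd.NaT
    if j >= len(cs):
        return PQLRecord(start_date, model.method, None, censored=True,
                         accumulated=float(cs[-1]))
    return PQLRecord(start_date, model.method, max(j + 1, 1),
                     accumulated=float(cs[j]))


def dd_pql_series(
    series: HourlyTemperatureSeries,
    model: DegreeDayModel,
    every_days: int = 1,
) -> list[PQLRecord]:
    """PQL for every start date at the requested spacing.

    Uses a cumulative-sum scan so the whole multi-decade sweep is a single
    vectorised pass.  Start dates whose accumulation would run past the end
    of the data yield censored records — values are never fabricated.
    """
    if every_days < 1:
        raise ValueError("every_days must be >= 1")
    dates, dd = daily_dd_from_series(series, model)
    cs = np.concatenate([[0.0], np.cumsum(dd)])
    thr = model.threshold
    starts = np.arange(0, len(dd), every_days)
    ends = np.searchsorted(cs, cs[starts] + thr, side="left")
    records: list[PQLRecord] = []
    for i, j in zip(starts, ends):
        if j > len(dd):
            records.append(
                PQLRecord(dates[i], model.method, None, censored=True,
                          accumulated=float(cs[-1] - cs[i]))
            )
        else:
            records.append(
                PQLRecord(dates[i], model.method, int(j - i),
                          accumulated=float(cs[j] - cs[i]))
            )
    return records


def pql_records_to_frame(records) -> pd.DataFrame:
    """PQL records as a DataFrame in the output CSV dialect column order."""
    return pd.DataFrame(
        {
            "start_date": [r.start_date.strftime("%Y-%m-%d") for r in records],
            "method": [r.method for r in records],
            "pql_days": [("" if r.censored else r.pql_days) for r in records],
            "censored": [int(r.censored) for r in records],
        }
    )
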
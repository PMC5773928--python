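"""Day-of-year normals and the statistical comparisons built on them.

A 'normal' here is the meteorological notion — all values for the same
calendar day irrespective of year (e.g. every 20-July) aggregated into
summary statistics — deliberately without the usual running-mean smoothing.
Built on those normals:

* ``normal_r2`` — the fraction of a series' variance captured by the mean of
  its day-of-year normal (how far the seasonal cycle alone predicts PQL),
* ``latitude_ols`` — OLS of per-site median PQL on latitude,
* ``nearest_site`` — great-circle matching of an outbreak location to the
  closest analysed station, and
* ``paired_comparison`` — the paired t-test and deviation-variance F-test
  contrasting degree-day against agent-based quarantine lengths for a set of
  historical outbreak start dates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .weather import SiteMeta

__all__ = [
    "DayOfYearNormal",
    "LatitudeFit",
    "PairedComparison",
    "HistoricalQuarantine",
    "compute_normals",
    "normals_to_frame",
    "normal_r2",
    "latitude_ols",
    "haversine_km",
    "nearest_site",
    "paired_comparison",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class DayOfYearNormal:
    """Summary statistics for one (month, day) across years."""

    month: int
    day: int
    n: int
    mean: float
    min: float
    max: float
    std: float
    q25: float
    median: float
    q75: float


@dataclass(frozen=True)
class LatitudeFit:
    """OLS of per-site median PQL on latitude (days per degree north)."""

    slope: float
    intercept: float
    F: float
    p: float
    n_sites: int


@dataclass(frozen=True)
class PairedComparison:
    """DD-vs-ABS paired contrast for matched start dates."""

    n: int
    mean_a: float
    mean_b: float
    std_a: float
    std_b: float
    t: float
    df: int
    p: float
    dev_std_a: float
    dev_std_b: float
    F: float
    F_p: float


@dataclass(frozen=True)
class HistoricalQuarantine:
    """A historical outbreak: start date, location, matched station."""

    start_date: pd.Timestamp
    latitude: float
    longitude: float
    matched_callsign: str | None = None

    def __post_init__(self) -> None:
        if not (-90.0 <= self.latitude <= 90.0 and -180.0 <= self.longitude <= 180.0):
            raise ValueError("invalid coordinates")


def compute_normals(dates, values, ddof: int = 0) -> pd.DataFrame:
    """Group values by calendar (month, day) across years — no smoothing.

    Returns a DataFrame indexed by (month, day) with columns
    ``n, mean, min, max, std, q25, median, q75``.  ``std`` is the population
    (divisor n) standard deviation by default; quartiles use the linear
    interpolation convention.  Feb-29 is retained as its own key (smaller n).
    NaN values (e.g. censored PQLs) are dropped before grouping.
    """
    dates = pd.DatetimeIndex(dates)
    values = np.asarray(values, dtype=float)
    if len(dates) != len(values):
        raise ValueError("dates and values must have equal length")
    ok = np.isfinite(values)
    if not ok.any():
        raise ValueError("no finite values to aggregate")
    s = pd.Series(values[ok], index=dates[ok])
    g = s.groupby([s.index.month, s.index.day])
    out = g.agg(
        n="count",
        mean="mean",
        min="min",
        max="max",
        std=lambda x: float(np.std(x, ddof=ddof)) if len(x) > ddof else 0.0,
        q25=lambda x: float(np.quantile(x, 0.25)),
        median="median",
        q75=lambda x: float(np.quantile(x, 0.75)),
    )
    out.index.names = ["month", "day"]
    return out


def normals_to_frame(normals: pd.DataFrame) -> pd.DataFrame:
    """Normals in the output CSV column order (month, day as columns)."""
    return normals.reset_index()[
        ["month", "day", "n", "mean", "min", "max", "std", "q25", "median", "q75"]
    ]


def normal_r2(dates, values, normals: pd.DataFrame | None = None) -> float:
    """Percentage of variance captured by the mean of the day-of-year normal.

    R² = 1 − Σ(y − ŷ_doy)² / Σ(y − ȳ)², where ŷ_doy is the mean normal for
    the value's calendar day; returned on the 0–100 scale.  Raises if the
    series has zero total variance.
    """
    dates = pd.DatetimeIndex(dates)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    dates, values = dates[ok], values[ok]
    if normals is None:
        normals = compute_normals(dates, values)
    key = pd.MultiIndex.from_arrays([dates.month, dates.day])
    yhat = normals["mean"].reindex(key).to_numpy()
    ss_tot = float(np.sum((values - values.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("total variance is zero; R^2 undefined")
    ss_res = float(np.sum((values - yhat) ** 2))
    return 100.0 * (1.0 - ss_res / ss_tot)


def latitude_ols(site_medians) -> LatitudeFit:
    """Simple OLS of per-site median PQL on latitude.

    ``site_medians`` is an iterable of (latitude, median) pairs; the F and p
    come from the regression's overall significance test.
    """
    pts = sorted((float(a), float(b)) for a, b in site_medians)
    if len(pts) < 3:
        raise ValueError("need at least 3 sites")
    lat = np.array([p[0] for p in pts])
    med = np.array([p[1] for p in pts])
    if np.ptp(lat) == 0.0:
        raise ValueError("all latitudes identical; fit is singular")
    res = sm.OLS(med, sm.add_constant(lat)).fit()
    return LatitudeFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        F=float(res.fvalue),
        p=float(res.f_pvalue),
        n_sites=len(pts),
    )


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in kilometres."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))

def nearest_site(q: HistoricalQuarantine, sites) -> SiteMeta:
    """The station closest to an outbreak by great-circle distance.

    Ties break to the lower latitude, then callsign order.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("no sites given")
    return min(
        sites,
        key=lambda s: (
            round(haversine_km(q.latitude, q.longitude, s.latitude, s.longitude), 9),
            s.latitude,
            s.callsign,
        ),
    )


def paired_comparison(
    values_a, values_b, normal_means_a, normal_means_b, ddof: int = 1
) -> PairedComparison:
    """Paired t-test plus deviation-variance F-test between two methods.

    ``values_a``/``values_b`` are PQLs for the same start dates under each
    method; ``normal_means_*`` are the corresponding mean-normal predictions
    for each date's day of year.  The t-test is on the paired differences
    (a − b).  Deviations are value − mean-normal; the F statistic is
    var(dev_a)/var(dev_b) on (n−1, n−1) df with a two-sided p (the larger
    variance mirrored into the numerator for the tail probability).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    na = np.asarray(normal_means_a, dtype=float)
    nb = np.asarray(normal_means_b, dtype=float)
    if not (len(a) == len(b) == len(na) == len(nb)):
        raise ValueError("all four inputs must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if float(np.std(d, ddof=1)) == 0.0:
        # degenerate pairs: identical differences everywhere
        t = 0.0 if d.mean() == 0.0 else np.sign(d.mean()) * np.inf
        p = 1.0 if d.mean() == 0.0 else 0.0
    else:
        t, p = stats.ttest_rel(a, b)
    dev_a = a - na
    dev_b = b - nb
    var_a = float(np.var(dev_a, ddof=1))
    var_b = float(np.var(dev_b, ddof=1))
    if var_b == 0.0:
        raise ValueError("zero deviation variance in denominator")
    F = var_a / var_b
    big = max(F, 1.0 / F) if F > 0 else np.inf
    F_p = min(2.0 * stats.f.sf(big, n - 1, n - 1), 1.0)
    return PairedComparison(
        n=n,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        std_a=float(np.std(a, ddof=ddof)),
        std_b=float(np.std(b, ddof=ddof)),
        t=float(t),
        df=n - 1,
        p=float(p),
        dev_std_a=float(np.sqrt(var_a)),
        dev_std_b=float(np.sqrt(var_b)),
        F=F,
        F_p=float(F_p),
    )
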
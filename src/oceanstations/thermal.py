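"""Site-level SST climatology and thermal-stress indices.

Implements the CoRTAD-style heat-stress index family (anomaly, TSA,
degree heating week, exceedance frequencies) and its cold-side analogue,
from daily satellite-pixel SST records to single-value site summaries.

Conventions used throughout:

* Day-of-year uses 366 bins; Feb 29 is bin 60, averaged over leap years
  only; in non-leap years bin 60 is skipped.
* "Past 52 weeks" is a trailing 364-day window inclusive of the current
  day; "past 12 weeks" a trailing 84-day window.
* Degree heating/cooling weeks are in °C-weeks (daily sums divided by 7).
* Percentiles interpolate linearly between closest order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal

from .geo import haversine_km

WEEK_WINDOW_DAYS = 364      # 52 weeks, trailing, inclusive of current day
DHW_WINDOW_DAYS = 84        # 12 weeks
TSA_THRESHOLD = 1.0         # °C
#: extra burn-in of the DHW/DCW frequency chain: a 364-day count of an
#: 84-day accumulation is fully determined only after 364+84-2 days.
FULL_BURN_IN_DAYS = WEEK_WINDOW_DAYS + DHW_WINDOW_DAYS - 2


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class SstSeries:
    """Daily site-level SST with per-day dispersion and pixel counts."""

    site_id: str
    dates: pd.DatetimeIndex
    sst_mean: np.ndarray          # °C, NaN where missing
    sst_sd: np.ndarray            # °C, NaN where n_pixels < 2
    n_pixels: np.ndarray          # pixels pooled that day

    def __post_init__(self):
        if len(self.dates) > 1:
            steps = np.diff(self.dates.view("int64"))
            if not (steps == steps[0]).all() or steps[0] != 86_400_000_000_000:
                raise ValueError("dates must be strictly increasing with daily step")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sst_mean_9pixel": self.sst_mean,
                             "sst_sd_9pixel": self.sst_sd,
                             "n_pixels": self.n_pixels}, index=self.dates)


@dataclass
class SeasonalClimatology:
    """Low-pass-filtered day-of-year SST cycle and its weekly extremes."""

    seasonal_cycle: np.ndarray    # 366 values, °C
    weekly_means: np.ndarray      # 52 values, °C
    max_weekly_clim: float
    min_weekly_clim: float

    def cycle_for(self, dates: pd.DatetimeIndex) -> np.ndarray:
        """Seasonal-cycle value for each calendar date."""
        return self.seasonal_cycle[day_of_year_366(dates) - 1]


@dataclass
class GapStats:
    """Lengths of consecutive-missing runs and their 95th percentile."""

    run_lengths: np.ndarray
    p95: float


@dataclass
class ThermalIndexSeries:
    """Per-day values of all thermal indices for one site.

    ``frame`` is indexed by date with one column per index (Table-style
    bracketed acronyms as headers) plus a boolean ``burn_in`` column.
    """

    site_id: str
    frame: pd.DataFrame
    climatology: SeasonalClimatology
    gap_stats: GapStats


@dataclass
class ThermalEventSummary:
    end_date: pd.Timestamp
    peak: float
    duration: int


@dataclass
class SiteThermalSummary:
    """Single-value summaries of each index at a sampling date."""

    site_id: str
    sampling_date: pd.Timestamp
    stats: pd.DataFrame           # rows = indices; cols = min/max/sum/mean/sd/at_sampling
    last_heat_event: Optional[ThermalEventSummary]
    last_cold_event: Optional[ThermalEventSummary]
    recovery_days_heat: float
    recovery_days_cold: float
    gap_p95: float


# ---------------------------------------------------------------------------
# Calendar helpers
# ---------------------------------------------------------------------------

def day_of_year_366(dates: pd.DatetimeIndex) -> np.ndarray:
    """Day-of-year on a 366-bin calendar: Feb 29 is always bin 60.

    In non-leap years days after Feb 28 are shifted by one so that e.g.
    Mar 1 is bin 61 in every year; bin 60 only ever holds Feb 29.
    """
    doy = dates.dayofyear.to_numpy()
    nonleap = ~dates.is_leap_year
    return np.where(nonleap & (doy >= 60), doy + 1, doy)


# ---------------------------------------------------------------------------
# Pixel pooling
# ---------------------------------------------------------------------------

def daily_average_pixels(pixel_records: pd.DataFrame, site_id: str = None) -> SstSeries:
    """Pool per-scene pixel SSTs into a daily mean/SD series.

    ``pixel_records`` needs columns ``date`` and ``value`` (°C), one row
    per extracted pixel (all platforms pooled); an optional ``site_id``
    column restricts to one site.  Days without pixels are missing.
    """
    rec = pixel_records.copy()
    if site_id is not None and "site_id" in rec.columns:
        rec = rec[rec["site_id"] == site_id]
    rec["date"] = pd.to_datetime(rec["date"]).dt.normalize()
    grouped = rec.groupby("date")["value"]
    daily = grouped.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count")
    full = pd.date_range(daily.index.min(), daily.index.max(), freq="D")
    daily = daily.reindex(full)
    n = daily["n"].fillna(0).to_numpy(dtype=int)
    sd = daily["sd"].to_numpy(dtype=float)
    sd[n < 2] = np.nan
    return SstSeries(site_id=site_id or "SITE", dates=full,
                     sst_mean=daily["mean"].to_numpy(dtype=float),
                     sst_sd=sd, n_pixels=n)


# ---------------------------------------------------------------------------
# Climatology
# ---------------------------------------------------------------------------

def build_climatology(series: SstSeries) -> SeasonalClimatology:
    """Day-of-year mean cycle, low-pass filtered, with weekly extremes.

    The 366-value cycle is triplicated and concatenated so a zero-phase
    Chebyshev type-I low-pass filter (order 3, 0.1 dB passband ripple,
    cutoff period 36 days) can run without edge artifacts; the middle copy
    is then extracted.  Weekly climatologies are the 52 contiguous 7-day
    bin means of the filtered cycle (bin 52 absorbs days 358-366); their
    extremes are the reference levels for heat and cold stress.
    """
    span_days = (series.dates[-1] - series.dates[0]).days
    if span_days < 3 * 365:
        raise ValueError("climatology requires a series spanning >= 3 full years")
    doy = day_of_year_366(series.dates)
    sums = np.zeros(366)
    counts = np.zeros(366)
    valid = ~np.isnan(series.sst_mean)
    np.add.at(sums, doy[valid] - 1, series.sst_mean[valid])
    np.add.at(counts, doy[valid] - 1, 1)
    cycle = np.full(366, np.nan)
    nz = counts > 0
    cycle[nz] = sums[nz] / counts[nz]
    if np.isnan(cycle[59]):  # Feb 29 absent (no leap-year data): neighbour mean
        cycle[59] = np.nanmean(cycle[[58, 60]])
    if np.isnan(cycle).any():
        missing_bins = np.flatnonzero(np.isnan(cycle)) + 1
        raise ValueError(
            "no data in any year for day-of-year bins "
            f"{missing_bins.tolist()}; interpolate the input across "
            "day-of-year bins before building a climatology")

    tripled = np.concatenate([cycle, cycle, cycle])
    # cutoff 1/36 cycles/day, i.e. 2/36 of the Nyquist frequency
    b, a = signal.cheby1(3, 0.1, 2.0 / 36.0)
    smooth = signal.filtfilt(b, a, tripled)[366:732]

    weekly = np.empty(52)
    for w in range(51):
        weekly[w] = smooth[7 * w:7 * (w + 1)].mean()
    weekly[51] = smooth[357:366].mean()
    return SeasonalClimatology(seasonal_cycle=smooth, weekly_means=weekly,
                               max_weekly_clim=float(weekly.max()),
                               min_weekly_clim=float(weekly.min()))


def compute_anomaly(series: SstSeries, clim: SeasonalClimatology) -> np.ndarray:
    """SST minus the seasonal cycle at the same day-of-year (NaN where SST missing)."""
    return series.sst_mean - clim.cycle_for(series.dates)


# ---------------------------------------------------------------------------
# Gap filling
# ---------------------------------------------------------------------------

def fill_gaps(values: np.ndarray) -> tuple[np.ndarray, GapStats]:
    """Linearly interpolate interior missing runs; leading/trailing stay missing.

    Also returns the lengths of all consecutive-missing runs and their
    95th percentile (linear interpolation between order statistics).
    """
    values = np.asarray(values, dtype=float)
    if np.isnan(values).all():
        raise ValueError("cannot fill an all-missing series")
    runs = missing_run_lengths(values)
    p95 = float(np.percentile(runs, 95)) if len(runs) else 0.0
    filled = (pd.Series(values)
              .interpolate(method="linear", limit_area="inside")
              .to_numpy())
    return filled, GapStats(run_lengths=runs, p95=p95)


def missing_run_lengths(values: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of missing values (leading/trailing included)."""
    miss = np.isnan(np.asarray(values, dtype=float))
    if not miss.any():
        return np.array([], dtype=int)
    padded = np.concatenate([[False], miss, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]
    return ends - starts


# ---------------------------------------------------------------------------
# Rolling indices
# ---------------------------------------------------------------------------

def rolling_exceedance_count(values: np.ndarray, threshold: float,
                             direction: str = "ge",
                             window: int = WEEK_WINDOW_DAYS) -> np.ndarray:
    """Per-day count of days in the trailing window meeting the comparison.

    ``direction`` is ``"ge"`` (values >= threshold) or ``"le"``; the
    window is inclusive of the current day and truncated at the series
    start (callers flag those days as burn-in).  NaNs never count.
    """
    values = np.asarray(values, dtype=float)
    if direction == "ge":
        hit = values >= threshold
    elif direction == "le":
        hit = values <= threshold
    else:
        raise ValueError("direction must be 'ge' or 'le'")
    hit = np.where(np.isnan(values), False, hit)
    return (pd.Series(hit.astype(float))
            .rolling(window, min_periods=1).sum().to_numpy())


def degree_weeks(tsa: np.ndarray, threshold: float = TSA_THRESHOLD,
                 window: int = DHW_WINDOW_DAYS, mode: str = "heat") -> np.ndarray:
    """Degree heating (or cooling) weeks: trailing accumulation in °C-weeks.

    Heat mode sums TSA over the past ``window`` days where TSA >= threshold
    and divides by 7; cold mode sums TSA where TSA <= -threshold (result
    <= 0).
    """
    tsa = np.asarray(tsa, dtype=float)
    if mode == "heat":
        contrib = np.where(np.isnan(tsa), 0.0, np.where(tsa >= threshold, tsa, 0.0))
    elif mode == "cold":
        contrib = np.where(np.isnan(tsa), 0.0, np.where(tsa <= -threshold, tsa, 0.0))
    else:
        raise ValueError("mode must be 'heat' or 'cold'")
    return (pd.Series(contrib).rolling(window, min_periods=1).sum() / 7.0).to_numpy()


# ---------------------------------------------------------------------------
# Assembly and summaries
# ---------------------------------------------------------------------------

#: column order of the per-day index table
INDEX_COLUMNS = [
    "sst_mean_9pixel", "seasonal_average_9pixel", "SST_anomaly_9pixel",
    "SST_mean_interpl", "SST_anomaly_interpl", "SST_anomaly_freq",
    "TSA_heat", "TSA_heat_freq", "TSA_DHW", "TSA_DHW_freq",
    "TSA_cold", "TSA_cold_freq", "TSA_DCW", "TSA_DCW_freq",
]


def assemble_indices(series: SstSeries,
                     clim: SeasonalClimatology | None = None) -> ThermalIndexSeries:
    """Compute the full per-day thermal-index table for one site.

    TSA_heat = interpolated SST minus the maximum weekly climatology;
    TSA_cold uses the minimum weekly climatology.  Exceedance frequencies
    count days in the past 52 weeks; DHW/DCW accumulate over the past 12
    weeks in °C-weeks; their own frequencies count days with DHW >= 1
    (DCW <= -1) °C-weeks in the past 52 weeks.
    """
    if clim is None:
        clim = build_climatology(series)
    anom = compute_anomaly(series, clim)
    sst_interp, gaps = fill_gaps(series.sst_mean)
    anom_interp = sst_interp - clim.cycle_for(series.dates)

    tsa_heat = sst_interp - clim.max_weekly_clim
    tsa_cold = sst_interp - clim.min_weekly_clim
    dhw = degree_weeks(tsa_heat, mode="heat")
    dcw = degree_weeks(tsa_cold, mode="cold")

    frame = pd.DataFrame({
        "sst_mean_9pixel": series.sst_mean,
        "seasonal_average_9pixel": clim.cycle_for(series.dates),
        "SST_anomaly_9pixel": anom,
        "SST_mean_interpl": sst_interp,
        "SST_anomaly_interpl": anom_interp,
        "SST_anomaly_freq": rolling_exceedance_count(anom_interp, 1.0, "ge"),
        "TSA_heat": tsa_heat,
        "TSA_heat_freq": rolling_exceedance_count(tsa_heat, 1.0, "ge"),
        "TSA_DHW": dhw,
        "TSA_DHW_freq": rolling_exceedance_count(dhw, 1.0, "ge"),
        "TSA_cold": tsa_cold,
        "TSA_cold_freq": rolling_exceedance_count(tsa_cold, -1.0, "le"),
        "TSA_DCW": dcw,
        "TSA_DCW_freq": rolling_exceedance_count(dcw, -1.0, "le"),
    }, index=series.dates)
    frame["burn_in"] = np.arange(len(frame)) < FULL_BURN_IN_DAYS
    return ThermalIndexSeries(site_id=series.site_id, frame=frame,
                              climatology=clim, gap_stats=gaps)


def _last_event(values: np.ndarray, dates: pd.DatetimeIndex, hit: np.ndarray,
                sampling_i: int) -> tuple[Optional[ThermalEventSummary], float]:
    """Most recent maximal exceedance run at or before the sampling day."""
    hit = hit[:sampling_i + 1]
    if not hit.any():
        return None, np.nan
    idx = np.flatnonzero(hit)
    end = idx[-1]
    start = end
    while start > 0 and hit[start - 1]:
        start -= 1
    ev = ThermalEventSummary(end_date=dates[end],
                             peak=float(np.nanmax(np.abs(values[start:end + 1])) *
                                        np.sign(values[end])),
                             duration=int(end - start + 1))
    recovery = float(sampling_i - end)
    return ev, recovery


def summarize_site(indices: ThermalIndexSeries,
                   sampling_date) -> SiteThermalSummary:
    """Single-value site summary at a sampling date.

    Per-index min/max/sum/mean/sd over the non-burn-in span up to the
    sampling day, plus the value recorded at the sampling day (or the
    last available prior day), the last heat/cold events (end date, peak,
    duration) and the recovery time since each.
    """
    sampling_date = pd.Timestamp(sampling_date)
    frame = indices.frame
    dates = frame.index
    if sampling_date < dates[0] or sampling_date > dates[-1]:
        raise ValueError("sampling_date outside the series span")
    sampling_i = int(dates.get_loc(sampling_date))
    burn_in_end = int(frame["burn_in"].to_numpy().sum())
    if sampling_i < burn_in_end:
        raise ValueError("sampling_date falls inside the index burn-in period")

    window = frame.iloc[burn_in_end:sampling_i + 1]
    rows = {}
    for col in INDEX_COLUMNS:
        v = window[col].to_numpy(dtype=float)
        at = frame[col].iloc[:sampling_i + 1].dropna()
        rows[col] = {
            "min": np.nanmin(v), "max": np.nanmax(v), "sum": np.nansum(v),
            "mean": np.nanmean(v), "sd": np.nanstd(v, ddof=1),
            "at_sampling": at.iloc[-1] if len(at) else np.nan,
        }
    stats = pd.DataFrame(rows).T[["min", "max", "sum", "mean", "sd", "at_sampling"]]

    tsa_heat = frame["TSA_heat"].to_numpy(dtype=float)
    tsa_cold = frame["TSA_cold"].to_numpy(dtype=float)
    heat_ev, rec_heat = _last_event(tsa_heat, dates, tsa_heat >= TSA_THRESHOLD,
                                    sampling_i)
    cold_ev, rec_cold = _last_event(tsa_cold, dates, tsa_cold <= -TSA_THRESHOLD,
                                    sampling_i)
    span = float(sampling_i - burn_in_end)
    if heat_ev is None:
        rec_heat = span
    if cold_ev is None:
        rec_cold = span
    return SiteThermalSummary(site_id=indices.site_id, sampling_date=sampling_date,
                              stats=stats, last_heat_event=heat_ev,
                              last_cold_event=cold_ev,
                              recovery_days_heat=rec_heat,
                              recovery_days_cold=rec_cold,
                              gap_p95=indices.gap_stats.p95)


# ---------------------------------------------------------------------------
# Reef Check proximity matching
# ---------------------------------------------------------------------------

def match_reefcheck(site_lat: float, site_lon: float,
                    candidates: pd.DataFrame,
                    max_km: float = 10.0) -> Optional[tuple[int, float]]:
    """Nearest candidate site within ``max_km`` (haversine), or None.

    ``candidates`` needs ``lat``/``lon`` columns; returns (positional
    index, distance km) of the closest candidate if within range.
    """
    if len(candidates) == 0:
        return None
    d = haversine_km(site_lat, site_lon,
                     candidates["lat"].to_numpy(), candidates["lon"].to_numpy())
    i = int(np.argmin(d))
    if d[i] <= max_km:
        return i, float(d[i])
    return None
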
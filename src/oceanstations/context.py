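"""Environmental-context aggregation, bias-corrected merging and provenance.

Heterogeneous measurement records (in-situ samples, underway sensors,
satellite match-ups, model output) are matched to samples with explicit
time/space/depth lag bookkeeping, satellite grids are extracted with
pixel buffers, biased sources are corrected by regression against the
in-situ reference and merged under a source-priority policy, and every
sample carries the sampling-design label and station/island assignment.

Missing-value vocabulary (emitted literally in outputs):
``nav`` not-available, ``npr`` not-provided, ``nac`` confidential,
``nap`` not-applicable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats as sstats

from .geo import haversine_km, nautical_miles_to_km

MISSING_TOKENS = {
    "not_collected": "nav",
    "withheld": "npr",
    "confidential": "nac",
    "not_applicable": "nap",
}

STATION_MAX_KM = 75.0
STATION_MAX_DAYS = 0.25
ISLAND_MAX_KM = nautical_miles_to_km(200.0)     # 370.4 km, printed as 370


def encode_missing(reason: str) -> str:
    """Token for a missing value given the reason it is missing."""
    try:
        return MISSING_TOKENS[reason]
    except KeyError:
        raise ValueError(f"unknown missing-value reason {reason!r}") from None


# ---------------------------------------------------------------------------
# Sampling-design labels
# ---------------------------------------------------------------------------

_LABEL_RANGES = {"oa": 249, "island": 32, "site": 99, "colony": 999}


def compose_design_label(oa: int, island: int, site: int, colony: int) -> str:
    """Zero-padded sampling-design label ``OA###-I##-S##-C###``."""
    for name, value in zip(_LABEL_RANGES, (oa, island, site, colony)):
        if not (0 <= int(value) <= _LABEL_RANGES[name]):
            raise ValueError(f"{name} component {value} out of range "
                             f"[0, {_LABEL_RANGES[name]}]")
    return f"OA{oa:03d}-I{island:02d}-S{site:02d}-C{colony:03d}"


def parse_design_label(label: str) -> tuple[int, int, int, int]:
    """Inverse of :func:`compose_design_label`."""
    parts = label.split("-")
    if (len(parts) != 4 or parts[0][:2] != "OA" or parts[1][:1] != "I"
            or parts[2][:1] != "S" or parts[3][:1] != "C"):
        raise ValueError(f"malformed sampling-design label {label!r}")
    return (int(parts[0][2:]), int(parts[1][1:]),
            int(parts[2][1:]), int(parts[3][1:]))


# ---------------------------------------------------------------------------
# Station grouping and island annotation
# ---------------------------------------------------------------------------

def assign_station(events: pd.DataFrame,
                   max_km: float = STATION_MAX_KM,
                   max_days: float = STATION_MAX_DAYS) -> np.ndarray:
    """Greedy time-ordered clustering of sampling events into stations.

    ``events`` needs ``time`` (datetime), ``lat``, ``lon`` columns and may
    carry a boolean ``systematic`` column.  An event joins the currently
    open station when it lies within ``max_km`` and ``max_days`` of the
    station centroid, otherwise it opens the next station.  Isolated
    non-systematic events are assigned station 0.
    """
    times = pd.to_datetime(events["time"]).to_numpy()
    if len(times) > 1 and (np.diff(times.astype("int64")) < 0).any():
        raise ValueError("events must be time-sorted")
    lat = events["lat"].to_numpy(dtype=float)
    lon = events["lon"].to_numpy(dtype=float)
    systematic = (events["systematic"].to_numpy(dtype=bool)
                  if "systematic" in events.columns
                  else np.ones(len(events), dtype=bool))

    clusters: list[list[int]] = []
    for i in range(len(events)):
        if clusters:
            members = clusters[-1]
            c_lat = lat[members].mean()
            c_lon = lon[members].mean()
            c_time = times[members].astype("int64").mean()
            d_km = haversine_km(lat[i], lon[i], c_lat, c_lon)
            d_days = abs(times[i].astype("int64") - c_time) / 86_400e9
            if d_km <= max_km and d_days <= max_days:
                members.append(i)
                continue
        clusters.append([i])

    ids = np.zeros(len(events), dtype=int)
    next_id = 1
    for members in clusters:
        if len(members) == 1 and not systematic[members[0]]:
            continue  # isolated non-systematic event stays station 0
        for m in members:
            ids[m] = next_id
        next_id += 1
    return ids


def annotate_island(station_lat: float, station_lon: float,
                    islands: pd.DataFrame,
                    max_km: float = ISLAND_MAX_KM) -> Optional[int]:
    """Code of the nearest island within 200 nautical miles (370 km), else None.

    ``islands`` needs ``code``, ``lat``, ``lon`` columns; distance ties
    break toward the lower island code.
    """
    if len(islands) == 0:
        return None
    d = haversine_km(station_lat, station_lon,
                     islands["lat"].to_numpy(), islands["lon"].to_numpy())
    order = np.lexsort((islands["code"].to_numpy(), d))
    best = order[0]
    if d[best] <= max_km:
        return int(islands["code"].iloc[best])
    return None


# ---------------------------------------------------------------------------
# Satellite-grid buffer extraction
# ---------------------------------------------------------------------------

def buffer_window_size(buffer_pixels: int, pixel_size_km: float = 4.0) -> tuple[int, float]:
    """Window edge in pixels and km for a given pixel buffer.

    A b-pixel buffer around the containing pixel is a (2b+1)×(2b+1)
    square; at 4 km resolution the 2-pixel buffer is 5×5 pixels over a
    20 km side and the 12-pixel buffer 25×25 pixels over 100 km.
    """
    edge = 2 * buffer_pixels + 1
    return edge, edge * pixel_size_km


def buffer_extract(grid: xr.DataArray, lat: float, lon: float,
                   buffer_pixels: int = 2) -> dict:
    """Statistics of the pixel window centred on the containing pixel.

    ``grid`` is a 2-D mapped field with ``lat``/``lon`` coordinates (cell
    centres).  Missing pixels are excluded; an all-missing window returns
    the ``nav`` token with n = 0.  Points outside the grid raise.
    """
    if buffer_pixels < 0:
        raise ValueError("buffer must be >= 0 pixels")
    glat = grid["lat"].values
    glon = grid["lon"].values
    dlat = abs(glat[1] - glat[0])
    dlon = abs(glon[1] - glon[0])
    if not (glat.min() - dlat / 2 <= lat <= glat.max() + dlat / 2
            and glon.min() - dlon / 2 <= lon <= glon.max() + dlon / 2):
        raise ValueError("point outside the mapped grid")
    i = int(np.argmin(np.abs(glat - lat)))
    j = int(np.argmin(np.abs(glon - lon)))
    b = buffer_pixels
    window = grid.values[max(i - b, 0):i + b + 1, max(j - b, 0):j + b + 1]
    vals = window[np.isfinite(window)]
    if len(vals) == 0:
        return {"n": 0, "mean": MISSING_TOKENS["not_collected"]}
    return {"n": int(len(vals)), "mean": float(vals.mean()),
            "stdev": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            "P05": float(np.percentile(vals, 5)),
            "P25": float(np.percentile(vals, 25)),
            "P50": float(np.percentile(vals, 50)),
            "P75": float(np.percentile(vals, 75)),
            "P95": float(np.percentile(vals, 95))}


# ---------------------------------------------------------------------------
# Sample-level aggregation with lags
# ---------------------------------------------------------------------------

@dataclass
class SampleLocator:
    """Identity and space/time/depth reference of one sample."""

    sample_id: str
    time: pd.Timestamp
    lat: float
    lon: float
    depth: float = 0.0            # m, positive down; altitude negative


@dataclass
class AggregatedContext:
    """Per-sample statistics of matched context records with lags.

    ``dt`` is sample-time minus context-time in fractional days; ``dxy``
    the great-circle distance in km; ``dz`` sample depth minus context
    depth in m (positive when the sample is deeper).  All lags are those
    of the nearest contributing record.  ``missing`` carries a token when
    no record matched.
    """

    sample_id: str
    variable: str
    n: int
    mean: float = np.nan
    stdev: float = np.nan
    p05: float = np.nan
    p25: float = np.nan
    p50: float = np.nan
    p75: float = np.nan
    p95: float = np.nan
    dt: float = np.nan
    dxy: float = np.nan
    dz: float = np.nan
    missing: Optional[str] = None


def match_context(sample: SampleLocator, records: pd.DataFrame,
                  max_dt: float, max_dxy: float, max_dz: float,
                  variable: str = "") -> AggregatedContext:
    """Aggregate context records within the time/space/depth tolerances.

    ``records`` needs ``time``, ``lat``, ``lon``, ``depth``, ``value``
    columns.  Returns n/mean/stdev/P05–P95 over the matched subset plus
    the lags of the nearest matched record (nearest in |dt|, ties broken
    by dxy then |dz|); an empty match yields the ``nav`` token.
    """
    if min(max_dt, max_dxy, max_dz) <= 0:
        raise ValueError("tolerances must be positive")
    rec = records.dropna(subset=["value"])
    if len(rec) == 0:
        return AggregatedContext(sample.sample_id, variable, 0,
                                 missing=MISSING_TOKENS["not_collected"])
    t = pd.to_datetime(rec["time"])
    dt = (pd.Timestamp(sample.time) - t).dt.total_seconds().to_numpy() / 86400.0
    dxy = haversine_km(sample.lat, sample.lon,
                       rec["lat"].to_numpy(), rec["lon"].to_numpy())
    dz = sample.depth - rec["depth"].to_numpy(dtype=float)
    keep = (np.abs(dt) <= max_dt) & (dxy <= max_dxy) & (np.abs(dz) <= max_dz)
    if not keep.any():
        return AggregatedContext(sample.sample_id, variable, 0,
                                 missing=MISSING_TOKENS["not_collected"])
    vals = rec["value"].to_numpy(dtype=float)[keep]
    order = np.lexsort((np.abs(dz)[keep], dxy[keep], np.abs(dt)[keep]))
    nearest = order[0]
    return AggregatedContext(
        sample.sample_id, variable, int(keep.sum()),
        mean=float(vals.mean()),
        stdev=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        p05=float(np.percentile(vals, 5)), p25=float(np.percentile(vals, 25)),
        p50=float(np.percentile(vals, 50)), p75=float(np.percentile(vals, 75)),
        p95=float(np.percentile(vals, 95)),
        dt=float(dt[keep][nearest]), dxy=float(dxy[keep][nearest]),
        dz=float(dz[keep][nearest]))


# ---------------------------------------------------------------------------
# Bias correction and priority merging
# ---------------------------------------------------------------------------

@dataclass
class BiasCorrection:
    slope: float
    intercept: float
    r: float
    n: int
    corrected: np.ndarray
    accepted: bool


def bias_correct_source(source: np.ndarray, reference: np.ndarray,
                        min_r: float = 0.5,
                        slope_bounds: tuple = (0.33, 3.0),
                        min_n: int = 10,
                        inversion: str = "divide_first") -> BiasCorrection:
    """Regress a satellite/model source on the in-situ reference and de-bias it.

    Ordinary least squares of source on reference over paired non-missing
    values.  The default inversion is corrected = (source − intercept) /
    slope, the exact inverse of the fitted affine bias;
    ``inversion="subtract_last"`` gives source/slope − intercept instead.
    The correction is accepted only when r >= min_r, the slope lies in
    ``slope_bounds`` and n >= min_n; rejected sources must not be merged.
    """
    source = np.asarray(source, dtype=float)
    reference = np.asarray(reference, dtype=float)
    paired = np.isfinite(source) & np.isfinite(reference)
    n = int(paired.sum())
    if n < 2:
        raise ValueError("need at least 2 paired values")
    if np.std(reference[paired]) == 0:
        raise ValueError("reference has zero variance; regression undefined")
    fit = sstats.linregress(reference[paired], source[paired])
    slope, intercept, r = float(fit.slope), float(fit.intercept), float(fit.rvalue)
    if inversion == "divide_first":
        corrected = (source - intercept) / slope
    elif inversion == "subtract_last":
        corrected = source / slope - intercept
    else:
        raise ValueError("inversion must be 'divide_first' or 'subtract_last'")
    accepted = (abs(r) >= min_r and slope_bounds[0] <= slope <= slope_bounds[1]
                and n >= min_n)
    return BiasCorrection(slope, intercept, r, n, corrected, accepted)


@dataclass
class MergePolicy:
    """Ordered source priority plus correction-acceptance thresholds."""

    priority: Sequence[str] = ("insitu_sample", "insitu_sensor", "satellite", "model")
    min_r: float = 0.5
    slope_bounds: tuple = (0.33, 3.0)
    min_n: int = 10

    def __post_init__(self):
        if not self.priority:
            raise ValueError("priority must be non-empty")


def merge_sources(series_by_source: dict[str, pd.Series],
                  policy: MergePolicy = MergePolicy()) -> pd.DataFrame:
    """First non-missing value in priority order, with per-value provenance.

    Input series must share an index (site/station keys).  Values from
    satellite/model sources are expected to be already bias-corrected and
    accepted; an in-situ value is never overwritten.  Stations missing in
    every source get the ``nav`` token in the provenance column and NaN
    as value.
    """
    index = None
    for s in series_by_source.values():
        index = s.index if index is None else index.union(s.index)
    merged = pd.Series(np.nan, index=index, dtype=float)
    provenance = pd.Series(MISSING_TOKENS["not_collected"], index=index, dtype=object)
    for source in policy.priority:
        if source not in series_by_source:
            continue
        s = series_by_source[source].reindex(index)
        take = merged.isna() & s.notna()
        merged[take] = s[take]
        provenance[take] = source
    return pd.DataFrame({"value": merged, "source": provenance})


def interpolate_station_gap(values: pd.Series) -> pd.Series:
    """Time-weighted linear interpolation of station-level gaps.

    ``values`` is indexed by station time (datetime-like or numeric in
    station order).  Interior gaps are filled linearly in index units;
    boundary gaps stay missing.
    """
    idx = values.index
    if isinstance(idx, pd.DatetimeIndex):
        return values.interpolate(method="index", limit_area="inside")
    numeric = pd.Series(values.to_numpy(dtype=float),
                        index=pd.Index(np.asarray(idx, dtype=float)))
    out = numeric.interpolate(method="index", limit_area="inside")
    return pd.Series(out.to_numpy(), index=idx)
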
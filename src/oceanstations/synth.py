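"""Synthetic input generators with known ground truth.

Every downstream stage (thermal indices, flow diagnostics, multi-source
merging, size spectra) can be exercised on data produced here, where the
seasonal cycle, injected heat/cold events, analytic flow diagnostics,
source biases and spectral slopes are all known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import xarray as xr

from .geo import METERS_PER_DEGREE
from .thermal import SstSeries
from .nbss import PlanktonSample

SECONDS_PER_DAY = 86400.0


# ---------------------------------------------------------------------------
# SST scenarios
# ---------------------------------------------------------------------------

@dataclass
class ThermalEvent:
    """A synthetic heat wave (amplitude > 0) or cold spell (amplitude < 0).

    ``square`` events add the full amplitude on every day of the window;
    ``triangular`` events ramp linearly up to the amplitude at the window
    midpoint and back down, reaching zero just outside the window.
    """

    start_date: str | pd.Timestamp
    duration: int
    amplitude: float
    shape: str = "square"

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("event duration must be positive")
        if self.shape not in ("square", "triangular"):
            raise ValueError(f"unknown event shape {self.shape!r}")

    def anomaly_profile(self) -> np.ndarray:
        d = self.duration
        if self.shape == "square":
            return np.full(d, self.amplitude)
        if d == 1:
            return np.array([self.amplitude])
        mid = (d - 1) / 2.0
        i = np.arange(d)
        return self.amplitude * (1.0 - np.abs(i - mid) / mid)


@dataclass
class SstScenario:
    """Parameters of a synthetic daily SST record for one site.

    The series is seasonal cycle + linear trend + AR(1) noise + injected
    events, with geometric-length runs of missing days.  ``trend`` is in
    °C per decade; ``noise_sd`` is the stationary (marginal) SD of the
    AR(1) noise; ``ar1`` its lag-1 autocorrelation.
    """

    site_id: str = "SITE"
    start_date: str = "2002-01-01"
    end_date: str = "2016-12-31"
    mean_sst: float = 27.0
    seasonal_amplitude: float = 2.0
    peak_day: int = 70
    trend: float = 0.0
    noise_sd: float = 0.3
    ar1: float = 0.0
    events: list = field(default_factory=list)
    gap_mean_len: float = 5.0
    gap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if pd.Timestamp(self.end_date) <= pd.Timestamp(self.start_date):
            raise ValueError("end_date must be after start_date")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.ar1 < 1):
            raise ValueError("ar1 must lie in [0, 1)")
        if not (0 <= self.gap_fraction < 0.5):
            raise ValueError("gap_fraction must lie in [0, 0.5)")


def generate_sst_series(scenario: SstScenario) -> tuple[SstSeries, pd.DataFrame]:
    """Generate a daily SST series plus its noise-free ground truth.

    Returns ``(series, truth)`` where ``truth`` has one row per day with
    columns ``seasonal`` (cycle + trend, °C), ``event_anomaly`` (injected
    anomaly, °C) and ``noise`` (the AR(1) term actually drawn).

    Raises if the date span is shorter than three years: the downstream
    climatology needs multiple seasonal cycles.
    """
    dates = pd.date_range(scenario.start_date, scenario.end_date, freq="D")
    n = len(dates)
    if n < 3 * 365:
        raise ValueError("scenario span must cover at least 3 years")
    rng = np.random.default_rng(scenario.seed)

    doy = dates.dayofyear.to_numpy(dtype=float)
    seasonal = scenario.mean_sst + scenario.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - scenario.peak_day) / 365.25
    )
    t_days = np.arange(n, dtype=float)
    seasonal = seasonal + scenario.trend / 3652.5 * t_days

    event_anom = np.zeros(n)
    for ev in scenario.events:
        start = pd.Timestamp(ev.start_date)
        i0 = (start - dates[0]).days
        if i0 < 0 or i0 + ev.duration > n:
            raise ValueError("event window outside scenario span")
        event_anom[i0:i0 + ev.duration] += ev.anomaly_profile()

    # AR(1) started at its stationary distribution: no burn-in artifacts.
    noise = np.zeros(n)
    if scenario.noise_sd > 0:
        innov_sd = scenario.noise_sd * np.sqrt(1.0 - scenario.ar1 ** 2)
        noise[0] = rng.normal(0.0, scenario.noise_sd)
        e = rng.normal(0.0, innov_sd, size=n)
        for t in range(1, n):
            noise[t] = scenario.ar1 * noise[t - 1] + e[t]

    sst = seasonal + event_anom + noise

    missing = _draw_gap_mask(n, scenario.gap_fraction, scenario.gap_mean_len, rng)
    sst_obs = sst.copy()
    sst_obs[missing] = np.nan
    n_pixels = np.where(missing, 0, 9)
    sst_sd = np.where(missing, np.nan, 0.1)

    series = SstSeries(site_id=scenario.site_id, dates=dates,
                       sst_mean=sst_obs, sst_sd=sst_sd, n_pixels=n_pixels)
    truth = pd.DataFrame({"seasonal": seasonal, "event_anomaly": event_anom,
                          "noise": noise}, index=dates)
    return series, truth


def _draw_gap_mask(n: int, gap_fraction: float, gap_mean_len: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Geometric-length missing runs placed uniformly, non-overlapping.

    First and last day are kept present so downstream interpolation always
    has anchors.
    """
    mask = np.zeros(n, dtype=bool)
    if gap_fraction <= 0:
        return mask
    target = int(round(gap_fraction * n))
    p = 1.0 / max(gap_mean_len, 1.0)
    placed = 0
    attempts = 0
    while placed < target and attempts < 50 * n:
        attempts += 1
        run = int(rng.geometric(p))
        run = min(run, target - placed)
        start = int(rng.integers(1, n - run - 1))
        if mask[max(start - 1, 0):start + run + 1].any():
            continue
        mask[start:start + run] = True
        placed += run
    return mask


# ---------------------------------------------------------------------------
# Velocity-field scenarios
# ---------------------------------------------------------------------------

@dataclass
class FlowScenario:
    """An analytic surface-velocity field on a regular lon/lat/day grid.

    Kinds with closed-form diagnostics (rates given per day):

    - ``uniform``: constant (u, v) m/s; zero derivatives everywhere.
    - ``solid_body``: rotation at angular rate ``omega`` about the domain
      centre; vorticity 2*omega, divergence 0, OW = -4*omega^2.
    - ``strain``: pure strain at rate ``sigma`` (u = sigma*x, v = -sigma*y);
      OW = +4*sigma^2, FTLE = sigma at any horizon.
    - ``divergent``: isotropic expansion at rate ``delta``; divergence delta.
    - ``double_gyre``: the standard time-periodic two-gyre stream function;
      no closed-form truth, used for qualitative FTLE-ridge checks.
    """

    kind: str = "uniform"
    params: dict = field(default_factory=dict)
    lon_range: tuple = (-2.0, 2.0)
    lat_range: tuple = (-2.0, 2.0)
    resolution: float = 0.25
    n_days: int = 70
    steady: bool = True

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        nlon = int(round((self.lon_range[1] - self.lon_range[0]) / self.resolution)) + 1
        nlat = int(round((self.lat_range[1] - self.lat_range[0]) / self.resolution)) + 1
        if nlon < 5 or nlat < 5:
            raise ValueError("grid must span at least 5x5 nodes")


_ANALYTIC_KINDS = ("uniform", "solid_body", "strain", "divergent")


def generate_velocity_field(scenario: FlowScenario) -> tuple[xr.Dataset, Optional[dict]]:
    """Build the gridded (time, lat, lon) u/v field plus analytic truth.

    Returns ``(field, truth)``.  For the four analytic kinds ``truth`` is a
    dict with scalars ``divergence`` and ``vorticity`` (d^-1), ``ow`` (d^-2)
    and ``ftle`` (d^-1, None when not defined in closed form); for
    ``double_gyre`` truth is None.
    """
    lon = np.arange(scenario.lon_range[0], scenario.lon_range[1] + scenario.resolution / 2,
                    scenario.resolution)
    lat = np.arange(scenario.lat_range[0], scenario.lat_range[1] + scenario.resolution / 2,
                    scenario.resolution)
    time = np.arange(scenario.n_days, dtype=float)
    lon0 = lon.mean()
    lat0 = lat.mean()
    # Local tangent-plane coordinates in metres, anchored at the domain centre.
    X, Y = np.meshgrid(
        METERS_PER_DEGREE * np.cos(np.radians(lat0)) * (lon - lon0),
        METERS_PER_DEGREE * (lat - lat0),
    )

    p = scenario.params
    kind = scenario.kind
    truth: Optional[dict] = None
    if kind == "uniform":
        u2 = np.full_like(X, p.get("u", 0.5))
        v2 = np.full_like(X, p.get("v", 0.0))
        truth = {"divergence": 0.0, "vorticity": 0.0, "ow": 0.0, "ftle": 0.0}
    elif kind == "solid_body":
        w = p.get("omega", 0.1) / SECONDS_PER_DAY
        u2, v2 = -w * Y, w * X
        om = p.get("omega", 0.1)
        truth = {"divergence": 0.0, "vorticity": 2 * om, "ow": -4 * om ** 2, "ftle": 0.0}
    elif kind == "strain":
        s = p.get("sigma", 0.1) / SECONDS_PER_DAY
        u2, v2 = s * X, -s * Y
        sg = p.get("sigma", 0.1)
        truth = {"divergence": 0.0, "vorticity": 0.0, "ow": 4 * sg ** 2, "ftle": sg}
    elif kind == "divergent":
        d = p.get("delta", 0.05) / SECONDS_PER_DAY
        u2, v2 = 0.5 * d * X, 0.5 * d * Y
        dl = p.get("delta", 0.05)
        truth = {"divergence": dl, "vorticity": 0.0, "ow": 0.0, "ftle": None}
    elif kind == "double_gyre":
        u2 = v2 = None  # time-dependent; built below
    else:
        raise ValueError(f"unknown flow kind {scenario.kind!r}")

    nt, nlat, nlon = len(time), len(lat), len(lon)
    u = np.empty((nt, nlat, nlon))
    v = np.empty((nt, nlat, nlon))
    if kind == "double_gyre":
        A = p.get("amplitude", 0.1)          # m/s
        eps = p.get("epsilon", 0.25)
        period = p.get("period", 10.0)       # days
        Lx = X.max() - X.min()
        Ly = Y.max() - Y.min()
        xs = (X - X.min()) / Lx * 2.0        # map to [0, 2] x [0, 1]
        ys = (Y - Y.min()) / Ly
        for k, t in enumerate(time):
            tt = 0.0 if scenario.steady else t
            omega_t = 2 * np.pi / period
            a = eps * np.sin(omega_t * tt)
            b = 1 - 2 * eps * np.sin(omega_t * tt)
            f = a * xs ** 2 + b * xs
            dfdx = 2 * a * xs + b
            u[k] = -np.pi * A * np.sin(np.pi * f) * np.cos(np.pi * ys)
            v[k] = np.pi * A * np.cos(np.pi * f) * np.sin(np.pi * ys) * dfdx
    else:
        for k in range(nt):
            u[k] = u2
            v[k] = v2

    field_ds = xr.Dataset(
        {"u": (("time", "lat", "lon"), u), "v": (("time", "lat", "lon"), v)},
        coords={"time": time, "lat": lat, "lon": lon},
        attrs={"units_u": "m s-1", "kind": kind},
    )
    return field_ds, truth


# ---------------------------------------------------------------------------
# Multi-source measurement tables
# ---------------------------------------------------------------------------

@dataclass
class SourceSpec:
    """Affine corruption of the truth: value = slope*truth + intercept + noise."""

    slope: float = 1.0
    intercept: float = 0.0
    noise_sd: float = 0.0
    missing_fraction: float = 0.0

    def __post_init__(self):
        if self.slope == 0:
            raise ValueError("slope must be nonzero")


@dataclass
class SourceScenario:
    """In-situ truth plus biased satellite/model renditions of one variable."""

    n: int = 200
    mean: float = 26.0
    amplitude: float = 2.0
    truth_noise_sd: float = 0.5
    satellite: SourceSpec = field(default_factory=SourceSpec)
    model: SourceSpec = field(default_factory=SourceSpec)
    insitu_missing_fraction: float = 0.0
    seed: int = 0


def generate_multisource(scenario: SourceScenario) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (truth, satellite, model) measurement tables.

    Each table is indexed by station (0..n-1) with a single ``value``
    column; satellite and model are affine corruptions of the truth with
    independent noise and missingness.
    """
    rng = np.random.default_rng(scenario.seed)
    t = np.arange(scenario.n)
    truth = (scenario.mean
             + scenario.amplitude * np.sin(2 * np.pi * t / max(scenario.n, 2))
             + rng.normal(0.0, scenario.truth_noise_sd, scenario.n))

    def corrupt(spec: SourceSpec) -> np.ndarray:
        vals = spec.slope * truth + spec.intercept
        if spec.noise_sd > 0:
            vals = vals + rng.normal(0.0, spec.noise_sd, scenario.n)
        if spec.missing_fraction > 0:
            miss = rng.random(scenario.n) < spec.missing_fraction
            vals = np.where(miss, np.nan, vals)
        return vals

    sat = corrupt(scenario.satellite)
    mod = corrupt(scenario.model)
    truth_obs = truth.copy()
    if scenario.insitu_missing_fraction > 0:
        miss = rng.random(scenario.n) < scenario.insitu_missing_fraction
        truth_obs = np.where(miss, np.nan, truth_obs)

    idx = pd.RangeIndex(scenario.n, name="station")
    return (pd.DataFrame({"value": truth_obs, "truth": truth}, index=idx),
            pd.DataFrame({"value": sat}, index=idx),
            pd.DataFrame({"value": mod}, index=idx))


# ---------------------------------------------------------------------------
# Plankton samples
# ---------------------------------------------------------------------------

def generate_plankton_sample(spectral_slope: float, n_objects: int,
                             volume_sampled: float,
                             size_range: tuple = (2.0 ** -6, 2.0 ** 6),
                             seed: int = 0,
                             net_id: str = "NET") -> PlanktonSample:
    """Draw object biovolumes from a power law pdf(s) ∝ s**spectral_slope.

    ``size_range`` bounds are in mm^3; ``volume_sampled`` in m^3.  The
    slope −1 case falls back to the log-uniform inverse CDF.  All objects
    are flagged living.
    """
    if n_objects <= 0:
        raise ValueError("n_objects must be positive")
    a, b = size_range
    if a <= 0 or b <= a:
        raise ValueError("size_range must be positive and increasing")
    if volume_sampled <= 0:
        raise ValueError("volume_sampled must be positive")
    rng = np.random.default_rng(seed)
    u = rng.random(n_objects)
    if np.isclose(spectral_slope, -1.0):
        biovol = a * (b / a) ** u
    else:
        g = spectral_slope + 1.0
        biovol = (a ** g + u * (b ** g - a ** g)) ** (1.0 / g)
    return PlanktonSample(biovolumes=biovol,
                          living=np.ones(n_objects, dtype=bool),
                          volume_sampled=volume_sampled, net_id=net_id)
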
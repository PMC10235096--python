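"""Eulerian and Lagrangian surface-flow diagnostics over station regions.

The sampled water mass of a station is modelled as a stadium shape (the
transect segment dilated by a 0.1° radius) filled with virtual particles
on a 0.01° lattice.  Five Eulerian diagnostics (absolute velocity,
kinetic energy, divergence, vorticity, Okubo-Weiss) are read from the
velocity field on the sampling day; four Lagrangian diagnostics (FTLE,
flow-network betweenness, Lagrangian divergence, retention time) follow
particles advected with fixed-step RK4 through the gridded field.

All spherical conversions use R = 6 371 000 m with longitude metres
scaled by cos(latitude); rates are reported per day (d^-1, d^-2).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

from .geo import METERS_PER_DEGREE

SECONDS_PER_DAY = 86400.0
DEFAULT_TAUS = (5, 10, 15, 20, 30, 60)
RK4_STEP_DAYS = 0.125
#: eddy membership: OW < -EDDY_OW_FACTOR * spatial std of OW that day
EDDY_OW_FACTOR = 0.2

EULERIAN_NAMES = ("Uabs", "Ekin", "EulerDiverg", "Vorticity", "OW")
LAGRANGIAN_NAMES = ("Ftle", "betw", "LagrDiverg", "RetentionTime")


# ---------------------------------------------------------------------------
# Stadium seeding
# ---------------------------------------------------------------------------

@dataclass
class StadiumSpec:
    """Transect endpoints plus the stadium radius and particle pitch (degrees)."""

    p_start: tuple
    p_end: tuple
    radius: float = 0.1
    spacing: float = 0.01

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.spacing > self.radius:
            raise ValueError("spacing must not exceed radius")


def point_segment_distance(px, py, ax, ay, bx, by):
    """Euclidean distance from points to the segment AB (flat degree metric)."""
    px, py = np.asarray(px, float), np.asarray(py, float)
    abx, aby = bx - ax, by - ay
    denom = abx * abx + aby * aby
    if denom == 0:
        return np.hypot(px - ax, py - ay)
    t = np.clip(((px - ax) * abx + (py - ay) * aby) / denom, 0.0, 1.0)
    return np.hypot(px - (ax + t * abx), py - (ay + t * aby))


def seed_stadium(spec: StadiumSpec) -> np.ndarray:
    """Particle positions (n, 2) lon/lat filling the stadium.

    The lattice has pitch ``spacing`` and is anchored at ``p_start``;
    points at distance exactly ``radius`` from the transect are included.
    """
    ax, ay = spec.p_start
    bx, by = spec.p_end
    r, h = spec.radius, spec.spacing
    lo_x, hi_x = min(ax, bx) - r, max(ax, bx) + r
    lo_y, hi_y = min(ay, by) - r, max(ay, by) + r
    i = np.arange(np.floor((lo_x - ax) / h), np.ceil((hi_x - ax) / h) + 1)
    j = np.arange(np.floor((lo_y - ay) / h), np.ceil((hi_y - ay) / h) + 1)
    X, Y = np.meshgrid(ax + i * h, ay + j * h)
    d = point_segment_distance(X.ravel(), Y.ravel(), ax, ay, bx, by)
    keep = d <= r * (1 + 1e-12)
    pts = np.column_stack([X.ravel()[keep], Y.ravel()[keep]])
    if len(pts) == 0:
        raise ValueError("stadium specification yields zero particles")
    return pts


# ---------------------------------------------------------------------------
# Eulerian diagnostics
# ---------------------------------------------------------------------------

def eulerian_fields(field: xr.Dataset, day: float) -> xr.Dataset:
    """Eulerian diagnostics on the velocity grid at one day.

    Derivatives use centred finite differences (one-sided at edges) with
    the spherical metric; divergence and vorticity are returned in d^-1,
    OW and s² in d^-2.  Missing velocities propagate to the diagnostics.
    """
    tvals = field["time"].values
    if day < tvals.min() or day > tvals.max():
        raise ValueError("day outside the velocity field time span")
    snap = field.sel(time=day, method="nearest")
    u = snap["u"].values
    v = snap["v"].values
    lon = field["lon"].values
    lat = field["lat"].values
    coslat = np.cos(np.radians(lat))[:, None]

    du_dlon = np.gradient(u, lon, axis=1)
    dv_dlon = np.gradient(v, lon, axis=1)
    du_dlat = np.gradient(u, lat, axis=0)
    dv_dlat = np.gradient(v, lat, axis=0)
    du_dx = du_dlon / (METERS_PER_DEGREE * coslat)
    dv_dx = dv_dlon / (METERS_PER_DEGREE * coslat)
    du_dy = du_dlat / METERS_PER_DEGREE
    dv_dy = dv_dlat / METERS_PER_DEGREE

    div = (du_dx + dv_dy) * SECONDS_PER_DAY
    vort = (dv_dx - du_dy) * SECONDS_PER_DAY
    s2 = ((du_dx - dv_dy) ** 2 + (dv_dx + du_dy) ** 2) * SECONDS_PER_DAY ** 2
    ow = s2 - vort ** 2

    return xr.Dataset(
        {"Uabs": (("lat", "lon"), np.hypot(u, v)),
         "Ekin": (("lat", "lon"), 0.5 * (u ** 2 + v ** 2)),
         "EulerDiverg": (("lat", "lon"), div),
         "Vorticity": (("lat", "lon"), vort),
         "OW": (("lat", "lon"), ow),
         "s2": (("lat", "lon"), s2)},
        coords={"lat": lat, "lon": lon})


def _stack_diagnostic(field: xr.Dataset, name: str) -> xr.DataArray:
    """A diagnostic computed for every day of the field, as (time, lat, lon)."""
    days = field["time"].values
    arr = np.stack([eulerian_fields(field, d)[name].values for d in days])
    return xr.DataArray(arr, coords={"time": days, "lat": field["lat"].values,
                                     "lon": field["lon"].values},
                        dims=("time", "lat", "lon"))


# ---------------------------------------------------------------------------
# Advection
# ---------------------------------------------------------------------------

class VelocityInterpolator:
    """Bilinear-in-space, linear-in-time lookup of (u, v) in m/s."""

    def __init__(self, field: xr.Dataset):
        t = field["time"].values.astype(float)
        lat = field["lat"].values
        lon = field["lon"].values
        self.t_range = (t.min(), t.max())
        self.lon_range = (lon.min(), lon.max())
        self.lat_range = (lat.min(), lat.max())
        self._u = RegularGridInterpolator((t, lat, lon), field["u"].values,
                                          bounds_error=False, fill_value=np.nan)
        self._v = RegularGridInterpolator((t, lat, lon), field["v"].values,
                                          bounds_error=False, fill_value=np.nan)

    def __call__(self, t: float, lons: np.ndarray, lats: np.ndarray):
        t = np.clip(t, *self.t_range)
        pts = np.column_stack([np.full_like(lons, t), lats, lons])
        return self._u(pts), self._v(pts)

    def in_domain(self, lons, lats):
        return ((lons >= self.lon_range[0]) & (lons <= self.lon_range[1]) &
                (lats >= self.lat_range[0]) & (lats <= self.lat_range[1]))


@dataclass
class TrajectorySet:
    """Daily particle positions over [t0, t0 ± tau].

    ``lons``/``lats`` have shape (tau+1, n); row k is the position after k
    days of advection (away from t0 for backward runs).  ``first_bad`` is
    the day index at which a particle beached or left the domain (tau+1
    when it never did); frozen particles keep their last position.
    """

    times: np.ndarray
    lons: np.ndarray
    lats: np.ndarray
    direction: str
    tau: int
    status: np.ndarray            # 'ok' | 'beached' | 'left_domain'
    first_bad: np.ndarray

    def ok_through(self, tau: int) -> np.ndarray:
        return self.first_bad > tau


def advect(particles: np.ndarray, field: xr.Dataset, t0: float, tau: int,
           direction: str = "backward", step: float = RK4_STEP_DAYS) -> TrajectorySet:
    """Fixed-step RK4 advection through the gridded velocity field.

    Particles whose velocity lookup fails (missing cell or outside the
    domain) are frozen at their last position and flagged.  Positions are
    stored at daily resolution.
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    sgn = 1.0 if direction == "forward" else -1.0
    interp = VelocityInterpolator(field)
    t_end = t0 + sgn * tau
    if not (interp.t_range[0] - 0.5 <= min(t0, t_end) and
            max(t0, t_end) <= interp.t_range[1] + 0.5):
        raise ValueError("required advection window outside the field time span")

    n = len(particles)
    lons = particles[:, 0].astype(float).copy()
    lats = particles[:, 1].astype(float).copy()
    steps_per_day = int(round(1.0 / step))
    out_lon = np.empty((tau + 1, n))
    out_lat = np.empty((tau + 1, n))
    out_lon[0], out_lat[0] = lons, lats
    active = np.ones(n, dtype=bool)
    first_bad = np.full(n, tau + 1, dtype=int)
    status = np.full(n, "ok", dtype=object)

    def deg_velocity(t, lo, la):
        u, v = interp(t, lo, la)
        dlon = u * SECONDS_PER_DAY / (METERS_PER_DEGREE * np.cos(np.radians(la)))
        dlat = v * SECONDS_PER_DAY / METERS_PER_DEGREE
        return dlon, dlat

    for day in range(tau):
        for s in range(steps_per_day):
            if not active.any():
                break
            t = t0 + sgn * (day + s * step)
            h = sgn * step
            lo, la = lons[active], lats[active]
            k1x, k1y = deg_velocity(t, lo, la)
            k2x, k2y = deg_velocity(t + h / 2, lo + h / 2 * k1x, la + h / 2 * k1y)
            k3x, k3y = deg_velocity(t + h / 2, lo + h / 2 * k2x, la + h / 2 * k2y)
            k4x, k4y = deg_velocity(t + h, lo + h * k3x, la + h * k3y)
            dx = h / 6 * (k1x + 2 * k2x + 2 * k3x + k4x)
            dy = h / 6 * (k1y + 2 * k2y + 2 * k3y + k4y)
            bad = ~np.isfinite(dx) | ~np.isfinite(dy)
            idx = np.flatnonzero(active)
            if bad.any():
                dead = idx[bad]
                first_bad[dead] = day + 1
                # beached = inside the domain on a missing-velocity cell;
                # otherwise the particle (or its RK4 lookahead) left the grid
                u_here, _ = interp(t, lons[dead], lats[dead])
                inside = interp.in_domain(lons[dead], lats[dead])
                beached = inside & ~np.isfinite(u_here)
                status[dead] = np.where(beached, "beached", "left_domain")
                active[dead] = False
            good = idx[~bad]
            lons[good] += dx[~bad]
            lats[good] += dy[~bad]
        out_lon[day + 1], out_lat[day + 1] = lons, lats

    times = t0 + sgn * np.arange(tau + 1)
    return TrajectorySet(times=times, lons=out_lon, lats=out_lat,
                         direction=direction, tau=tau, status=status,
                         first_bad=first_bad)


# ---------------------------------------------------------------------------
# Lagrangian diagnostics
# ---------------------------------------------------------------------------

def ftle(particles: np.ndarray, field: xr.Dataset, t0: float,
         taus: Sequence[int], spacing: float = 0.01,
         direction: str = "backward") -> dict[int, np.ndarray]:
    """Finite-time Lyapunov exponents (d^-1) per particle, per horizon.

    Each particle carries an auxiliary cross of four points at ±spacing
    in lon and lat; the flow-map gradient comes from central differences
    of the advected cross endpoints (in metres), and
    FTLE = ln(largest eigenvalue of FᵀF) / (2·tau).  A particle whose
    cross loses any point by time tau has missing FTLE there.
    """
    taus = sorted(taus)
    n = len(particles)
    lon0, lat0 = particles[:, 0], particles[:, 1]
    aux = np.concatenate([
        np.column_stack([lon0 + spacing, lat0]),
        np.column_stack([lon0 - spacing, lat0]),
        np.column_stack([lon0, lat0 + spacing]),
        np.column_stack([lon0, lat0 - spacing]),
    ])
    traj = advect(aux, field, t0, max(taus), direction=direction)
    dx0 = 2 * spacing * METERS_PER_DEGREE * np.cos(np.radians(lat0))
    dy0 = 2 * spacing * METERS_PER_DEGREE

    out: dict[int, np.ndarray] = {}
    for tau in taus:
        ok = traj.ok_through(tau).reshape(4, n).all(axis=0)
        lo = traj.lons[tau].reshape(4, n)
        la = traj.lats[tau].reshape(4, n)
        coslat_f = np.cos(np.radians(la.mean(axis=0)))
        # columns of the flow-map gradient F, metres per metre
        f11 = (lo[0] - lo[1]) * METERS_PER_DEGREE * coslat_f / dx0
        f21 = (la[0] - la[1]) * METERS_PER_DEGREE / dx0
        f12 = (lo[2] - lo[3]) * METERS_PER_DEGREE * coslat_f / dy0
        f22 = (la[2] - la[3]) * METERS_PER_DEGREE / dy0
        c11 = f11 ** 2 + f21 ** 2
        c22 = f12 ** 2 + f22 ** 2
        c12 = f11 * f12 + f21 * f22
        tr2 = 0.5 * (c11 + c22)
        disc = np.sqrt(np.maximum(tr2 ** 2 - (c11 * c22 - c12 ** 2), 0.0))
        lam_max = np.maximum(tr2 + disc, 1e-300)
        vals = np.log(lam_max) / (2.0 * tau)
        vals[~ok] = np.nan
        out[tau] = vals
    return out


def lagrangian_divergence(traj: TrajectorySet, field: xr.Dataset,
                          tau: Optional[int] = None) -> np.ndarray:
    """Time-mean Eulerian divergence along each trajectory (d^-1).

    Trapezoidal integration over the stored daily positions divided by
    the horizon, so a constant divergence field returns that constant.
    Particles lost before ``tau`` are missing.
    """
    tau = traj.tau if tau is None else tau
    div = _stack_diagnostic(field, "EulerDiverg")
    t = div["time"].values.astype(float)
    interp = RegularGridInterpolator(
        (t, div["lat"].values, div["lon"].values), div.values,
        bounds_error=False, fill_value=np.nan)
    n = traj.lons.shape[1]
    samples = np.empty((tau + 1, n))
    for k in range(tau + 1):
        tk = np.clip(traj.times[k], t.min(), t.max())
        pts = np.column_stack([np.full(n, tk), traj.lats[k], traj.lons[k]])
        samples[k] = interp(pts)
    vals = np.trapezoid(samples, dx=1.0, axis=0) / tau
    vals[~traj.ok_through(tau)] = np.nan
    return vals


def retention_time(particles: np.ndarray, field: xr.Dataset, t0: float,
                   window: int = 60,
                   eddy_factor: float = EDDY_OW_FACTOR) -> np.ndarray:
    """Days each water parcel has spent inside an eddy, counted backward.

    Eddy membership at each backward daily step: OW at the parcel position
    is below -eddy_factor times the spatial SD of OW over the domain that
    day.  The count stops at the first day outside an eddy; a parcel
    outside at t0 gets zero; the value is capped at ``window``.
    """
    traj = advect(particles, field, t0, window, direction="backward")
    ow = _stack_diagnostic(field, "OW")
    t = ow["time"].values.astype(float)
    interp = RegularGridInterpolator(
        (t, ow["lat"].values, ow["lon"].values), ow.values,
        bounds_error=False, fill_value=np.nan)
    sigma_by_day = {float(d): float(np.nanstd(ow.sel(time=d).values))
                    for d in t}

    n = len(particles)
    retention = np.zeros(n)
    counting = np.ones(n, dtype=bool)
    for k in range(window + 1):
        tk = float(np.clip(traj.times[k], t.min(), t.max()))
        nearest_day = t[np.argmin(np.abs(t - tk))]
        pts = np.column_stack([np.full(n, tk), traj.lats[k], traj.lons[k]])
        ow_here = interp(pts)
        thresh = -eddy_factor * sigma_by_day[float(nearest_day)]
        in_eddy = np.isfinite(ow_here) & (ow_here < thresh) & (traj.first_bad > k)
        counting &= in_eddy
        if k > 0:
            retention[counting] += 1.0
        elif not counting.any():
            break
    return np.minimum(retention, window)


# ---------------------------------------------------------------------------
# Flow-network betweenness
# ---------------------------------------------------------------------------

def betweenness_from_transitions(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Node betweenness Σ_{a,b} P1(a→m)·P2(m→b), normalized to sum 1.

    ``p1`` carries origin→node transition probabilities of the first
    advection leg, ``p2`` node→destination probabilities of the second.
    """
    inflow = p1.sum(axis=0)
    outflow = p2.sum(axis=1)
    btw = inflow * outflow
    total = btw.sum()
    if total <= 0:
        raise ValueError("empty flow network: no mass passes through any node")
    return btw / total


@dataclass
class BetweennessMap:
    lon_edges: np.ndarray
    lat_edges: np.ndarray
    values: np.ndarray            # (nlat_boxes, nlon_boxes), sums to 1

    def lookup(self, lons, lats) -> np.ndarray:
        i = np.clip(np.searchsorted(self.lat_edges, lats, side="right") - 1,
                    0, self.values.shape[0] - 1)
        j = np.clip(np.searchsorted(self.lon_edges, lons, side="right") - 1,
                    0, self.values.shape[1] - 1)
        return self.values[i, j]


def flow_network_betweenness(field: xr.Dataset, t0: float, tau: int,
                             node_size: Optional[float] = None) -> BetweennessMap:
    """Two-leg Lagrangian betweenness centred on the sampling day.

    The domain is binned into ``node_size`` boxes (default: the velocity
    grid resolution).  One particle per box is advected t0-τ/2 → t0
    (leg 1, giving P1) and t0 → t0+τ/2 (leg 2, giving P2); a node's
    betweenness is the product of its leg-1 inflow and leg-2 outflow,
    normalized over nodes.
    """
    lon = field["lon"].values
    lat = field["lat"].values
    if node_size is None:
        node_size = float(lon[1] - lon[0])
    lon_edges = np.arange(lon.min(), lon.max() + node_size / 2, node_size)
    lat_edges = np.arange(lat.min(), lat.max() + node_size / 2, node_size)
    cx = (lon_edges[:-1] + lon_edges[1:]) / 2
    cy = (lat_edges[:-1] + lat_edges[1:]) / 2
    CX, CY = np.meshgrid(cx, cy)
    seeds = np.column_stack([CX.ravel(), CY.ravel()])
    n_nodes = len(seeds)
    if n_nodes == 0:
        raise ValueError("empty flow network: no nodes in domain")

    def box_index(lons, lats):
        i = np.searchsorted(lat_edges, lats, side="right") - 1
        j = np.searchsorted(lon_edges, lons, side="right") - 1
        ok = (i >= 0) & (i < len(cy)) & (j >= 0) & (j < len(cx))
        return np.where(ok, i * len(cx) + j, -1)

    half = tau / 2.0
    leg1 = advect(seeds, field, t0 - half, int(np.ceil(half)), direction="forward")
    leg2 = advect(seeds, field, t0, int(np.ceil(half)), direction="forward")
    k = int(np.ceil(half))

    p1 = np.zeros((n_nodes, n_nodes))
    dest1 = box_index(leg1.lons[k], leg1.lats[k])
    ok1 = leg1.ok_through(k) & (dest1 >= 0)
    p1[np.flatnonzero(ok1), dest1[ok1]] = 1.0

    p2 = np.zeros((n_nodes, n_nodes))
    dest2 = box_index(leg2.lons[k], leg2.lats[k])
    ok2 = leg2.ok_through(k) & (dest2 >= 0)
    p2[np.flatnonzero(ok2), dest2[ok2]] = 1.0

    btw = betweenness_from_transitions(p1, p2)
    return BetweennessMap(lon_edges=lon_edges, lat_edges=lat_edges,
                          values=btw.reshape(len(cy), len(cx)))


# ---------------------------------------------------------------------------
# Station assembly
# ---------------------------------------------------------------------------

def _summary(values: np.ndarray, n_total: int) -> dict:
    vals = values[np.isfinite(values)]
    n_ok = len(vals)
    if n_ok < 4 or n_ok < 0.5 * n_total:
        return {"mean": np.nan, "p25": np.nan, "p50": np.nan, "p75": np.nan,
                "n_ok": n_ok}
    return {"mean": float(vals.mean()),
            "p25": float(np.percentile(vals, 25)),
            "p50": float(np.percentile(vals, 50)),
            "p75": float(np.percentile(vals, 75)),
            "n_ok": n_ok}


def station_diagnostics(spec: StadiumSpec, field: xr.Dataset, t0: float,
                        taus: Sequence[int] = DEFAULT_TAUS,
                        node_size: Optional[float] = None,
                        station_id: str = "OA000") -> pd.DataFrame:
    """Mean/p25/p50/p75 of every diagnostic over the stadium particles.

    Eulerian diagnostics are sampled at the particle positions on the
    sampling day and do not depend on the advective time; Lagrangian
    diagnostics are computed for each tau; retention time only at the
    largest tau.  Statistics are withheld (NaN) when fewer than 4
    particles survive or more than half are lost.
    """
    taus = sorted(taus)
    particles = seed_stadium(spec)
    n = len(particles)
    rows = []

    eul = eulerian_fields(field, t0)
    for name in EULERIAN_NAMES:
        da = eul[name]
        interp = RegularGridInterpolator(
            (da["lat"].values, da["lon"].values), da.values,
            bounds_error=False, fill_value=np.nan)
        vals = interp(np.column_stack([particles[:, 1], particles[:, 0]]))
        rows.append({"station": station_id, "diagnostic": name,
                     "tau_days": 0, **_summary(vals, n)})

    traj = advect(particles, field, t0, max(taus), direction="backward")
    ftle_by_tau = ftle(particles, field, t0, taus, spacing=spec.spacing)
    for tau in taus:
        rows.append({"station": station_id, "diagnostic": "Ftle",
                     "tau_days": tau, **_summary(ftle_by_tau[tau], n)})
        ld = lagrangian_divergence(traj, field, tau=tau)
        rows.append({"station": station_id, "diagnostic": "LagrDiverg",
                     "tau_days": tau, **_summary(ld, n)})
        bmap = flow_network_betweenness(field, t0, tau, node_size=node_size)
        bvals = bmap.lookup(particles[:, 0], particles[:, 1])
        rows.append({"station": station_id, "diagnostic": "betw",
                     "tau_days": tau, **_summary(bvals, n)})
    rt = retention_time(particles, field, t0, window=max(taus))
    rows.append({"station": station_id, "diagnostic": "RetentionTime",
                 "tau_days": max(taus), **_summary(rt, n)})

    out = pd.DataFrame(rows)
    if out["n_ok"].max() == 0:
        raise ValueError("all particles lost; no diagnostics available")
    return out
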
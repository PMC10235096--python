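# Methods

This note records the models, conventions and numerical choices behind each
stage, what the synthetic generators do and do not emulate, and the known
limitations.

## Thermal-stress indices

**Climatology.** The seasonal cycle is the per-day-of-year mean of the daily
SST record, on a 366-bin calendar: Feb 29 is bin 60 and is averaged over leap
years only; in non-leap years days after Feb 28 shift by one bin so that
Mar 1 is always bin 61. If the record contains no leap-year Feb 29 at all,
bin 60 is filled from its neighbours (the alternative — refusing to build a
climatology from a 3-year non-leap span — would make the minimum-span
contract unusable). Any other empty bin is an error: the caller must
pre-interpolate across day-of-year bins.

The 366-value cycle is triplicated and concatenated before filtering so the
zero-phase filter sees no year-boundary edge; the middle copy is extracted
afterwards. The filter is a Chebyshev type-I IIR, order 3, 0.1 dB passband
ripple, cutoff 1/36 cycles day⁻¹, applied forward–backward (`filtfilt`).
"Passband ripple" pins the family to Chebyshev I; the 36-day figure is read
as the cutoff period. A consequence worth knowing: because a Chebyshev
passband ripples by construction, the zero-phase gain at the annual frequency
is ≈ 0.998, so rebuilding a climatology from its own output moves a 2 °C
cycle by up to ~8 mK. The test suite checks idempotence exactly for a
constant cycle and at a ripple-derived 0.5%-of-amplitude tolerance otherwise.

**Weekly climatologies** are the 52 contiguous 7-day bin means of the
filtered cycle, with bin 52 absorbing days 358–366; their extremes are the
heat and cold stress reference levels. Contiguous weeks follow the CoRTAD
convention; the binning rule is otherwise free.

**Indices.** Missing SST and anomaly values are linearly interpolated
(interior gaps only; leading/trailing stay missing); gap statistics include
the 95th percentile of consecutive-missing run lengths. "Past 52 weeks" is a
trailing 364-day window inclusive of the current day; "past 12 weeks" an
84-day window. DHW/DCW divide the windowed sum of qualifying TSA by 7, giving
°C-weeks (the CoRTAD unit; the ±1 °C qualification is applied per day before
summation). The cold-side DCW frequency counts days with DCW ≤ −1 °C-weeks,
by symmetry with the heat side. Days whose full dependency chain
(364 + 84 − 2 days) precedes the series start are flagged burn-in and
excluded from site summaries.

**Event-magnitude recovery.** A square heat wave of amplitude A over D days
accumulates max DHW = A·D/7 when TSA equals A throughout — which requires the
reference climatology to be uncontaminated by the event itself. A climatology
built from a record containing the event absorbs part of it (≈ A·D_years⁻¹ in
the event weeks, ~0.1 °C for a 2 °C × 28 d event in a 15-year record),
lowering max DHW to ~7.6 °C-weeks. The recovery check therefore builds the
climatology from an event-free realization of the same scenario; the
contaminated path is still verified exactly against the brute-force oracle.
By default the climatology includes all data up to the sampling date,
matching operational practice.

**Percentiles** everywhere interpolate linearly between closest order
statistics (numpy's default).

## Flow diagnostics

**Geometry.** Spherical Earth, R = 6 371 000 m; metres per degree longitude
scale with cos(latitude). Stadium membership (distance to the transect
segment ≤ 0.1°) is evaluated in degree space with the lattice anchored at the
transect start; boundary ties are included. Note the inclusive lattice makes
the particle count exceed the continuum area estimate by ~spacing/(2·radius).

**Eulerian fields.** Centred finite differences (one-sided at edges) of u, v
on the grid, converted to d⁻¹ (×86 400) and d⁻² for OW = s² − ζ² with
s² = (∂u/∂x − ∂v/∂y)² + (∂v/∂x + ∂u/∂y)². Missing velocities propagate.

**Advection.** Fixed-step RK4, 0.125 d per step, bilinear spatial and linear
temporal velocity interpolation; positions stored daily. The step is far
below the grid-crossing time of ≤ 2 m/s surface flows. Particles whose
velocity lookup fails are frozen and classified beached (inside the domain on
a missing cell) or left-domain; station statistics are withheld when fewer
than 4 particles survive or more than half are lost.

**FTLE.** Each particle carries a cross of four auxiliary points at ±0.01°;
after backward advection over τ the flow-map gradient F comes from central
differences of the endpoints in metres and FTLE = ln λmax(FᵀF)/(2τ). Backward
advection is the default (it marks boundaries between waters of different
origin); forward is available. A lost auxiliary point voids that particle's
FTLE.

**Lagrangian divergence** is the trapezoidal time-mean of the Eulerian
divergence sampled along the backward trajectory (integral divided by τ), so
the unit stays d⁻¹ and a constant-divergence field returns that constant.

**Retention time** counts consecutive backward days the parcel satisfies
OW < −0.2·σ_OW, where σ_OW is the spatial standard deviation of OW over the
domain that day (a widespread Okubo–Weiss eddy criterion); zero if outside at
the sampling day, capped at the 60-day window.

**Betweenness** uses a two-leg path-probability construction: one particle
per grid box advected from t−τ/2 to t (leg 1) and from t to t+τ/2 (leg 2);
a node's betweenness is Σ_{a,b} P1(a→m)·P2(m→b) — its leg-1 inflow times its
leg-2 outflow — normalized to sum 1 over nodes. This keeps the "circulation
bottleneck" semantics while remaining exactly brute-forceable; it is a
deliberate simplification of full flow-network centralities.

## Context merging

Lags are signed: dt = sample time − context time (fractional days), dz
positive when the sample is deeper; dxy is the haversine distance. The lags
reported with an aggregation are those of the nearest contributing record,
nearest in |dt| with ties broken by dxy then |dz|.

Bias correction regresses the source on the in-situ reference (OLS) and
inverts with corrected = (source − intercept)/slope — the exact inverse of
the fitted affine bias; the alternative order (divide, then subtract) is
available behind a flag since the verbal prescription is ambiguous. A
correction is accepted only when r ≥ 0.5, slope ∈ [0.33, 3] and n ≥ 10;
these thresholds are this package's operationalization of "dropped when
large bias persisted". Merging takes the first non-missing value in priority
order (in-situ sample, in-situ sensor, satellite, model), never overwrites
in-situ data, and records provenance per value.

Station grouping is greedy centroid linkage in time order (≤ 75 km and
≤ 0.25 d to the open station's centroid); isolated non-systematic events
map to station 0. Island annotation takes the nearest island within 200
nautical miles (370.4 km), ties toward the lower code. Buffer extraction
uses the (2b+1)×(2b+1) window centred on the containing pixel, excluding
missing pixels; the 2- and 12-pixel windows are reported side by side
(the wide window is the cloud fallback).

## Size spectra

NBSS bins are log2-spaced in biovolume anchored at 2⁰ mm³ (standard NBSS
practice); per bin the summed living biovolume is divided by bin width and
sampled volume. Slope fitting excludes bins with fewer than 5 objects, whose
log-counts are noise-dominated. For biovolumes drawn from a power-law pdf
∝ s^k the expected NBSS slope is k + 1. Only theoretical tow volumes are
supported; flowmeter readings are out of scope by design.

## Synthetic generators

The SST generator composes seasonal sinusoid (period 365.25 d), linear trend
(°C/decade), AR(1) noise initialized at its stationary distribution
(noise_sd is the marginal SD) and additive events; square events add the full
amplitude, triangular events ramp linearly and symmetrically to the amplitude
at the window midpoint. Gaps are geometric-length runs placed uniformly
without overlap, keeping the first and last day present. The generator does
not emulate cloud masks, orbital sampling, platform offsets, or
non-stationary noise — so passing tests demonstrate the index algebra and
filtering, not robustness to realistic satellite artifacts.

Velocity fields are built on a local tangent plane anchored at the domain
centre, which makes the four analytic kinds exact at the centre latitude and
accurate to O(1 − cosφ/cosφ₀) away from it; default domains sit at the
equator with small extent, keeping the analytic-truth error below the 1e-3
tolerances used in tests. The double-gyre uses the standard time-periodic
stream function and claims no closed-form truth. Multi-source tables are
affine corruptions of a smooth truth; plankton samples draw from a bounded
power law by inverse CDF with a log-uniform special case at exponent −1.

## Orchestration and problem sizes

All stage seeds derive from one master seed (SeedSequence splits), manifests
record versions, seeds and parameters, and reruns are byte-identical. Tables
are UTF-8 TSV; missing tokens nav/npr/nac/nap round-trip literally. Velocity
grids are stored as NetCDF3 via xarray's scipy backend, which covers the
(lon, lat, time, u, v) layout used here.

Default study sizes: 15–20-year daily SST records; 0.25° velocity grids of a
few degrees' extent over 70 days; stadium spacing 0.01° (≈ 3–6 × 10³
particles per station; examples use 0.02–0.05° for quick runs); 200-station
source tables; 10⁴-object plankton samples. These sizes were chosen so every
ground-truth comparison is tight while a full run of all stages completes in
seconds.

## Known limitations

- Land handling is reduced to freezing beached particles; no coastline data.
- The betweenness and retention-time diagnostics implement the definitions
  stated above, not full reimplementations of the original flow-network and
  eddy-tracking methods they are inspired by.
- The climatology is not robust to multi-month data deserts (empty
  day-of-year bins error out rather than guessing).
- Bias correction is a single global affine fit per source; no seasonal or
  regional stratification.
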
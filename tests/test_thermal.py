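"""Thermal-stress index chain against brute-force and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest

from oceanstations.synth import SstScenario, ThermalEvent, generate_sst_series
from oceanstations.thermal import (SstSeries, assemble_indices, build_climatology,
                                   compute_anomaly, daily_average_pixels,
                                   day_of_year_366, degree_weeks, fill_gaps,
                                   match_reefcheck, missing_run_lengths,
                                   rolling_exceedance_count, summarize_site)


def make_series(values, start="2002-01-01", site="S"):
    values = np.asarray(values, dtype=float)
    dates = pd.date_range(start, periods=len(values), freq="D")
    return SstSeries(site_id=site, dates=dates, sst_mean=values,
                     sst_sd=np.full(len(values), np.nan),
                     n_pixels=np.where(np.isnan(values), 0, 9))


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_count(values, threshold, direction, window=364):
    out = np.zeros(len(values))
    for i in range(len(values)):
        w = values[max(0, i - window + 1):i + 1]
        w = w[~np.isnan(w)]
        out[i] = (w >= threshold).sum() if direction == "ge" else (w <= threshold).sum()
    return out


def brute_degree_weeks(tsa, mode, window=84):
    out = np.zeros(len(tsa))
    for i in range(len(tsa)):
        w = tsa[max(0, i - window + 1):i + 1]
        w = w[~np.isnan(w)]
        if mode == "heat":
            out[i] = w[w >= 1.0].sum() / 7.0
        else:
            out[i] = w[w <= -1.0].sum() / 7.0
    return out


# ---------------------------------------------------------------------------
# pixel pooling
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("pixels,mean,sd", [
    ([25.0, 25.0, 25.0], 25.0, 0.0),
    ([24.0, 26.0], 25.0, np.std([24.0, 26.0], ddof=1)),
])
def test_daily_average_pixels_pools_mean_and_sample_sd(pixels, mean, sd):
    rec = pd.DataFrame({"date": ["2010-01-01"] * len(pixels), "value": pixels})
    series = daily_average_pixels(rec)
    assert series.sst_mean[0] == pytest.approx(mean)
    assert series.sst_sd[0] == pytest.approx(sd)


def test_daily_average_pixels_empty_day_missing():
    rec = pd.DataFrame({"date": ["2010-01-01", "2010-01-03"], "value": [25.0, 26.0]})
    series = daily_average_pixels(rec)
    assert np.isnan(series.sst_mean[1]) and series.n_pixels[1] == 0


# ---------------------------------------------------------------------------
# climatology
# ---------------------------------------------------------------------------

def test_climatology_of_constant_series_is_constant():
    series = make_series(np.full(5 * 366, 26.5))
    clim = build_climatology(series)
    np.testing.assert_allclose(clim.seasonal_cycle, 26.5, atol=1e-9)
    assert clim.max_weekly_clim == pytest.approx(26.5)
    assert clim.min_weekly_clim == pytest.approx(26.5)


def test_climatology_preserves_annual_sinusoid():
    sc = SstScenario(noise_sd=0.0, seasonal_amplitude=2.0)
    series, truth = generate_sst_series(sc)
    clim = build_climatology(series)
    doy = day_of_year_366(series.dates)
    dev = clim.seasonal_cycle[doy - 1] - truth["seasonal"].to_numpy()
    assert np.abs(dev).max() < 0.05 * sc.seasonal_amplitude


def test_climatology_suppresses_white_noise():
    sc = SstScenario(start_date="2002-01-01", end_date="2016-12-31",
                     noise_sd=1.0, ar1=0.0, seed=21)
    series, truth = generate_sst_series(sc)
    clim = build_climatology(series)
    doy = day_of_year_366(series.dates)
    dev = clim.seasonal_cycle[doy - 1] - truth["seasonal"].to_numpy()
    assert np.abs(dev).max() < 3.0 / np.sqrt(15)


def test_climatology_idempotent_on_own_cycle():
    """Rebuilding from the filtered cycle leaves it unchanged up to the
    filter's passband ripple (exactly so for a constant cycle)."""
    flat = build_climatology(make_series(np.full(5 * 366, 26.5)))
    dates = pd.date_range("2004-01-01", "2011-12-31", freq="D")  # leap-anchored
    doy = day_of_year_366(dates)
    replay = SstSeries("S", dates, flat.seasonal_cycle[doy - 1],
                       np.full(len(dates), np.nan), np.full(len(dates), 9))
    np.testing.assert_allclose(build_climatology(replay).seasonal_cycle,
                               flat.seasonal_cycle, atol=1e-9)

    sc = SstScenario(noise_sd=0.0, seasonal_amplitude=2.0)
    series, _ = generate_sst_series(sc)
    clim = build_climatology(series)
    replay = SstSeries("S", dates, clim.seasonal_cycle[doy - 1],
                       np.full(len(dates), np.nan), np.full(len(dates), 9))
    clim2 = build_climatology(replay)
    # zero-phase Chebyshev-I gain at the annual frequency is ~0.998: each
    # refiltering may move the cycle by up to ~0.5% of its amplitude
    np.testing.assert_allclose(clim2.seasonal_cycle, clim.seasonal_cycle,
                               atol=0.005 * sc.seasonal_amplitude)


def test_empty_day_of_year_bin_is_an_error():
    values = np.full(4 * 366, 26.0)
    series = make_series(values)
    mask = day_of_year_366(series.dates) == 100
    values[mask] = np.nan
    with pytest.raises(ValueError, match="day-of-year"):
        build_climatology(make_series(values))


def test_anomaly_identity_and_injection(noisy_sst):
    series, _ = noisy_sst
    clim = build_climatology(series)
    anom = compute_anomaly(series, clim)
    present = ~np.isnan(series.sst_mean)
    np.testing.assert_allclose(anom[present] + clim.cycle_for(series.dates)[present],
                               series.sst_mean[present], atol=1e-12)


def test_triangular_event_peak_recovered_in_anomaly():
    sc = SstScenario(start_date="2002-01-01", end_date="2021-12-31",
                     noise_sd=0.0,
                     events=[ThermalEvent("2015-07-01", 7, 3.0, "triangular")])
    series, _ = generate_sst_series(sc)
    anom = compute_anomaly(series, build_climatology(series))
    assert abs(np.nanmax(anom) - 3.0) <= 0.05


# ---------------------------------------------------------------------------
# gap filling
# ---------------------------------------------------------------------------

def test_fill_gaps_linear_and_statistics():
    filled, _ = fill_gaps(np.array([10.0, np.nan, 12.0]))
    assert filled[1] == pytest.approx(11.0)
    filled, _ = fill_gaps(np.array([10.0, np.nan, np.nan, np.nan, np.nan, 20.0]))
    np.testing.assert_allclose(filled[1:5], [12.0, 14.0, 16.0, 18.0])

    v = np.ones(40)
    for start, ln in [(1, 1), (5, 1), (10, 2), (15, 5), (25, 9)]:
        v[start:start + ln] = np.nan
    _, stats = fill_gaps(v)
    assert sorted(stats.run_lengths.tolist()) == [1, 1, 2, 5, 9]
    assert stats.p95 == pytest.approx(np.percentile([1, 1, 2, 5, 9], 95))


def test_fill_gaps_keeps_boundary_missing_and_rejects_all_missing():
    filled, _ = fill_gaps(np.array([np.nan, 5.0, np.nan, 7.0, np.nan]))
    assert np.isnan(filled[0]) and np.isnan(filled[-1])
    assert filled[2] == pytest.approx(6.0)
    with pytest.raises(ValueError, match="all-missing"):
        fill_gaps(np.array([np.nan, np.nan]))


def test_missing_run_lengths_counts_boundary_runs():
    v = np.array([np.nan, np.nan, 1.0, np.nan, 1.0, np.nan, np.nan, np.nan])
    assert sorted(missing_run_lengths(v).tolist()) == [1, 2, 3]


# ---------------------------------------------------------------------------
# rolling indices
# ---------------------------------------------------------------------------

def test_exceedance_count_saturates_and_zeroes():
    n = 800
    counts = rolling_exceedance_count(np.full(n, 2.0), 1.0, "ge")
    assert counts[-1] == 364 and counts[0] == 1
    assert rolling_exceedance_count(np.zeros(n), 1.0, "ge").max() == 0


def test_exceedance_plateau_matches_brute_force():
    v = np.zeros(900)
    v[100:110] = 2.0
    counts = rolling_exceedance_count(v, 1.0, "ge")
    np.testing.assert_array_equal(counts, brute_count(v, 1.0, "ge"))
    assert counts[109] == 10 and counts[400] == 10 and counts[600] == 0


@pytest.mark.parametrize("mode,tsa,day,expect", [
    ("heat", ("block", 2.0, 14), 13, 4.0),       # 2*14/7
    ("heat", ("const", 0.9, 0), -1, 0.0),        # below threshold
    ("cold", ("block", -1.5, 7), 6, -1.5),       # -1.5*7/7
])
def test_degree_weeks_examples(mode, tsa, day, expect):
    kind, amp, ln = tsa
    v = np.full(200, amp) if kind == "const" else np.zeros(200)
    if kind == "block":
        v[:ln] = amp
    dw = degree_weeks(v, mode=mode)
    assert dw[day] == pytest.approx(expect)
    np.testing.assert_allclose(dw, brute_degree_weeks(v, mode), atol=1e-9)


# ---------------------------------------------------------------------------
# assembled indices
# ---------------------------------------------------------------------------

def test_flat_climatology_gives_tsa_equal_anomaly(flat_sst):
    """With a flat reference climatology the TSA reduces to the anomaly."""
    series, _ = flat_sst
    ref, _ = generate_sst_series(SstScenario(
        start_date="2002-01-01", end_date="2016-12-31",
        seasonal_amplitude=0.0, noise_sd=0.0, seed=1))
    idx = assemble_indices(series, clim=build_climatology(ref))
    f = idx.frame
    np.testing.assert_allclose(f["TSA_heat"], f["SST_anomaly_interpl"], atol=1e-9)
    event = f.loc["2015-04-01":"2015-04-28", "TSA_heat"]
    np.testing.assert_allclose(event, 2.0, atol=1e-9)


def test_full_indices_match_brute_force(noisy_sst):
    series, _ = noisy_sst
    idx = assemble_indices(series)
    f = idx.frame
    sst = f["SST_mean_interpl"].to_numpy()
    clim = idx.climatology
    tsa_heat = sst - clim.max_weekly_clim
    tsa_cold = sst - clim.min_weekly_clim
    anom = sst - clim.cycle_for(series.dates)
    np.testing.assert_allclose(f["TSA_heat"], tsa_heat, atol=1e-12)
    np.testing.assert_allclose(f["SST_anomaly_freq"],
                               brute_count(anom, 1.0, "ge"), atol=0)
    np.testing.assert_allclose(f["TSA_heat_freq"],
                               brute_count(tsa_heat, 1.0, "ge"), atol=0)
    np.testing.assert_allclose(f["TSA_cold_freq"],
                               brute_count(tsa_cold, -1.0, "le"), atol=0)
    dhw = brute_degree_weeks(tsa_heat, "heat")
    dcw = brute_degree_weeks(tsa_cold, "cold")
    np.testing.assert_allclose(f["TSA_DHW"], dhw, atol=1e-9)
    np.testing.assert_allclose(f["TSA_DCW"], dcw, atol=1e-9)
    np.testing.assert_allclose(f["TSA_DHW_freq"], brute_count(dhw, 1.0, "ge"),
                               atol=1e-9)
    np.testing.assert_allclose(f["TSA_DCW_freq"], brute_count(dcw, -1.0, "le"),
                               atol=1e-9)
    assert (f["TSA_DHW"] >= 0).all() and (f["TSA_DCW"] <= 0).all()
    for col in ["SST_anomaly_freq", "TSA_heat_freq", "TSA_DHW_freq",
                "TSA_cold_freq", "TSA_DCW_freq"]:
        assert f[col].between(0, 364).all()


def test_dhw_recovers_event_magnitude():
    """A 2 °C x 28 d square heat wave accumulates A*D/7 = 8 °C-weeks."""
    base = dict(start_date="2002-01-01", end_date="2016-12-31",
                seasonal_amplitude=0.0, noise_sd=0.0, seed=1)
    ref, _ = generate_sst_series(SstScenario(**base))
    clim = build_climatology(ref)  # event-free reference climatology
    ev, _ = generate_sst_series(SstScenario(
        events=[ThermalEvent("2015-04-01", 28, 2.0, "square")], **base))
    idx = assemble_indices(ev, clim=clim)
    assert abs(idx.frame["TSA_DHW"].max() - 8.0) <= 0.1
    # DHW non-decreasing while the exceedance persists
    during = idx.frame.loc["2015-04-01":"2015-04-28", "TSA_DHW"].to_numpy()
    assert (np.diff(during) >= -1e-12).all()


# ---------------------------------------------------------------------------
# site summaries
# ---------------------------------------------------------------------------

def test_summary_of_constructed_event(flat_sst):
    series, _ = flat_sst
    idx = assemble_indices(series)
    s = summarize_site(idx, "2015-05-28")   # 30 d after the Apr 28 event end
    assert s.recovery_days_heat == pytest.approx(30)
    assert s.last_heat_event.duration == 28
    assert s.last_heat_event.peak == pytest.approx(2.0, abs=0.15)
    inside = summarize_site(idx, "2015-04-15")
    assert inside.recovery_days_heat == 0
    st = s.stats
    assert (st["min"] <= st["mean"] + 1e-9).all()
    assert (st["mean"] <= st["max"] + 1e-9).all()


def test_summary_without_events_and_burn_in_guard():
    sc = SstScenario(noise_sd=0.0, seasonal_amplitude=0.5)
    series, _ = generate_sst_series(sc)
    idx = assemble_indices(series)
    s = summarize_site(idx, "2015-06-01")
    assert s.last_heat_event is None and s.last_cold_event is None
    assert s.recovery_days_heat >= 0
    assert s.stats.loc["TSA_DHW", ["min", "max", "sum"]].eq(0).all()
    with pytest.raises(ValueError, match="burn-in"):
        summarize_site(idx, "2002-06-01")


# ---------------------------------------------------------------------------
# Reef Check matching
# ---------------------------------------------------------------------------

def test_reefcheck_matching_rules():
    sites = pd.DataFrame({"lat": [0.0, 0.05, 1.0], "lon": [0.0, 0.0, 0.0]})
    hit = match_reefcheck(0.0, 0.0, sites)
    assert hit == (0, pytest.approx(0.0))
    hit = match_reefcheck(0.051, 0.0, sites.iloc[[1]])
    assert hit[1] == pytest.approx(0.111, abs=0.01)
    far = pd.DataFrame({"lat": [0.135], "lon": [0.0]})     # ~15 km
    assert match_reefcheck(0.0, 0.0, far) is None
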
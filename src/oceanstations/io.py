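"""Round-trip-safe table I/O, run configuration and pipeline orchestration.

All tabular outputs are UTF-8 tab-separated values with a header row;
missing-value tokens (nav/npr/nac/nap) and sampling-design labels
survive a write/read round trip unchanged.  Velocity fields are stored
as NetCDF grids with (lon, lat, time) dimensions and u/v variables in
m/s.  A full run derives every stage seed from one master seed and
records all parameters in a manifest, so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import __version__
from .context import (MISSING_TOKENS, MergePolicy, bias_correct_source,
                      compose_design_label, merge_sources)
from .nbss import compute_nbss, net_efficiency, nbss_slope
from .synth import (FlowScenario, SourceScenario, SourceSpec, SstScenario,
                    ThermalEvent, generate_multisource, generate_plankton_sample,
                    generate_sst_series, generate_velocity_field)
from .thermal import assemble_indices, summarize_site

_TOKENS = set(MISSING_TOKENS.values())


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_table(frame: pd.DataFrame, path, index: bool = False) -> None:
    """Write a UTF-8 tab-separated table with header row."""
    frame.to_csv(path, sep="\t", index=index, encoding="utf-8")


def read_table(path) -> pd.DataFrame:
    """Read a tab-separated table, preserving missing tokens literally.

    Columns are converted to numeric when every entry parses as a number;
    columns carrying tokens (nav/npr/nac/nap) or labels stay as text.
    Malformed files raise a parse error naming the offending line.
    """
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str,
                            keep_default_na=False, na_values=[""],
                            encoding="utf-8")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed table {path}: {exc}") from exc
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        original_na = frame[col].isna()
        if (converted.notna() | original_na).all():
            frame[col] = converted
    return frame


def write_velocity_field(field_ds: xr.Dataset, path) -> None:
    """Store a (lon, lat, time) u/v grid as NetCDF."""
    field_ds.to_netcdf(path)


def read_velocity_field(path) -> xr.Dataset:
    with xr.open_dataset(path) as ds:
        return ds.load()


def write_config(mapping: dict, path) -> None:
    """Plain-text key-value (YAML) configuration file."""
    Path(path).write_text(yaml.safe_dump(mapping, sort_keys=True),
                          encoding="utf-8")


def read_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}


# ---------------------------------------------------------------------------
# Run configuration and orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a full synthetic-station pipeline run.

    Each enabled stage draws its inputs from the synthetic generators
    with a seed split deterministically from ``seed``.  Threshold
    overrides are recorded verbatim in the manifest.
    """

    out_dir: str = "run_output"
    seed: int = 0
    stages: tuple = ("thermal", "flow", "merge", "nbss")
    sampling_date: str = "2015-06-15"
    flow_taus: tuple = (5, 10)
    overrides: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = read_config(path)
        known = {f.name for f in dataclasses.fields(cls)}
        cfg = cls(**{k: v for k, v in raw.items() if k in known})
        cfg.stages = tuple(cfg.stages)
        cfg.flow_taus = tuple(cfg.flow_taus)
        return cfg


def _stage_seed(master: int, stage: str) -> int:
    ss = np.random.SeedSequence([master, sum(ord(c) for c in stage)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_station_context(config: RunConfig, log=None) -> dict:
    """Execute the configured stages on synthetic inputs and write tables.

    Writes one table per stage plus ``manifest.yaml`` holding the
    package version, the master and per-stage seeds and every parameter
    and override in effect.  Reruns with the same config are
    byte-identical.  Returns the paths written, keyed by product name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = log or (lambda stage, msg: print(f"[{stage}] {msg}", file=sys.stderr))
    paths: dict[str, Path] = {}
    manifest = {"package_version": __version__, "master_seed": config.seed,
                "stages": list(config.stages), "stage_seeds": {},
                "parameters": {}, "overrides": dict(config.overrides)}

    if "thermal" in config.stages:
        stage_seed = _stage_seed(config.seed, "thermal")
        manifest["stage_seeds"]["thermal"] = stage_seed
        scenario = SstScenario(
            site_id="SYN01", start_date="2002-01-01", end_date="2016-12-31",
            noise_sd=0.3, ar1=0.3, gap_fraction=0.05, gap_mean_len=5,
            events=[ThermalEvent("2015-04-01", 28, 2.0, "square")],
            seed=stage_seed)
        manifest["parameters"]["thermal"] = {
            "scenario": "seasonal+AR1, one 2°C × 28 d square heat wave",
            "sampling_date": config.sampling_date}
        try:
            series, _ = generate_sst_series(scenario)
            indices = assemble_indices(series)
            summary = summarize_site(indices, config.sampling_date)
        except Exception as exc:
            raise RuntimeError(f"thermal stage failed: {exc}") from exc
        p = out / "thermal_indices.tsv"
        frame = indices.frame.copy()
        frame.insert(0, "date", frame.index.strftime("%Y-%m-%d"))
        write_table(frame.round(6), p)
        paths["thermal_indices"] = p
        p2 = out / "thermal_site_summary.tsv"
        write_table(summary.stats.round(6), p2, index=True)
        paths["thermal_summary"] = p2
        log("thermal", f"indices for {scenario.site_id} -> {p}")

    if "flow" in config.stages:
        from .flow import StadiumSpec, station_diagnostics
        stage_seed = _stage_seed(config.seed, "flow")
        manifest["stage_seeds"]["flow"] = stage_seed
        scenario = FlowScenario(kind="solid_body", params={"omega": 0.1},
                                lon_range=(-3, 3), lat_range=(-3, 3),
                                resolution=0.25, n_days=70)
        manifest["parameters"]["flow"] = {
            "kind": "solid_body", "omega_per_day": 0.1,
            "taus": list(config.flow_taus)}
        try:
            field_ds, _ = generate_velocity_field(scenario)
            spec = StadiumSpec(p_start=(0.4, 0.0), p_end=(0.55, 0.1),
                               spacing=0.02)
            table = station_diagnostics(spec, field_ds, t0=60.0,
                                        taus=config.flow_taus)
        except Exception as exc:
            raise RuntimeError(f"flow stage failed: {exc}") from exc
        p = out / "flow_station_diagnostics.tsv"
        write_table(table.round(8), p)
        paths["flow_diagnostics"] = p
        log("flow", f"station diagnostics -> {p}")

    if "merge" in config.stages:
        stage_seed = _stage_seed(config.seed, "merge")
        manifest["stage_seeds"]["merge"] = stage_seed
        scenario = SourceScenario(
            n=200, satellite=SourceSpec(1.3, -0.5, 0.1),
            model=SourceSpec(0.9, 0.2, 0.2),
            insitu_missing_fraction=0.2, seed=stage_seed)
        manifest["parameters"]["merge"] = {
            "n_stations": 200, "satellite_bias": [1.3, -0.5],
            "model_bias": [0.9, 0.2]}
        try:
            truth, sat, mod = generate_multisource(scenario)
            ref = truth["value"].to_numpy()
            sat_fix = bias_correct_source(sat["value"].to_numpy(), ref)
            mod_fix = bias_correct_source(mod["value"].to_numpy(), ref)
            sources = {"insitu_sample": truth["value"]}
            if sat_fix.accepted:
                sources["satellite"] = pd.Series(sat_fix.corrected,
                                                 index=sat.index)
            if mod_fix.accepted:
                sources["model"] = pd.Series(mod_fix.corrected, index=mod.index)
            merged = merge_sources(sources, MergePolicy())
            merged.insert(0, "label", [compose_design_label(0, 0, 0, 0)
                                       if i >= 249 else
                                       compose_design_label(i, 0, 0, 0)
                                       for i in merged.index])
        except Exception as exc:
            raise RuntimeError(f"merge stage failed: {exc}") from exc
        p = out / "merged_site_values.tsv"
        write_table(merged.round(6), p, index=True)
        paths["merged_sites"] = p
        log("merge", f"bias-corrected merge (sat slope {sat_fix.slope:.3f}) -> {p}")

    if "nbss" in config.stages:
        stage_seed = _stage_seed(config.seed, "nbss")
        manifest["stage_seeds"]["nbss"] = stage_seed
        manifest["parameters"]["nbss"] = {"spectral_slope": -2.0,
                                          "n_objects": 10_000}
        try:
            a = generate_plankton_sample(-2.0, 10_000, 40.0, seed=stage_seed,
                                         net_id="HSN")
            b = generate_plankton_sample(-2.0, 10_000, 120.0,
                                         seed=stage_seed + 1, net_id="MANTA")
            bins = np.exp2(np.arange(-6, 7)).astype(float)
            sa, sb = compute_nbss(a, bins), compute_nbss(b, bins)
            eff_mean, eff_sd = net_efficiency(sa, sb)
            frame = sa.to_frame()
            frame["nbss_other"] = sb.nbss
        except Exception as exc:
            raise RuntimeError(f"nbss stage failed: {exc}") from exc
        p = out / "nbss_spectra.tsv"
        write_table(frame.round(8), p)
        paths["nbss"] = p
        manifest["parameters"]["nbss"]["efficiency_mean"] = round(eff_mean, 6)
        manifest["parameters"]["nbss"]["fitted_slope"] = round(nbss_slope(sa), 6)
        log("nbss", f"spectra and efficiency ({eff_mean:.3f}±{eff_sd:.3f}) -> {p}")

    mpath = out / "manifest.yaml"
    write_config(manifest, mpath)
    paths["manifest"] = mpath
    return paths
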
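"""End-to-end pipeline: simulate -> limits -> index -> timings ->
trends -> effects -> report, driven by one YAML configuration.

Every stage writes a delimited-text table into the output directory and
the run closes with a manifest (config hash, seed, package version,
per-stage row counts).  Rerunning with the same configuration
reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .climate import seasonal_limit_summary, classify_site
from .effects import (
    gsi_sgsi_difference, greenup_deviation_regression, greenup_exclusion,
    seasonal_values, similar_met_years, snowmelt_deviation_regression,
    effect_report,
)
from .emulator import (
    EmulatorParams, calibrate_uptake, run_toy_ecosystem,
    snowmelt_delay_experiment, delayed_days,
)
from .gsi import annual_index, calibrate_thresholds
from .seasons import SEASONS, get_season
from .synthetic import (
    PhenologyRules, SiteConfig, SnowParams, derive_phenology,
    generate_met, generate_snow, write_met, write_snow,
)
from .timings import extract_timings
from .trends import TimingTrend

log = logging.getLogger("phenoflux")

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "phenoflux_run",
    "sites": [{"site_id": "SYN-1"}],
    "emulator": {},
    "snow": {},
    "phenology": {},
    "trend_three_sigma": {"snowmelt_doy": 6.6, "greenup_doy": 10.0},
    "effect_seasons": ["early", "GS"],
    # fraction of GS weeks a year must keep within +-1 SD of the weekly
    # norm to count as met-similar; 0.9 retains a realistic share of
    # years (roughly half of an 18-year record)
    "mask_fraction": 0.9,
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = {**DEFAULT_CONFIG, **user}
    if not cfg.get("sites"):
        raise ValueError("config must list at least one site")
    for key in ("emulator", "snow", "phenology"):
        if not isinstance(cfg.get(key, {}), dict):
            raise ValueError(f"config section {key!r} must be a mapping")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_site(cfg: dict, site_cfg: dict, out: Path, seed: int) -> dict:
    """Run every stage for one site; returns manifest entries."""
    site = SiteConfig(**{**site_cfg, "seed": seed})
    sid = site.site_id
    log.info("site %s: simulating %d years", sid, site.years)

    met = generate_met(site)
    snow = generate_snow(met, SnowParams(**cfg.get("snow", {})))
    timings_obs = derive_phenology(met, PhenologyRules(**cfg.get("phenology", {})))

    write_met(met, out / f"{sid}_met.csv")
    write_snow(snow, out / f"{sid}_snow.csv")
    timings_obs.to_csv(out / f"{sid}_phenology.csv", index=False)

    limits = seasonal_limit_summary(met)
    limit_class = classify_site(limits["t_limit"], limits["w_limit"])
    limits.to_frame(sid).T.to_csv(out / f"{sid}_limits.csv")

    spring = calibrate_thresholds(met, timings_obs, "spring")
    fall = calibrate_thresholds(met, timings_obs, "fall")
    index = annual_index(met, spring, fall, snow=snow)
    index.to_csv(out / f"{sid}_gsi.csv", index=False)

    params = EmulatorParams(**cfg.get("emulator", {}))
    state_gsi = run_toy_ecosystem(met, snow, index, params, "gsi")
    state_sgsi = run_toy_ecosystem(met, snow, index, params, "sgsi")
    state_sgsi.to_csv(out / f"{sid}_state.csv", index=False)

    timing_tbl = extract_timings(snow=snow, gsi=index, flux=state_sgsi)
    timing_tbl = timing_tbl.merge(timings_obs, on="year", how="left")
    timing_tbl.to_csv(out / f"{sid}_timings.csv", index=False)

    trend_rows = []
    for col, s3 in cfg["trend_three_sigma"].items():
        if col in timing_tbl and timing_tbl[col].notna().sum() >= 4:
            res = TimingTrend.from_dataframe(timing_tbl, col).fit(
                three_sigma=s3, seed=seed
            )
            trend_rows.append(res.summary())
    trends = pd.DataFrame(trend_rows)
    trends.to_csv(out / f"{sid}_trends.csv", index=False)

    masks = similar_met_years(
        index, required_fraction=cfg.get("mask_fraction", 0.9)
    ).merge(
        greenup_exclusion(timings_obs), on="year", how="outer"
    )
    masks.to_csv(out / f"{sid}_masks.csv", index=False)

    snow_timing = timing_tbl[["year", "snowmelt_doy"]]
    effect_rows = []
    for season_name in cfg["effect_seasons"]:
        window = get_season(season_name)
        nep = seasonal_values(state_sgsi, window, "nep", mode="total")
        try:
            est = snowmelt_deviation_regression(
                snow_timing, nep, masks, season=season_name)
            effect_rows.append(est.summary())
        except ValueError as exc:
            log.warning("site %s %s snowmelt effect skipped: %s",
                        sid, season_name, exc)
        try:
            est = greenup_deviation_regression(
                timings_obs, nep, masks, season=season_name)
            effect_rows.append(est.summary())
        except ValueError as exc:
            log.warning("site %s %s greenup effect skipped: %s",
                        sid, season_name, exc)
        diff = snowmelt_delay_experiment(
            met, snow,
            lambda s: annual_index(met, spring, fall, snow=s),
            params, delays=range(0, 11), season=window,
        )
        est = gsi_sgsi_difference(diff, season=season_name)
        if est is not None:
            effect_rows.append(est.summary())
    effects = pd.DataFrame(effect_rows)
    effects["site"] = sid
    effects["limit_class"] = limit_class
    effects.to_csv(out / f"{sid}_effects.csv", index=False)

    return {
        "site": sid,
        "limit_class": limit_class,
        "rows": {
            "met": len(met), "snow": len(snow), "gsi": len(index),
            "timings": len(timing_tbl), "trends": len(trends),
            "effects": len(effects),
        },
        "effects": effects,
    }


def run_pipeline(config_path, out_dir=None, seed=None) -> dict:
    """Execute the full pipeline described by a YAML config file.

    Returns the run manifest (also written as ``manifest.json``).
    """
    cfg = load_config(config_path)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)

    site_entries = []
    all_effects = []
    for i, site_cfg in enumerate(cfg["sites"]):
        entry = run_site(cfg, site_cfg, out, seed=cfg["seed"] + i)
        all_effects.append(entry.pop("effects"))
        site_entries.append(entry)

    report = effect_report(pd.concat(all_effects, ignore_index=True))
    report.to_csv(out / "effect_report.csv", index=False)

    manifest = {
        "version": __version__,
        "seed": cfg["seed"],
        "config_hash": _config_hash(cfg),
        "sites": site_entries,
        "report_rows": len(report),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
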
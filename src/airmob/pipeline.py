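"""End-to-end orchestration: simulate -> ingest -> aggregate -> decompose ->
exceedance -> hotspots, with persisted stage outputs and a run manifest."""

from __future__ import annotations

import datetime as dt
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .aggregate import daytime_summary, diurnal_profile, hourly_median, rolling_median_8s
from .baseline import component_fractions, partition_event_scales
from .config import PipelineConfig
from .hotspots import HotspotConfig, hotspot_pipeline, write_geojson
from .ingest import (
    convert_nox,
    drop_missing_key_variables,
    forward_fill_o3,
    read_observations,
    substitute_below_lod,
)
from .pollutants import LodTable
from .standards import (
    builtin_standards,
    evaluate_exceedance,
    select_polluted_days,
    summary_table,
)
from .synthetic import (
    ScenarioConfig,
    default_background_models,
    default_plume_models,
    default_route,
    generate_scenario,
    write_scenario,
)

logger = logging.getLogger(__name__)

METRIC_TO_FRAME = {"daytime_median": "daily", "hourly_median": "hourly",
                   "daily_1h_max": "daily"}


class StageFailure(RuntimeError):
    pass


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; return the run manifest.

    Stage outputs are persisted as CSV/JSON/GeoJSON under ``out_dir``; the
    manifest (written last, as ``manifest.json``) records the config hash,
    seed, and per-stage input/output row counts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "started_utc": dt.datetime.now(dt.timezone.utc).isoformat(),
        "stages": [],
    }

    def record(stage: str, n_in: int, n_out: int, **extra) -> None:
        manifest["stages"].append({"stage": stage, "rows_in": n_in, "rows_out": n_out, **extra})
        logger.info("stage %s: %d rows in, %d rows out %s", stage, n_in, n_out, extra)

    obs = None
    truth = None
    lod_table = (
        LodTable.from_yaml(config.ingest.lod_table)
        if config.ingest.lod_table
        else LodTable()
    )

    try:
        if config.stages.simulate and config.input_path is None:
            sim = config.simulate
            scenario = ScenarioConfig(
                seed=config.seed,
                n_days=sim.n_days,
                start_date=dt.date.fromisoformat(sim.start_date),
                pollutants=tuple(sim.pollutants),
                missingness_fraction=sim.missingness_fraction,
                cell_size_m=sim.cell_size_m,
            )
            plume_models = {
                p: m
                for p, m in default_plume_models(
                    frozenset(sim.hotspot_cells), sim.hotspot_rate_multiplier
                ).items()
                if p in sim.pollutants
            }
            bg_models = {
                p: m for p, m in default_background_models().items() if p in sim.pollutants
            }
            obs, truth = generate_scenario(default_route(), bg_models, plume_models, scenario)
            write_scenario(obs, truth, out / "scenario", lod_table)
            record("simulate", 0, len(obs), pollutants=list(sim.pollutants))
        elif config.input_path is not None:
            obs = read_observations(config.input_path)
            record("read", 0, len(obs))

        if obs is None:
            raise StageFailure("no input: enable the simulate stage or set input_path")

        if config.stages.ingest:
            n_in = len(obs)
            obs = substitute_below_lod(obs, lod_table, config.ingest.resolution)
            if "O3" in obs.columns:
                obs = forward_fill_o3(obs)
            if "NO2" in obs.columns:
                # express NO(+NO2) ppb as NOx-as-NO2 in ug/m3, the scale the
                # guideline thresholds use; drop the now-absorbed NO channel
                no_ppb = obs["NO"] if "NO" in obs.columns else 0.0
                obs["NO2"] = convert_nox(no_ppb, obs["NO2"])
                obs = obs.drop(columns=["NO"], errors="ignore")
                logger.info("converted NO/NO2 ppb to NOx-as-NO2 ug/m3")
            obs, report = drop_missing_key_variables(obs, config.ingest.key_variables)
            with open(out / "retention_report.json", "w") as fh:
                json.dump(report.to_dict(), fh, indent=2)
            obs.to_csv(out / "clean_observations.csv", index_label="time")
            record("ingest", n_in, len(obs), retention=report.retention)

        segments = hourly = daily = None
        if config.stages.aggregate:
            agg = config.aggregate
            segments = rolling_median_8s(obs, lod_table)
            hourly = hourly_median(segments, min_samples=agg.min_samples)
            daily = daytime_summary(
                segments, hourly, min_hours=agg.min_hours, source=agg.daytime_source
            )
            segments.to_csv(out / "segments_8s.csv", index_label="time")
            hourly.to_csv(out / "hourly.csv")
            daily.to_csv(out / "daily.csv", index_label="date")
            for pollutant in [c for c in obs.columns if c not in ("lat", "lon")]:
                profile = diurnal_profile(hourly, pollutant)
                profile.to_csv(out / f"diurnal_{pollutant.replace('.', '')}.csv")
            record("aggregate", len(obs), len(segments),
                   hours=len(hourly), days=len(daily))

        if config.stages.decompose:
            if segments is None:
                raise StageFailure("decompose requires the aggregate stage")
            frames = []
            fractions = {}
            for pollutant in [c for c in segments.columns
                              if c in obs.columns and c not in ("lat", "lon")]:
                part = partition_event_scales(segments[pollutant].dropna())
                part["pollutant"] = pollutant
                frames.append(part)
                fractions[pollutant] = component_fractions(part)
            decomp = pd.concat(frames)
            decomp.to_csv(out / "decomposition.csv", index_label="time")
            with open(out / "decomposition_fractions.json", "w") as fh:
                json.dump(fractions, fh, indent=2)
            record("decompose", len(segments), len(decomp))

        exceedance_reports = []
        if config.stages.exceedance:
            if hourly is None or daily is None:
                raise StageFailure("exceedance requires the aggregate stage")
            frames = {"daily": daily, "hourly": hourly}
            for std in builtin_standards():
                frame_key = METRIC_TO_FRAME.get(std.metric)
                if frame_key is None or std.pollutant not in frames[frame_key].columns:
                    continue
                values = frames[frame_key][std.pollutant].dropna()
                if values.empty:
                    continue
                exceedance_reports.append(
                    evaluate_exceedance(values, std, config.exceedance.precision).to_dict()
                )
            with open(out / "exceedance.json", "w") as fh:
                json.dump(exceedance_reports, fh, indent=2)
            summary_table(
                obs[[c for c in obs.columns if c not in ("lat", "lon")]]
            ).to_csv(out / "summary_table.csv")
            record("exceedance", len(daily) + len(hourly), len(exceedance_reports))

        if config.stages.hotspots:
            if segments is None or daily is None:
                raise StageFailure("hotspots require the aggregate stage")
            hs = config.hotspots
            polluted = select_polluted_days(daily) if {"PM2.5", "NO2"} <= set(daily.columns) else daily
            if polluted.empty:
                record("hotspots", len(segments), 0, skipped="no polluted days")
            else:
                layers = hotspot_pipeline(
                    segments,
                    list(polluted.index),
                    hs.pollutant,
                    HotspotConfig(
                        cell_size_m=hs.cell_size_m,
                        band_distance_m=hs.band_distance_m,
                        min_count=hs.min_count,
                        correction=hs.correction,
                        grid=truth.grid if truth is not None else None,
                    ),
                    per_day=hs.per_day,
                )
                write_geojson(layers["pooled"]["geojson"], out / "hotspots_pooled.geojson")
                layers["pooled"]["cells"].to_csv(out / "hotspots_pooled.csv", index=False)
                for day, layer in layers["per_day"].items():
                    write_geojson(layer["geojson"], out / f"hotspots_{day}.geojson")
                record("hotspots", len(segments), len(layers["pooled"]["cells"]),
                       days=len(polluted))
        else:
            manifest["stages"].append({"stage": "hotspots", "skipped": True})
    except StageFailure as exc:
        manifest["failure"] = str(exc)
        manifest["finished_utc"] = dt.datetime.now(dt.timezone.utc).isoformat()
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise

    manifest["finished_utc"] = dt.datetime.now(dt.timezone.utc).isoformat()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def report_tables(out_dir) -> str:
    """Aligned-text summary + exceedance tables from persisted stage outputs."""
    out = Path(out_dir)
    lines: list[str] = []
    summary_path = out / "summary_table.csv"
    if summary_path.exists():
        table = pd.read_csv(summary_path, index_col=0)
        lines.append("Summary statistics (raw observations)")
        lines.append(table.round(2).to_string())
    exceed_path = out / "exceedance.json"
    if exceed_path.exists():
        with open(exceed_path) as fh:
            reports = json.load(fh)
        lines.append("")
        lines.append("Guideline exceedance")
        for rec in reports:
            lines.append(
                f"  {rec['pollutant']:>6} {rec['metric']:<16} {rec['authority']:<13} "
                f"> {rec['threshold']:g} {rec['unit']}: "
                f"{rec['n_exceed']} ({rec['percentage']}%) of {rec['n_total']}"
            )
    return "\n".join(lines) if lines else "(no aggregate outputs found)"
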
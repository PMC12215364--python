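"""End-to-end orchestration: simulate, filter, rasterize, summarize, compare.

A single :class:`RunConfig` drives both the backward analysis (released at
destination-country traps, evaluated against origin-country traps and
districts) and the forward analysis (the mirror image), guaranteeing the
two directions share identical period bins — a precondition for matching
backward and forward hits into candidate origin-destination pairs.

Every run writes its artifacts plus a manifest (config hash, stage counts,
period list) so a result can be replayed and audited.  Any stage failure
aborts the run with the stage name; partially written artifacts are
removed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .comparison import (ComparisonGrid, Target, candidate_frame, classify_cases,
                         export_grid_image, hit_ratio, hit_ratio_frame,
                         match_candidates, target_from_buffer, target_from_regions)
from .occurrence import (OccurrenceTable, SamplingPeriod, TrapSite, complete,
                         filter_trajectories, load_occurrence, load_sites,
                         weekly_periods)
from .raster import RasterGrid, make_grid, rasterize_trajectories, write_raster
from .trajectory import TrajectoryConfig, TrajectoryEnsemble, run_campaign
from .windfield import WindField
from .zonal import RegionSet, export_choropleth, load_regions, zonal_mean

__all__ = ["RunConfig", "PipelineError", "run_backward_analysis",
           "run_forward_analysis", "run_matching"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Inputs and knobs for one two-country campaign analysis.

    Path fields may alternatively hold the already-loaded objects (a
    :class:`WindField`, site list, tables, region sets), which is how the
    synthetic scenario drives the pipeline without touching disk.
    ``met_type`` is accepted for interface compatibility with
    reanalysis-driven runs and is recorded in the manifest but has no
    effect: meteorology arrives through ``wind``.
    """

    wind: object = None                      # path or WindField
    sites: object = None                     # path or list[TrapSite]
    origin_occurrence: object = None         # path or OccurrenceTable
    destination_occurrence: object = None
    origin_regions: object = None            # path or RegionSet
    destination_regions: object = None
    period_start: str = "2022-04-03"
    period_end: str = "2022-05-28"
    period_length: int = 7
    trajectory: dict = field(default_factory=dict)   # TrajectoryConfig overrides
    release_days: str = "period_start"       # period_start | all
    raster_resolution: float = 0.1
    polygon_mode: str = "district"           # district | buffer
    trap_buffer_km: float = 50.0
    densify: int = 0
    outdir: str = "out"
    seed: int = 0
    met_type: str = "reanalysis"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.serializable(), fh, sort_keys=True)

    def serializable(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            try:
                json.dumps(v)
                out[f.name] = v
            except TypeError:
                out[f.name] = f"<{type(v).__name__}>"
        return out

    def config_hash(self) -> str:
        blob = json.dumps(self.serializable(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # -- loaded views -----------------------------------------------------
    def periods(self) -> list[SamplingPeriod]:
        return weekly_periods(self.period_start, self.period_end,
                              self.period_length)

    def load_wind(self) -> WindField:
        return self.wind if isinstance(self.wind, WindField) \
            else WindField.from_netcdf(self.wind)

    def load_site_list(self) -> list[TrapSite]:
        return self.sites if isinstance(self.sites, list) else load_sites(self.sites)

    def load_occ(self, which: str) -> OccurrenceTable:
        v = getattr(self, f"{which}_occurrence")
        return v if isinstance(v, OccurrenceTable) else load_occurrence(v)

    def load_region_set(self, which: str) -> RegionSet:
        v = getattr(self, f"{which}_regions")
        return v if isinstance(v, RegionSet) else load_regions(v)

    def trajectory_config(self, direction: str) -> TrajectoryConfig:
        return TrajectoryConfig(direction=direction, **self.trajectory)


@dataclass
class Artifacts:
    direction: str
    ensemble: TrajectoryEnsemble
    filtered: TrajectoryEnsemble
    raster: RasterGrid
    summaries: list
    grid: ComparisonGrid
    ratios_location: list
    ratios_period: list
    targets: list[Target]
    manifest: dict
    outdir: Path


def _release_dates(config: RunConfig, periods):
    if config.release_days == "all":
        return [d.date() for p in periods
                for d in pd.date_range(p.start, p.end, freq="D")]
    return [p.start for p in periods]


def _build_targets(sites, regions: RegionSet, config: RunConfig) -> list[Target]:
    if config.polygon_mode == "buffer":
        return [target_from_buffer(s, config.trap_buffer_km) for s in sites]
    return [target_from_regions(s, regions) for s in sites]


def _run_direction(config: RunConfig, direction: str) -> Artifacts:
    outdir = Path(config.outdir) / direction
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        field_ = config.load_wind()
        sites = config.load_site_list()
        periods = config.periods()
        origin_sites = [s for s in sites if s.country == "origin"]
        dest_sites = [s for s in sites if s.country == "destination"]
        if direction == "backward":
            release_sites, release_occ_key = dest_sites, "destination"
            target_sites, target_occ_key, region_key = origin_sites, "origin", "origin"
        else:
            release_sites, release_occ_key = origin_sites, "origin"
            target_sites, target_occ_key, region_key = dest_sites, "destination", "destination"
        release_occ = complete(config.load_occ(release_occ_key),
                               [s.site_id for s in release_sites], periods)
        target_occ = complete(config.load_occ(target_occ_key),
                              [s.site_id for s in target_sites], periods)
        regions = config.load_region_set(region_key)

        stage = "simulate"
        cfg = config.trajectory_config(direction)
        ensemble = run_campaign(release_sites, _release_dates(config, periods),
                                cfg, field_)

        stage = "filter"
        filtered = filter_trajectories(ensemble, release_occ, periods)
        df = filtered.to_dataframe()
        p = outdir / "trajectories.csv"
        df.to_csv(p, index=False)
        written.append(p)

        stage = "rasterize"
        xs = [r.geometry.bounds for r in regions]
        lon_min = min(b[0] for b in xs)
        lat_min = min(b[1] for b in xs)
        lon_max = max(b[2] for b in xs)
        lat_max = max(b[3] for b in xs)
        grid0 = make_grid(lat_min, lat_max, lon_min, lon_max,
                          resolution=config.raster_resolution)
        raster = rasterize_trajectories(filtered, grid0, densify=config.densify)
        p = outdir / "raster.asc"
        write_raster(raster, p)
        written.append(p)

        stage = "zonal"
        summaries = zonal_mean(raster, regions)
        sdf = pd.DataFrame(
            [(s.region_id, s.nhits_mean if s.defined else "", s.n_cells, s.is_max)
             for s in summaries],
            columns=["region_id", "nhits_mean", "n_cells", "is_max"],
        )
        p = outdir / "region_summary.csv"
        sdf.to_csv(p, index=False)
        written.append(p)
        export_choropleth(summaries, regions, outdir / "choropleth.geojson",
                          title=f"{direction} trajectory frequency (nhits_mean)")
        written += [outdir / "choropleth.geojson", outdir / "choropleth.png"]

        stage = "classify"
        targets = _build_targets(target_sites, regions, config)
        grid = classify_cases(filtered, target_occ, targets, periods,
                              densify=config.densify, direction=direction,
                              country=regions.country)
        p = outdir / "comparison_grid.csv"
        grid.to_csv(p)
        written.append(p)
        export_grid_image(grid, outdir / "comparison_grid.png")
        written.append(outdir / "comparison_grid.png")
        rl = hit_ratio(grid, by="location")
        rp = hit_ratio(grid, by="period")
        for name, r in (("hit_ratio_by_location.csv", rl),
                        ("hit_ratio_by_period.csv", rp)):
            p = outdir / name
            hit_ratio_frame(r).to_csv(p, index=False)
            written.append(p)

        stage = "manifest"
        manifest = {
            "direction": direction,
            "seed": config.seed,
            "config_sha256": config.config_hash(),
            "met_type": config.met_type,
            "package_version": __version__,
            "periods": [pp.period_id for pp in periods],
            "counts": {
                "simulated": len(ensemble),
                "rejected_starts": len(ensemble.rejections),
                "filtered": len(filtered),
                "raster_nhits_total": int(raster.nhits.sum()),
                "case_labels": grid.counts(),
            },
        }
        p = outdir / "manifest.json"
        with open(p, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        written.append(p)
        return Artifacts(direction, ensemble, filtered, raster, summaries, grid,
                         rl, rp, targets, manifest, outdir)
    except Exception as exc:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise PipelineError(stage, exc) from exc


def run_backward_analysis(config: RunConfig) -> Artifacts:
    """Steps 1-4 plus classification for the backward direction:
    releases at destination-country traps, origin-country targets."""
    return _run_direction(config, "backward")


def run_forward_analysis(config: RunConfig) -> Artifacts:
    """Mirror of the backward analysis: releases at origin-country traps,
    destination-country targets."""
    return _run_direction(config, "forward")


def run_matching(backward: Artifacts, forward: Artifacts,
                 config: RunConfig) -> list:
    """Match backward and forward hits into candidate origin-destination
    pairs; writes candidates.csv and a human-readable report."""
    if backward.grid.periods != forward.grid.periods:
        raise PipelineError("match", ValueError(
            "backward and forward runs cover different periods"))
    periods = config.periods()
    pairs = match_candidates(backward.grid, forward.grid, backward.filtered,
                             forward.filtered, backward.targets,
                             forward.targets, periods,
                             densify=config.densify)
    outdir = Path(config.outdir)
    candidate_frame(pairs).to_csv(outdir / "candidates.csv", index=False)
    lines = [f"{len(pairs)} candidate origin-destination pairs"]
    for c in pairs:
        lines.append(f"  period {c.period_id}: origin {c.origin_site} "
                     f"-> destination {c.destination_site}")
    (outdir / "candidates_report.txt").write_text("\n".join(lines) + "\n")
    return pairs
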
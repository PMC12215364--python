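"""Zonal statistics of frequency rasters over administrative polygons.

Step 4 masks/crops the nhits raster by a set of administrative district
polygons and reports, per district, the mean of nhits over the raster cells
whose centers fall inside the polygon (``nhits_mean``), zero-count cells
included.  Districts containing no cell centers report a missing mean — the
choropleth draws both missing and zero in neutral grey, but the attribute
table keeps them distinct.  The district(s) attaining the highest defined
mean ("max_nhits" regions) are the most likely source (backward analysis)
or destination (forward analysis) areas.

Region geometries are WGS84 polygons from GeoJSON (or any mapping shapely
understands); invalid geometries are repaired with make_valid on load and
rejected by id if still invalid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import mapping, shape

__all__ = ["Region", "RegionSet", "RegionSummary", "load_regions",
           "zonal_mean", "find_max_regions", "export_choropleth"]


@dataclass(frozen=True)
class Region:
    region_id: str
    name: str
    geometry: shapely.Geometry


@dataclass
class RegionSet:
    regions: list[Region]
    country: str = ""

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("region_ids must be unique")

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __getitem__(self, region_id: str) -> Region:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(region_id)

    def region_containing(self, lat: float, lon: float) -> Region | None:
        pt = shapely.Point(lon, lat)
        for r in self.regions:
            if r.geometry.covers(pt):
                return r
        return None


def load_regions(path, id_field: str = "GID_2", name_field: str = "NAME_2",
                 country: str = "") -> RegionSet:
    """Load polygons from GeoJSON; GADM district field names are the default.

    Geometries are repaired with ``make_valid``; features invalid after
    repair are rejected with their ids named.
    """
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    regions, bad = [], []
    for i, f in enumerate(feats):
        props = f.get("properties", {})
        rid = str(props.get(id_field, props.get("region_id", i)))
        name = str(props.get(name_field, props.get("name", rid)))
        geom = shape(f["geometry"])
        if not geom.is_valid:
            geom = shapely.make_valid(geom)
        if not geom.is_valid or geom.is_empty:
            bad.append(rid)
            continue
        regions.append(Region(rid, name, geom))
    if bad:
        raise ValueError(f"invalid geometries after repair: {bad}")
    return RegionSet(regions, country=country)


def save_regions(regions: RegionSet, path, id_field: str = "region_id") -> None:
    feats = [
        {"type": "Feature",
         "properties": {id_field: r.region_id, "name": r.name},
         "geometry": mapping(r.geometry)}
        for r in regions
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


@dataclass
class RegionSummary:
    region_id: str
    nhits_mean: float    # NaN when undefined (no member cells)
    n_cells: int
    is_max: bool = False

    @property
    def defined(self) -> bool:
        return self.n_cells > 0


def zonal_mean(grid, regions: RegionSet) -> list[RegionSummary]:
    """Mean nhits per region over cells whose centers lie inside the polygon.

    Zero-count member cells enter the denominator; regions with no member
    cells report ``n_cells = 0`` and a NaN (missing) mean rather than zero.
    The returned summaries carry ``is_max`` flags from
    :func:`find_max_regions`.
    """
    if len(regions) == 0:
        raise ValueError("empty RegionSet")
    lats, lons = grid.cell_centers()
    lon_m, lat_m = np.meshgrid(lons, lats)
    flat_lon, flat_lat = lon_m.ravel(), lat_m.ravel()
    counts = grid.nhits.ravel()
    out = []
    for r in regions:
        shapely.prepare(r.geometry)
        inside = shapely.contains_xy(r.geometry, flat_lon, flat_lat)
        n = int(inside.sum())
        mean = float(counts[inside].mean()) if n else math.nan
        out.append(RegionSummary(r.region_id, mean, n))
    flagged = find_max_regions(out)
    for s in out:
        s.is_max = s.region_id in flagged
    return out


def find_max_regions(summaries: list[RegionSummary]) -> set[str]:
    """Ids of all regions attaining the maximal defined mean (ties flagged).

    Returns the empty set when every defined mean is zero (or none is
    defined): a uniformly untouched map nominates no source region.
    Scale-invariant: multiplying every count by a positive constant leaves
    the flagged set unchanged.
    """
    if not summaries:
        raise ValueError("need at least one summary")
    defined = [s for s in summaries if s.defined]
    if not defined:
        return set()
    best = max(s.nhits_mean for s in defined)
    if best <= 0:
        return set()
    return {s.region_id for s in defined if s.nhits_mean == best}


def _normalized_means(summaries: list[RegionSummary]) -> dict[str, float]:
    """Per-map min-max normalization of the defined means to [0, 1].

    This is the color scale of the choropleth: invariant under positive
    rescaling of the counts, so the same map rendered from doubled counts
    colors identically.
    """
    defined = [s for s in summaries if s.defined and not math.isnan(s.nhits_mean)]
    if not defined:
        return {}
    vals = [s.nhits_mean for s in defined]
    lo, hi = min(vals), max(vals)
    span = hi - lo
    if span == 0:
        return {s.region_id: 0.0 for s in defined}
    return {s.region_id: (s.nhits_mean - lo) / span for s in defined}


def export_choropleth(summaries: list[RegionSummary], regions: RegionSet,
                      path, title: str = "") -> dict:
    """Write a GeoJSON attribute layer and a rendered PNG map.

    ``path`` is the GeoJSON destination; the PNG lands beside it with the
    same stem.  Colors are normalized per map (min-max of this map's
    defined means); regions with zero or undefined means are drawn grey.
    Returns the paths written.
    """
    by_id = {s.region_id: s for s in summaries}
    missing = [r.region_id for r in regions if r.region_id not in by_id]
    if missing:
        raise ValueError(f"summaries missing for regions: {missing}")

    feats = []
    for r in regions:
        s = by_id[r.region_id]
        feats.append({
            "type": "Feature",
            "properties": {
                "region_id": r.region_id,
                "name": r.name,
                "nhits_mean": None if not s.defined else s.nhits_mean,
                "n_cells": s.n_cells,
                "is_max": bool(s.is_max),
            },
            "geometry": mapping(r.geometry),
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon as MplPolygon

    norm = _normalized_means(summaries)
    cmap = plt.get_cmap("Reds")
    grey = (0.82, 0.82, 0.82, 1.0)
    fig, ax = plt.subplots(figsize=(7, 6))
    for r in regions:
        s = by_id[r.region_id]
        if s.defined and s.nhits_mean > 0 and r.region_id in norm:
            face = cmap(norm[r.region_id])
        else:
            face = grey
        geoms = getattr(r.geometry, "geoms", [r.geometry])
        for g in geoms:
            ax.add_patch(MplPolygon(np.asarray(g.exterior.coords), closed=True,
                                    facecolor=face,
                                    edgecolor="k",
                                    linewidth=2.0 if s.is_max else 0.5))
    ax.autoscale_view()
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    if title:
        ax.set_title(title)
    png = str(path).rsplit(".", 1)[0] + ".png"
    fig.savefig(png, dpi=120)
    plt.close(fig)
    return {"geojson": str(path), "png": png}
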
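"""Model-vs-trap agreement: case labels, hit ratios, candidate pairs.

Each (trap site, sampling period) cell is labelled with two letters, model
first, trap second:

* ``OO`` — a retained trajectory crossed the site's target polygon during
  the period and moths were captured there (a *hit*);
* ``OX`` — a trajectory crossed but nothing was captured (*no-hit*);
* ``XO`` — no trajectory crossed, yet moths were captured;
* ``XX`` — neither.

The hit ratio for a location (column) or period (row) is
``100 * n_OO / (n_OO + n_OX)``.  XO and XX cells never enter either side of
the ratio: with only a handful of traps per country they reflect the
sparseness of the ground truth, not model skill.  A location or period with
no OO/OX cells at all has no computable ratio; it is reported as 0% with
``defined=False``.

Candidate origin-destination pairs are the shortlist for downstream
genotypic/phenotypic validation: an (origin site, destination site, period)
triple is emitted only when the backward grid shows OO at the origin, the
forward grid shows OO at the destination, a backward trajectory released at
that destination crossed the origin's polygon in the period, and a forward
trajectory released at that origin crossed the destination's polygon in the
same period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .occurrence import OccurrenceTable, SamplingPeriod, TrapSite, period_containing

__all__ = ["ComparisonGrid", "HitRatio", "CandidatePair", "Target",
           "trajectory_crosses", "classify_cases", "hit_ratio",
           "match_candidates", "target_from_regions", "target_from_buffer"]

LABELS = ("OO", "OX", "XO", "XX")


@dataclass(frozen=True)
class Target:
    """A trap site together with the polygon trajectories are tested against.

    The default reading of the "target area" is the administrative district
    containing the trap; a circular buffer around the trap coordinates is
    the region-free alternative.
    """

    site: TrapSite
    polygon: shapely.Geometry


def target_from_regions(site: TrapSite, regions) -> Target:
    r = regions.region_containing(site.lat, site.lon)
    if r is None:
        raise ValueError(f"site {site.site_id} lies in no region polygon")
    return Target(site, r.geometry)


def target_from_buffer(site: TrapSite, radius_km: float) -> Target:
    """Circular buffer of radius_km around the trap (equirectangular degrees)."""
    from shapely import affinity

    deg_lat = radius_km / 111.32
    circ = shapely.Point(site.lon, site.lat).buffer(deg_lat, quad_segs=32)
    scale = 1.0 / np.cos(np.radians(site.lat))
    return Target(site, affinity.scale(circ, xfact=scale, yfact=1.0,
                                       origin=(site.lon, site.lat)))


def _split_points(points: np.ndarray, densify: int):
    lat, lon = points[:, 1], points[:, 2]
    if densify <= 0 or len(lat) < 2:
        return lat, lon
    f = np.linspace(0.0, 1.0, densify + 2)[:-1]
    la = (lat[:-1, None] * (1 - f) + lat[1:, None] * f).ravel()
    lo = (lon[:-1, None] * (1 - f) + lon[1:, None] * f).ravel()
    return np.append(la, lat[-1]), np.append(lo, lon[-1])


def trajectory_crosses(ensemble, target_polygon, period: SamplingPeriod,
                       densify: int = 0) -> bool:
    """True iff any trajectory released in ``period`` has a point in the polygon.

    Point semantics (matching the rasterizer): a path that straddles the
    polygon between recorded points does not cross unless densification
    places a point inside.
    """
    shapely.prepare(target_polygon)
    for t in ensemble:
        if period_containing(t.init_time.date(), [period]) is None:
            continue
        la, lo = _split_points(np.asarray(t.points, dtype=float), densify)
        if shapely.intersects_xy(target_polygon, lo, la).any():
            return True
    return False


@dataclass
class ComparisonGrid:
    """Periods x sites table of case labels.

    ``df`` is indexed by period_id (rows, in campaign order) with one
    column per trap site.
    """

    df: pd.DataFrame
    direction: str = ""
    country: str = ""

    def __post_init__(self) -> None:
        bad = set(self.df.values.ravel()) - set(LABELS)
        if bad:
            raise ValueError(f"invalid case labels: {bad}")

    def label(self, period_id: str, site_id: str) -> str:
        return str(self.df.at[period_id, site_id])

    @property
    def periods(self) -> list[str]:
        return list(self.df.index)

    @property
    def sites(self) -> list[str]:
        return list(self.df.columns)

    def counts(self) -> dict[str, int]:
        flat = self.df.values.ravel()
        return {lab: int((flat == lab).sum()) for lab in LABELS}

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index_label="period_id")

    @classmethod
    def from_csv(cls, path, direction: str = "", country: str = "") -> "ComparisonGrid":
        return cls(pd.read_csv(path, index_col="period_id"),
                   direction=direction, country=country)


def classify_cases(ensemble, occ: OccurrenceTable, targets: list[Target],
                   periods: list[SamplingPeriod], densify: int = 0,
                   direction: str = "", country: str = "") -> ComparisonGrid:
    """Label every (trap, period) cell from (crossed?, captured?).

    ``ensemble`` is the Step-2-filtered ensemble arriving in the targets'
    country.  Occurrence records missing for a (trap, period) are treated
    as count 0.
    """
    data = {}
    by_period = {p.period_id: [] for p in periods}
    for t in ensemble:
        p = period_containing(t.init_time.date(), periods)
        if p is not None:
            by_period[p.period_id].append(t)
    for tgt in targets:
        shapely.prepare(tgt.polygon)
        col = []
        for p in periods:
            crossed = False
            for t in by_period[p.period_id]:
                la, lo = _split_points(np.asarray(t.points, dtype=float), densify)
                if shapely.intersects_xy(tgt.polygon, lo, la).any():
                    crossed = True
                    break
            captured = occ.count_for(tgt.site.site_id, p.period_id) > 0
            col.append(("O" if crossed else "X") + ("O" if captured else "X"))
        data[tgt.site.site_id] = col
    df = pd.DataFrame(data, index=[p.period_id for p in periods])
    return ComparisonGrid(df, direction=direction, country=country)


@dataclass
class HitRatio:
    key: str             # site_id or period_id
    n_OO: int
    n_OX: int
    ratio_percent: float
    defined: bool

    @staticmethod
    def from_counts(key: str, n_oo: int, n_ox: int) -> "HitRatio":
        denom = n_oo + n_ox
        if denom == 0:
            return HitRatio(key, n_oo, n_ox, 0.0, False)
        return HitRatio(key, n_oo, n_ox, 100.0 * n_oo / denom, True)


def hit_ratio(grid: ComparisonGrid, by: str = "location") -> list[HitRatio]:
    """Hit ratios per column (``by="location"``) or per row (``by="period"``).

    An empty denominator (no OO or OX cells) is reported as ratio 0 with
    ``defined=False`` — the convention used when a ratio is "impossible to
    calculate".
    """
    if by not in ("location", "period"):
        raise ValueError("by must be 'location' or 'period'")
    axis = 0 if by == "location" else 1
    keys = grid.sites if by == "location" else grid.periods
    vals = grid.df.values
    out = []
    for i, key in enumerate(keys):
        cells = vals[:, i] if axis == 0 else vals[i, :]
        out.append(HitRatio.from_counts(key,
                                        int((cells == "OO").sum()),
                                        int((cells == "OX").sum())))
    return out


def hit_ratio_frame(ratios: list[HitRatio]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.key, r.n_OO, r.n_OX, r.ratio_percent, r.defined) for r in ratios],
        columns=["key", "n_OO", "n_OX", "hit_ratio_percent", "defined"],
    )


@dataclass(frozen=True)
class CandidatePair:
    origin_site: str
    destination_site: str
    period_id: str


def match_candidates(backward_grid: ComparisonGrid, forward_grid: ComparisonGrid,
                     backward_ensemble, forward_ensemble,
                     origin_targets: list[Target],
                     destination_targets: list[Target],
                     periods: list[SamplingPeriod],
                     densify: int = 0) -> list[CandidatePair]:
    """Match backward and forward hits into origin-destination candidates.

    The backward ensemble is released at destination-country traps with the
    origin-country traps as targets; the forward ensemble is the mirror.
    Both grids must cover identical period bins.
    """
    if backward_grid.periods != forward_grid.periods:
        raise ValueError("backward and forward grids cover different periods")
    by_id = {p.period_id: p for p in periods}
    dest_by_id = {t.site.site_id: t for t in destination_targets}
    pairs: set[CandidatePair] = set()
    for origin in origin_targets:
        oid = origin.site.site_id
        shapely.prepare(origin.polygon)
        for pid in backward_grid.periods:
            if backward_grid.label(pid, oid) != "OO":
                continue
            period = by_id[pid]
            # destination-country release sites whose backward parcels
            # reached this origin's polygon in the period
            dest_starts = set()
            for t in backward_ensemble:
                if period_containing(t.init_time.date(), [period]) is None:
                    continue
                la, lo = _split_points(np.asarray(t.points, dtype=float), densify)
                if shapely.intersects_xy(origin.polygon, lo, la).any():
                    dest_starts.add(t.site_id)
            for did in dest_starts:
                if did not in dest_by_id:
                    continue
                if forward_grid.label(pid, did) != "OO":
                    continue
                fwd_from_origin = forward_ensemble.subset(
                    lambda t, o=oid: t.site_id == o
                )
                if trajectory_crosses(fwd_from_origin, dest_by_id[did].polygon,
                                      period, densify=densify):
                    pairs.add(CandidatePair(oid, did, pid))
    period_order = {p.period_id: i for i, p in enumerate(periods)}
    return sorted(pairs, key=lambda c: (period_order[c.period_id],
                                        c.origin_site, c.destination_site))


def candidate_frame(pairs: list[CandidatePair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.period_id, c.origin_site, c.destination_site) for c in pairs],
        columns=["period_id", "origin_site", "destination_site"],
    )


def export_grid_image(grid: ComparisonGrid, path,
                      candidates: list[CandidatePair] | None = None,
                      site_role: str = "destination") -> None:
    """Colored comparison table: blue OO (hit), red OX (no-hit), grey X rows.

    Candidate cells (site and period appearing in a matched pair) get a
    bold outline.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"OO": "#4f81bd", "OX": "#c0504d", "XO": "#d9d9d9", "XX": "#f2f2f2"}
    bold = set()
    for c in candidates or []:
        sid = c.destination_site if site_role == "destination" else c.origin_site
        bold.add((c.period_id, sid))
    nrows, ncols = len(grid.periods), len(grid.sites)
    fig, ax = plt.subplots(figsize=(1.0 + 0.7 * ncols, 1.0 + 0.4 * nrows))
    for i, pid in enumerate(grid.periods):
        for j, sid in enumerate(grid.sites):
            lab = grid.label(pid, sid)
            lw = 2.5 if (pid, sid) in bold else 0.5
            ax.add_patch(plt.Rectangle((j, nrows - 1 - i), 1, 1,
                                       facecolor=colors[lab], edgecolor="k",
                                       linewidth=lw))
            ax.text(j + 0.5, nrows - 0.5 - i, f"{lab[0]}-{lab[1]}",
                    ha="center", va="center", fontsize=8)
    ax.set_xlim(0, ncols)
    ax.set_ylim(0, nrows)
    ax.set_xticks(np.arange(ncols) + 0.5, grid.sites, fontsize=8)
    ax.set_yticks(np.arange(nrows) + 0.5, list(reversed(grid.periods)), fontsize=7)
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
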
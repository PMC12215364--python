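"""Synthetic inputs with known structure: wind, regions, traps, counts.

Every pipeline stage is testable without downloads: analytic wind regimes
(uniform flow, solid-body rotation, a westerly jet with a sinusoidal
meander) admit closed-form or near-closed-form trajectories; administrative
districts are rectangular tilings; and the migration scenario plants a
known origin-destination connection that the full pipeline should recover.

The default scenario emulates the statistical shape of a two-country trap
campaign: an origin country upwind (west) with one truly emitting site and
decoy sites that catch moths without wind connectivity to the destinations,
and a destination country downwind whose traps record arrivals.  Counts are
Poisson; deliveries are decided by a distance radius around integrated
forward trajectories rather than by the pipeline's own polygon-crossing
rules, so the planted truth is independent of the code under test.

Origin-country districts default to latitudinal strips (one per 2 degrees
of latitude): under a predominantly zonal flow the backward-trajectory
corridor crosses every longitude at one latitude band, so strip districts
make the maximal-mean district well defined, where a 2-D tiling would tie
along the corridor.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .occurrence import OccurrenceTable, SamplingPeriod, TrapSite, weekly_periods
from .tdump import write_tdump  # re-exported: fixture writer lives with the parser
from .trajectory import TrajectoryConfig, run_campaign
from .windfield import WindField
from .zonal import Region, RegionSet

__all__ = ["ScenarioSpec", "make_windfield", "make_regions", "make_sites",
           "simulate_migration_scenario", "default_scenario", "write_tdump"]

EARTH_RADIUS_KM = 6371.0
M_PER_DEG = 111_320.0


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of a planted-migration scenario (pure function of seed)."""

    seed: int = 0
    # wind
    wind_kind: str = "westerly_jet"       # uniform | solid_rotation | westerly_jet
    U0: float = 5.0                        # mean zonal wind, m/s
    V0: float = 0.4                        # meridional amplitude, m/s
    A: float = 1.5                         # jet shear amplitude, m/s
    L: float = 12.0                        # jet latitudinal wavelength, deg
    M: float = 14.0                        # meander longitudinal wavelength, deg
    omega: float = 7.27e-6                 # solid-rotation angular velocity, rad/s
    center: tuple[float, float] = (35.0, 125.0)   # rotation center (lat, lon)
    lat_bounds: tuple[float, float] = (26.0, 44.0)
    lon_bounds: tuple[float, float] = (106.0, 134.0)
    grid_step: float = 1.0                 # deg
    time_step_hours: int = 24
    # campaign
    start_date: dt.date = dt.date(2022, 4, 3)
    n_periods: int = 8
    period_length: int = 7
    # sites
    n_origin_sites: int = 3
    n_destination_sites: int = 5
    true_origin_ids: tuple[str, ...] = ("O1",)
    origin_lat: float = 34.2               # latitude of the emitting origin
    decoy_lats: tuple[float, ...] = (38.2, 30.2)
    origin_lon: float = 117.5
    dest_lat: float = 34.2
    dest_lat_jitter: float = 0.25          # deg, uniform
    dest_lons: tuple[float, ...] = (125.8, 126.2, 126.6, 127.0, 127.4)
    # counts
    emission_rate: float = 20.0            # mean moths per period at occupied origins
    capture_rate: float = 0.8              # thinning probability at destinations
    connect_radius_km: float = 100.0       # delivery distance to a trajectory point

    def __post_init__(self) -> None:
        if not (0 < self.capture_rate <= 1):
            raise ValueError("capture_rate must lie in (0, 1]")
        if self.emission_rate <= 0:
            raise ValueError("emission_rate must be positive")
        n_decoys = self.n_origin_sites - len(self.true_origin_ids)
        if n_decoys < 0:
            raise ValueError("more true origins than origin sites")
        if len(self.decoy_lats) < n_decoys:
            raise ValueError("not enough decoy latitudes for the decoy count")

    def periods(self) -> list[SamplingPeriod]:
        end = self.start_date + dt.timedelta(days=self.n_periods * self.period_length - 1)
        return weekly_periods(self.start_date, end, self.period_length)


def make_windfield(spec: ScenarioSpec) -> WindField:
    """Deterministic analytic wind field over the scenario domain.

    Kinds: ``uniform`` (u=U0, v=V0 everywhere); ``solid_rotation`` (rigid
    rotation about ``center`` at ``omega`` rad/s in the local
    equirectangular plane — circular streamlines, a fixed point at the
    center); ``westerly_jet`` (u = U0 + A*sin(2*pi*lat/L),
    v = V0*sin(2*pi*lon/M) — a sheared westerly with a standing meander;
    A=0, V0=0 reduces it to uniform flow).
    """
    la0, la1 = spec.lat_bounds
    lo0, lo1 = spec.lon_bounds
    if la0 >= la1 or lo0 >= lo1:
        raise ValueError("degenerate wind domain")
    lats = np.arange(la0, la1 + 1e-9, spec.grid_step)
    lons = np.arange(lo0, lo1 + 1e-9, spec.grid_step)
    # cover the campaign plus the 72-h integration margin on both sides
    t_first = pd.Timestamp(spec.start_date) - pd.Timedelta(hours=96)
    t_last = (pd.Timestamp(spec.start_date)
              + pd.Timedelta(days=spec.n_periods * spec.period_length)
              + pd.Timedelta(hours=96))
    times = pd.date_range(t_first, t_last, freq=f"{spec.time_step_hours}h")
    lon_m, lat_m = np.meshgrid(lons, lats)

    if spec.wind_kind == "uniform":
        u2d = np.full_like(lat_m, spec.U0)
        v2d = np.full_like(lat_m, spec.V0)
    elif spec.wind_kind == "westerly_jet":
        u2d = spec.U0 + spec.A * np.sin(2 * np.pi * lat_m / spec.L)
        v2d = spec.V0 * np.sin(2 * np.pi * lon_m / spec.M)
    elif spec.wind_kind == "solid_rotation":
        lat_c, lon_c = spec.center
        x = (lon_m - lon_c) * M_PER_DEG * np.cos(np.radians(lat_c))
        y = (lat_m - lat_c) * M_PER_DEG
        u2d = -spec.omega * y
        v2d = spec.omega * x
    else:
        raise ValueError(f"unknown wind_kind {spec.wind_kind!r}")

    u = np.broadcast_to(u2d, (len(times),) + u2d.shape).copy()
    v = np.broadcast_to(v2d, (len(times),) + v2d.shape).copy()
    return WindField(lats, lons, times.to_numpy(), u, v)


def make_regions(bbox: tuple[float, float, float, float], n_rows: int,
                 n_cols: int, country: str = "") -> RegionSet:
    """Rectangular district tiling of ``bbox = (lat0, lon0, lat1, lon1)``.

    Ids are ``R{row}_{col}`` with row 0 the southernmost; the tiling is
    disjoint and covers the box exactly.
    """
    lat0, lon0, lat1, lon1 = bbox
    if lat0 >= lat1 or lon0 >= lon1 or n_rows < 1 or n_cols < 1:
        raise ValueError("degenerate region tiling")
    dlat = (lat1 - lat0) / n_rows
    dlon = (lon1 - lon0) / n_cols
    regions = []
    for r in range(n_rows):
        for c in range(n_cols):
            geom = shapely.box(lon0 + c * dlon, lat0 + r * dlat,
                               lon0 + (c + 1) * dlon, lat0 + (r + 1) * dlat)
            regions.append(Region(f"R{r}_{c}", f"R{r}_{c}", geom))
    return RegionSet(regions, country=country)


def make_sites(spec: ScenarioSpec, rng: np.random.Generator
               ) -> tuple[list[TrapSite], list[TrapSite]]:
    """Origin sites (one emitter per true_origin_id plus decoys) and
    destination traps with jittered latitudes."""
    origins = []
    decoy_iter = iter(spec.decoy_lats)
    for i in range(spec.n_origin_sites):
        sid = f"O{i + 1}"
        lat = spec.origin_lat if sid in spec.true_origin_ids else next(decoy_iter)
        origins.append(TrapSite(sid, "origin", lat, spec.origin_lon))
    dests = []
    for i in range(spec.n_destination_sites):
        lat = spec.dest_lat + rng.uniform(-spec.dest_lat_jitter,
                                          spec.dest_lat_jitter)
        lon = spec.dest_lons[i % len(spec.dest_lons)]
        dests.append(TrapSite(f"D{i + 1}", "destination", float(lat), lon))
    return origins, dests


def _haversine_km(lat1, lon1, lat2, lon2):
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def simulate_migration_scenario(spec: ScenarioSpec, field: WindField | None = None):
    """Generate origin/destination occurrence tables and the planted truth.

    All origin sites (emitters and decoys) draw per-period counts from
    Poisson(emission_rate).  For each (true origin, period) with a positive
    count, forward trajectories are integrated (one per campaign day at
    00 UTC); a destination within ``connect_radius_km`` of any trajectory
    point is *delivered* and records, with probability ``capture_rate``, a
    positive count 1 + Poisson(capture_rate * emission_rate), else 0.
    Decoy origins get counts but never deliver.

    Returns ``(origin_table, destination_table, truth)`` where ``truth``
    holds sites, intended (delivered) links and realized (captured) links.
    """
    rng = np.random.default_rng(spec.seed)
    if field is None:
        field = make_windfield(spec)
    periods = spec.periods()
    origins, dests = make_sites(spec, rng)

    origin_rows = []
    for s in origins:
        for p in periods:
            origin_rows.append((s.site_id, p.period_id,
                                int(rng.poisson(spec.emission_rate))))
    origin_table = OccurrenceTable(
        pd.DataFrame(origin_rows, columns=["site_id", "period_id", "count"]),
        native_resolution="interval",
    )

    cfg = TrajectoryConfig(direction="forward", daily_hours=(0,),
                           duration=72, output_interval=1)
    true_sites = [s for s in origins if s.site_id in spec.true_origin_ids]

    intended: list[tuple[str, str, str]] = []   # (origin, dest, period)
    delivered: dict[tuple[str, str], set[str]] = {}
    for s in true_sites:
        for p in periods:
            if origin_table.count_for(s.site_id, p.period_id) <= 0:
                continue
            days = pd.date_range(p.start, p.end, freq="D")
            ens = run_campaign([s], list(days), cfg, field)
            pts = np.vstack([t.points[:, 1:3] for t in ens]) if len(ens) else None
            for d in dests:
                if pts is None:
                    continue
                dist = _haversine_km(pts[:, 0], pts[:, 1], d.lat, d.lon)
                if dist.min() <= spec.connect_radius_km:
                    intended.append((s.site_id, d.site_id, p.period_id))
                    delivered.setdefault((d.site_id, p.period_id), set()).add(s.site_id)

    dest_rows = []
    realized: list[tuple[str, str, str]] = []
    for d in dests:
        for p in periods:
            key = (d.site_id, p.period_id)
            count = 0
            if key in delivered and rng.random() < spec.capture_rate:
                count = 1 + int(rng.poisson(spec.capture_rate * spec.emission_rate))
                for o in sorted(delivered[key]):
                    realized.append((o, d.site_id, p.period_id))
            dest_rows.append((d.site_id, p.period_id, count))
    dest_table = OccurrenceTable(
        pd.DataFrame(dest_rows, columns=["site_id", "period_id", "count"]),
        native_resolution="interval",
    )

    truth = {
        "true_origins": list(spec.true_origin_ids),
        "decoy_origins": [s.site_id for s in origins
                          if s.site_id not in spec.true_origin_ids],
        "origin_sites": origins,
        "destination_sites": dests,
        "intended_links": intended,
        "realized_links": realized,
    }
    return origin_table, dest_table, truth


def default_scenario(seed: int = 0) -> ScenarioSpec:
    """The reference planted-migration scenario: 1 emitting origin, 2 decoys,
    5 destination traps, 8 weekly periods, sheared-westerly wind."""
    return ScenarioSpec(seed=seed)


def default_origin_regions() -> RegionSet:
    """Latitudinal strip districts for the origin country (see module note)."""
    return make_regions((29.0, 113.0, 41.0, 121.0), n_rows=6, n_cols=1,
                        country="origin")


def default_destination_regions() -> RegionSet:
    return make_regions((29.0, 122.0, 41.0, 130.0), n_rows=6, n_cols=1,
                        country="destination")
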
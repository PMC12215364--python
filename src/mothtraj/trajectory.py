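"""Forward/backward air-parcel trajectory integration over a wind field.

The integrator is the standard two-stage predictor-corrector used by
Lagrangian trajectory models: from position P at time t,

    P' = P + V(P, t) * dt                  (predictor)
    P(t + dt) = P + 0.5 * [V(P, t) + V(P', t + dt)] * dt   (corrector)

with an internal step (default 6 minutes) much shorter than the hourly
output cadence.  Backward trajectories use dt < 0, sampling the wind at the
correspondingly earlier times.  Horizontal displacement converts metres to
degrees with a local equirectangular metric (1 deg lat = 111,320 m;
1 deg lon = 111,320 * cos(lat) m); this is a regional mid-latitude tool and
polar domains are rejected by :class:`~mothtraj.windfield.WindField`.

A parcel that leaves the horizontal domain, runs past the field's time
coverage, or exceeds the model top is truncated (flagged), never
extrapolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .windfield import WindField

__all__ = [
    "TrajectoryConfig",
    "Trajectory",
    "TrajectoryEnsemble",
    "integrate_trajectory",
    "run_campaign",
]

log = logging.getLogger(__name__)

M_PER_DEG_LAT = 111_320.0


@dataclass(frozen=True)
class TrajectoryConfig:
    """Initialization and integration settings for one release point.

    ``daily_hours`` lists the UTC hours of day at which runs start on each
    simulation day (the full 0..23 by default, i.e. hourly releases);
    ``vert_motion`` advects height with the field's vertical velocity when
    one is present, otherwise height is held fixed.
    """

    lat: float = 0.0
    lon: float = 0.0
    height: float = 1000.0          # m AGL at release
    duration: int = 72              # simulated hours
    direction: str = "backward"
    daily_hours: tuple[int, ...] = tuple(range(24))
    model_height: float = 20_000.0  # vertical cap, m
    vert_motion: bool = False
    output_interval: int = 1        # hours between recorded positions
    internal_dt: float = 0.1        # integration step, hours

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"direction must be forward|backward, got {self.direction!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not self.daily_hours:
            raise ValueError("daily_hours must not be empty")
        if any(h < 0 or h > 23 for h in self.daily_hours):
            raise ValueError("daily_hours entries must lie in 0..23")
        if self.height >= self.model_height:
            raise ValueError("start height must be below model_height")
        if self.output_interval <= 0 or self.duration % self.output_interval:
            raise ValueError("output_interval must divide duration")


@dataclass
class Trajectory:
    """One parcel path: ordered (elapsed_hours, lat, lon, height) records.

    ``elapsed_hours`` counts simulated hours from release in both
    directions; the wall-clock time of point k is
    ``init_time + elapsed`` for forward and ``init_time - elapsed`` for
    backward runs.  ``truncated`` marks parcels that left the domain or the
    vertical bounds before completing the configured duration.
    """

    site_id: str
    init_time: pd.Timestamp
    direction: str
    points: np.ndarray  # shape (n, 4): elapsed_h, lat, lon, height
    truncated: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.init_time = pd.Timestamp(self.init_time)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def lats(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def lons(self) -> np.ndarray:
        return self.points[:, 2]

    def times(self) -> pd.DatetimeIndex:
        sign = 1 if self.direction == "forward" else -1
        return self.init_time + pd.to_timedelta(sign * self.points[:, 0], unit="h")


@dataclass
class TrajectoryEnsemble:
    """A collection of same-direction trajectories with campaign metadata."""

    trajectories: list[Trajectory]
    direction: str
    provenance: str = "simulated"   # simulated | tdump
    sites: tuple[str, ...] = ()
    rejections: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t in self.trajectories:
            if t.direction != self.direction:
                raise ValueError("all ensemble members must share direction")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def subset(self, keep) -> "TrajectoryEnsemble":
        return replace(self, trajectories=[t for t in self.trajectories if keep(t)])

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: one row per recorded position."""
        rows = []
        for t in self.trajectories:
            for e, la, lo, h in t.points:
                rows.append((t.site_id, t.init_time, t.direction, e, la, lo, h,
                             t.truncated))
        return pd.DataFrame(
            rows,
            columns=["site_id", "init_time", "direction", "elapsed_h",
                     "lat", "lon", "height_m", "truncated"],
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TrajectoryEnsemble":
        trajs = []
        df = df.copy()
        df["init_time"] = pd.to_datetime(df["init_time"])
        for (sid, it, direction), g in df.groupby(
            ["site_id", "init_time", "direction"], sort=True
        ):
            g = g.sort_values("elapsed_h")
            pts = g[["elapsed_h", "lat", "lon", "height_m"]].to_numpy(float)
            trajs.append(Trajectory(str(sid), it, direction, pts,
                                    truncated=bool(g["truncated"].any())))
        direction = trajs[0].direction if trajs else "forward"
        return cls(trajs, direction,
                   sites=tuple(sorted({t.site_id for t in trajs})))


def _hours(ts: pd.Timestamp) -> float:
    return pd.Timestamp(ts).value / 3.6e12


def _integrate_batch(
    field: WindField,
    lat0: np.ndarray,
    lon0: np.ndarray,
    h0: np.ndarray,
    t0_h: np.ndarray,
    cfg: TrajectoryConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance N parcels together.

    Returns ``(paths, n_valid)``: paths has shape (N, n_out+1, 4) with NaN
    rows past truncation, n_valid the number of recorded rows per parcel.
    """
    n = lat0.size
    sign = 1.0 if cfg.direction == "forward" else -1.0
    n_sub = max(1, int(round(cfg.output_interval / cfg.internal_dt)))
    dt = cfg.output_interval / n_sub          # hours, exact divisor
    dts = sign * dt * 3600.0                  # signed seconds
    n_out = cfg.duration // cfg.output_interval

    lat = lat0.astype(float).copy()
    lon = lon0.astype(float).copy()
    hgt = h0.astype(float).copy()
    active = np.ones(n, dtype=bool)

    paths = np.full((n, n_out + 1, 4), np.nan)
    paths[:, 0, 0] = 0.0
    paths[:, 0, 1] = lat
    paths[:, 0, 2] = lon
    paths[:, 0, 3] = hgt
    n_valid = np.ones(n, dtype=int)

    use_w = cfg.vert_motion and field.w is not None
    elapsed = 0.0
    for k_out in range(1, n_out + 1):
        for _ in range(n_sub):
            t_cur = t0_h + sign * elapsed
            u1, v1, w1, ok1 = field.sample_many(lat, lon, t_cur)
            active &= ok1
            if not active.any():
                return paths, n_valid
            dlat1 = dts * v1 / M_PER_DEG_LAT
            dlon1 = dts * u1 / (M_PER_DEG_LAT * np.cos(np.radians(lat)))
            lat_p = lat + dlat1
            lon_p = _wrap_lon(lon + dlon1)
            u2, v2, w2, ok2 = field.sample_many(lat_p, lon_p, t0_h + sign * (elapsed + dt))
            active &= ok2
            dlat = 0.5 * dts * (v1 + v2) / M_PER_DEG_LAT
            dlon = 0.5 * dts * (
                u1 / np.cos(np.radians(lat)) + u2 / np.cos(np.radians(lat_p))
            ) / M_PER_DEG_LAT
            lat = np.where(active, lat + dlat, lat)
            lon = np.where(active, _wrap_lon(lon + dlon), lon)
            if use_w:
                hgt = np.where(active, np.maximum(hgt + 0.5 * dts * (w1 + w2), 0.0), hgt)
                active &= hgt <= cfg.model_height
            elapsed += dt
        rec = active
        paths[rec, k_out, 0] = elapsed
        paths[rec, k_out, 1] = lat[rec]
        paths[rec, k_out, 2] = lon[rec]
        paths[rec, k_out, 3] = hgt[rec]
        n_valid[rec] = k_out + 1
    return paths, n_valid


def _wrap_lon(lon: np.ndarray) -> np.ndarray:
    return (lon + 180.0) % 360.0 - 180.0


def integrate_trajectory(
    config: TrajectoryConfig,
    field: WindField,
    init_time,
    site_id: str = "start",
) -> Trajectory:
    """Integrate a single parcel released at ``(config.lat, config.lon)``.

    Raises ``ValueError`` if the release point (in space and time) is not
    inside the wind field.
    """
    t0 = pd.Timestamp(init_time)
    if not field.contains(config.lat, config.lon, t0):
        raise ValueError(
            f"start point outside wind-field domain: site={site_id!r} "
            f"lat={config.lat} lon={config.lon} time={t0}"
        )
    paths, n_valid = _integrate_batch(
        field,
        np.array([config.lat]), np.array([config.lon]),
        np.array([config.height]), np.array([_hours(t0)]), config,
    )
    n_expected = config.duration // config.output_interval + 1
    nv = int(n_valid[0])
    return Trajectory(
        site_id=site_id,
        init_time=t0,
        direction=config.direction,
        points=paths[0, :nv, :],
        truncated=nv < n_expected,
    )


def run_campaign(sites, dates, config_template: TrajectoryConfig,
                 field: WindField) -> TrajectoryEnsemble:
    """One trajectory per (site, date, daily_hour) triple.

    ``sites`` is an iterable of objects with ``site_id``, ``lat``, ``lon``
    attributes (or (site_id, lat, lon) tuples); ``dates`` an iterable of
    calendar dates (UTC days).  Releases whose start point falls outside the
    field are rejected and logged, not integrated.
    """
    sites = list(sites)
    dates = list(dates)
    if not sites or not dates:
        raise ValueError("run_campaign needs at least one site and one date")

    def unpack(s):
        if hasattr(s, "site_id"):
            return s.site_id, float(s.lat), float(s.lon)
        sid, la, lo = s
        return str(sid), float(la), float(lo)

    starts = []          # (site_id, lat, lon, init_time)
    rejections = []
    for s in sites:
        sid, la, lo = unpack(s)
        for d in dates:
            day = pd.Timestamp(d)
            for h in sorted(config_template.daily_hours):
                t0 = day + pd.Timedelta(hours=int(h))
                if field.contains(la, lo, t0):
                    starts.append((sid, la, lo, t0))
                else:
                    msg = f"rejected start: site={sid} lat={la} lon={lo} time={t0}"
                    rejections.append(msg)
                    log.warning(msg)

    trajs: list[Trajectory] = []
    if starts:
        lat0 = np.array([s[1] for s in starts])
        lon0 = np.array([s[2] for s in starts])
        h0 = np.full(len(starts), config_template.height)
        t0h = np.array([_hours(s[3]) for s in starts])
        paths, n_valid = _integrate_batch(field, lat0, lon0, h0, t0h,
                                          config_template)
        n_expected = config_template.duration // config_template.output_interval + 1
        for idx, (sid, _, _, t0) in enumerate(starts):
            nv = int(n_valid[idx])
            trajs.append(Trajectory(sid, t0, config_template.direction,
                                    paths[idx, :nv, :], truncated=nv < n_expected))
    return TrajectoryEnsemble(
        trajs,
        direction=config_template.direction,
        provenance="simulated",
        sites=tuple(sorted({unpack(s)[0] for s in sites})),
        rejections=rejections,
    )
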
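"""Trap sites, sampling periods and moth occurrence counts.

Pheromone-trap campaigns yield per-site count series at either daily
resolution (inspection every day) or interval resolution (counts attributed
to the inspection interval).  Downstream comparison grids are keyed on
fixed sampling periods — typically 7-day bins from the campaign start with
a truncated final bin — so daily tables are aggregated onto those bins.
Occurrence drives Step-2 filtering: trajectories initialized at a site and
period with zero captures are excluded from the frequency analysis.

Date-to-period membership is inclusive on both ends; periods must not
overlap.  Counts from interval-censored traps are attributed wholly to the
period containing the inspection date.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, replace

import pandas as pd

__all__ = [
    "TrapSite",
    "SamplingPeriod",
    "OccurrenceTable",
    "weekly_periods",
    "period_containing",
    "load_sites",
    "load_occurrence",
    "aggregate_to_periods",
    "filter_trajectories",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrapSite:
    site_id: str
    country: str          # role label: origin | destination
    lat: float
    lon: float
    region_id: str | None = None


@dataclass(frozen=True)
class SamplingPeriod:
    period_id: str
    start: dt.date
    end: dt.date          # inclusive

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"period {self.period_id}: start after end")

    def contains(self, day: dt.date) -> bool:
        return self.start <= day <= self.end


def _as_date(x) -> dt.date:
    if isinstance(x, dt.datetime):
        return x.date()
    if isinstance(x, dt.date):
        return x
    return pd.Timestamp(x).date()


def _label(start: dt.date, end: dt.date) -> str:
    return f"{start:%m/%d}-{end:%m/%d}"


def weekly_periods(start, end, length: int = 7) -> list[SamplingPeriod]:
    """Fixed-length bins from ``start``, final bin truncated at ``end``.

    Labels follow the month/day convention of field reports
    (e.g. ``04/03-04/09``); both bounds are inclusive.
    """
    start, end = _as_date(start), _as_date(end)
    if start > end:
        raise ValueError("campaign end precedes start")
    out, s = [], start
    while s <= end:
        e = min(s + dt.timedelta(days=length - 1), end)
        out.append(SamplingPeriod(_label(s, e), s, e))
        s = e + dt.timedelta(days=1)
    return out


def _check_disjoint(periods: list[SamplingPeriod]) -> None:
    ordered = sorted(periods, key=lambda p: p.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start <= a.end:
            raise ValueError(f"periods {a.period_id} and {b.period_id} overlap")


def period_containing(day, periods: list[SamplingPeriod]) -> SamplingPeriod | None:
    day = _as_date(day)
    for p in periods:
        if p.contains(day):
            return p
    return None


@dataclass
class OccurrenceTable:
    """Per-site counts at daily or interval (period) resolution.

    ``df`` always has columns ``site_id, period_id, count``; daily tables
    additionally carry a ``date`` column and use the ISO date as period_id.
    """

    df: pd.DataFrame
    native_resolution: str = "interval"   # daily | interval

    def __post_init__(self) -> None:
        req = {"site_id", "period_id", "count"}
        if not req <= set(self.df.columns):
            raise ValueError(f"occurrence table missing columns {req - set(self.df.columns)}")
        if (self.df["count"] < 0).any():
            bad = self.df.index[self.df["count"] < 0][0]
            raise ValueError(f"negative count at row {bad}")
        if self.df.duplicated(["site_id", "period_id"]).any():
            raise ValueError("duplicate (site_id, period_id) records")
        self.df = self.df.reset_index(drop=True)

    def count_for(self, site_id: str, period_id: str) -> int:
        m = self.df[(self.df["site_id"] == site_id)
                    & (self.df["period_id"] == period_id)]
        return int(m["count"].iloc[0]) if len(m) else 0

    def total(self) -> int:
        return int(self.df["count"].sum())

    def sites(self) -> list[str]:
        return sorted(self.df["site_id"].unique())


def load_sites(path) -> list[TrapSite]:
    """Sites CSV: columns site_id, country, lat, lon[, region_id]."""
    df = pd.read_csv(path)
    has_region = "region_id" in df.columns
    return [
        TrapSite(str(r.site_id), str(r.country), float(r.lat), float(r.lon),
                 str(r.region_id) if has_region and pd.notna(r.region_id) else None)
        for r in df.itertuples()
    ]


def load_occurrence(table_path, sites_path=None, sites=None) -> OccurrenceTable:
    """Load and validate an occurrence CSV.

    Daily layout: ``site_id, date, count``.  Interval layouts:
    ``site_id, period_start, period_end, count`` (period labelled
    ``mm/dd-mm/dd``) or pre-labelled ``site_id, period_id, count``.
    Unknown site ids (against the site register) are an error; negative
    counts or unparseable dates name the offending row.
    """
    df = pd.read_csv(table_path)
    if sites is None and sites_path is not None:
        sites = load_sites(sites_path)
    if sites is not None:
        known = {s.site_id for s in sites}
        unknown = set(df["site_id"].astype(str)) - known
        if unknown:
            raise ValueError(f"unknown site_ids in occurrence table: {sorted(unknown)}")

    for i, c in df["count"].items():
        try:
            if int(c) < 0:
                raise ValueError
        except (TypeError, ValueError):
            raise ValueError(f"{table_path}: row {i}: invalid count {c!r}") from None
    df["count"] = df["count"].astype(int)
    df["site_id"] = df["site_id"].astype(str)

    if "period_id" in df.columns:
        out = df[["site_id", "period_id", "count"]].copy()
        out["period_id"] = out["period_id"].astype(str)
        return OccurrenceTable(out, native_resolution="interval")

    if "date" in df.columns:
        try:
            dates = pd.to_datetime(df["date"])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{table_path}: unparseable date column: {exc}") from None
        out = pd.DataFrame({
            "site_id": df["site_id"],
            "period_id": dates.dt.strftime("%Y-%m-%d"),
            "count": df["count"],
            "date": dates.dt.date,
        })
        return OccurrenceTable(out, native_resolution="daily")

    if {"period_start", "period_end"} <= set(df.columns):
        s = pd.to_datetime(df["period_start"]).dt.date
        e = pd.to_datetime(df["period_end"]).dt.date
        out = pd.DataFrame({
            "site_id": df["site_id"],
            "period_id": [_label(a, b) for a, b in zip(s, e)],
            "count": df["count"],
        })
        return OccurrenceTable(out, native_resolution="interval")
    raise ValueError(f"{table_path}: need either a 'date' or "
                     "'period_start'/'period_end' columns")


def complete(table: OccurrenceTable, sites: list[str],
             periods: list[SamplingPeriod]) -> OccurrenceTable:
    """Fill missing (site, period) combinations with count 0 (logged)."""
    rows, missing = [], 0
    have = {(r.site_id, r.period_id) for r in table.df.itertuples()}
    for s in sites:
        for p in periods:
            if (s, p.period_id) not in have:
                rows.append((s, p.period_id, 0))
                missing += 1
    if missing:
        log.info("filled %d missing (site, period) records with count 0", missing)
        df = pd.concat(
            [table.df[["site_id", "period_id", "count"]],
             pd.DataFrame(rows, columns=["site_id", "period_id", "count"])],
            ignore_index=True,
        )
        return OccurrenceTable(df, native_resolution=table.native_resolution)
    return table


def aggregate_to_periods(daily: OccurrenceTable,
                         periods: list[SamplingPeriod]) -> OccurrenceTable:
    """Sum daily counts into sampling periods (inclusive date membership).

    Days outside every period are dropped; the dropped total is logged so
    that period totals plus dropped counts conserve the daily total.
    """
    if daily.native_resolution != "daily":
        raise ValueError("aggregate_to_periods expects a daily-resolution table")
    _check_disjoint(periods)
    if "date" not in daily.df.columns:
        raise ValueError("daily table lacks a date column")
    acc: dict[tuple[str, str], int] = {}
    dropped = 0
    for r in daily.df.itertuples():
        p = period_containing(r.date, periods)
        if p is None:
            dropped += int(r.count)
            continue
        key = (r.site_id, p.period_id)
        acc[key] = acc.get(key, 0) + int(r.count)
    if dropped:
        log.info("aggregate_to_periods: dropped %d counts outside all periods",
                 dropped)
    df = pd.DataFrame(
        [(s, pid, c) for (s, pid), c in sorted(acc.items())],
        columns=["site_id", "period_id", "count"],
    )
    out = OccurrenceTable(df, native_resolution="interval")
    out.dropped_count = dropped  # bookkeeping for conservation checks
    return out


def filter_trajectories(ensemble, occ: OccurrenceTable,
                        periods: list[SamplingPeriod]):
    """Step-2 filter: keep trajectories whose (site, release period) saw moths.

    A trajectory is retained iff the period containing its initialization
    date has a positive count for its site; releases outside all periods
    are dropped (counted in the log).  Idempotent by construction.
    """
    _check_disjoint(periods)
    kept, outside, zero = [], 0, 0
    for t in ensemble.trajectories:
        p = period_containing(t.init_time.date(), periods)
        if p is None:
            outside += 1
            continue
        if occ.count_for(t.site_id, p.period_id) > 0:
            kept.append(t)
        else:
            zero += 1
    if outside or zero:
        log.info("filter_trajectories: dropped %d outside periods, %d zero-count",
                 outside, zero)
    return replace(ensemble, trajectories=kept)
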
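"""Read and write HYSPLIT trajectory endpoint ("tdump") files.

The endpoint layout is the plain-text format HYSPLIT writes after a
trajectory run: a header block (meteorological grid records, start-location
records, a diagnostic-variable record) followed by one data record per
trajectory per output hour, carrying the trajectory number, timestamp,
trajectory age, latitude, longitude and height.  Backward runs carry
negative ages.  Reading such files lets ensembles produced by a real
HYSPLIT installation flow through the same downstream analysis as the
built-in integrator; writing them makes synthetic ensembles consumable by
HYSPLIT-centric tooling.

Endpoint files carry no site identifiers, so trajectories read from disk
are labelled ``traj1``, ``traj2``, ... in file order.  Positions are
written with three decimals, heights and ages with one.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .trajectory import Trajectory, TrajectoryEnsemble

__all__ = ["read_tdump", "write_tdump"]

log = logging.getLogger(__name__)


class TdumpParseError(ValueError):
    """Malformed endpoint file; the message names the offending line."""


def write_tdump(ensemble: TrajectoryEnsemble, path) -> None:
    """Write an ensemble in HYSPLIT endpoint layout (one met grid, omega)."""
    trajs = ensemble.trajectories
    lines: list[str] = []
    lines.append(f"{1:6d}{1:6d}")
    ref = trajs[0].init_time if trajs else pd.Timestamp("2000-01-01")
    lines.append(
        f"    SYNT{ref.year % 100:6d}{ref.month:6d}{ref.day:6d}{ref.hour:6d}{0:6d}"
    )
    word = "FORWARD " if ensemble.direction == "forward" else "BACKWARD"
    lines.append(f"{len(trajs):6d} {word} OMEGA   ")
    for t in trajs:
        it = t.init_time
        lines.append(
            f"{it.year % 100:6d}{it.month:6d}{it.day:6d}{it.hour:6d}"
            f"{t.points[0, 1]:9.3f}{t.points[0, 2]:9.3f}{t.points[0, 3]:9.1f}"
        )
    lines.append(f"{1:6d} PRESSURE")
    sign = 1.0 if ensemble.direction == "forward" else -1.0
    for num, t in enumerate(trajs, start=1):
        for elapsed, la, lo, h in t.points:
            when = t.init_time + pd.Timedelta(hours=sign * elapsed)
            age = sign * elapsed
            lines.append(
                f"{num:6d}{1:6d}{when.year % 100:6d}{when.month:6d}{when.day:6d}"
                f"{when.hour:6d}{when.minute:6d}{0:6d}"
                f"{age:8.1f}{la:9.3f}{lo:9.3f}{h:9.1f}{0.0:9.1f}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _year4(yy: int) -> int:
    return 2000 + yy if yy < 70 else 1900 + yy


def read_tdump(path) -> TrajectoryEnsemble:
    """Parse an endpoint file into a :class:`TrajectoryEnsemble`.

    Direction is inferred from the sign of the trajectory ages (falling back
    to the header's FORWARD/BACKWARD word for files with only age-0
    records); points are ordered by |age|.
    """
    with open(path) as fh:
        raw = fh.read().splitlines()

    def fail(lineno, why):
        raise TdumpParseError(f"{path}: line {lineno + 1}: {why}")

    if not raw:
        raise TdumpParseError(f"{path}: empty file")
    try:
        ngrids = int(raw[0].split()[0])
    except (ValueError, IndexError):
        fail(0, "expected met-grid count")
    idx = 1 + ngrids
    if idx >= len(raw):
        fail(len(raw) - 1, "truncated header: missing trajectory-count record")
    parts = raw[idx].split()
    try:
        ntraj = int(parts[0])
    except (ValueError, IndexError):
        fail(idx, "expected trajectory count")
    header_word = parts[1].upper() if len(parts) > 1 else "FORWARD"
    start_rows = raw[idx + 1: idx + 1 + ntraj]
    if len(start_rows) < ntraj:
        fail(len(raw) - 1, "truncated header: missing start-location records")
    init_times: list[pd.Timestamp] = []
    for off, row in enumerate(start_rows):
        p = row.split()
        if len(p) < 7:
            fail(idx + 1 + off, "start-location record too short")
        yy, mo, da, hr = (int(x) for x in p[:4])
        init_times.append(pd.Timestamp(year=_year4(yy), month=mo, day=da, hour=hr))
    data_start = idx + 1 + ntraj + 1  # skip diagnostic-variable record

    recs: dict[int, list[tuple[float, float, float, float]]] = {
        i + 1: [] for i in range(ntraj)
    }
    any_age = []
    for lineno in range(data_start, len(raw)):
        row = raw[lineno]
        if not row.strip():
            continue
        p = row.split()
        if len(p) < 12:
            fail(lineno, f"data record has {len(p)} fields, expected >= 12")
        try:
            num = int(p[0])
            age = float(p[8])
            la, lo, h = float(p[9]), float(p[10]), float(p[11])
        except ValueError:
            fail(lineno, "unparseable numeric field in data record")
        if num not in recs:
            fail(lineno, f"trajectory number {num} not declared in header")
        recs[num].append((age, la, lo, h))
        any_age.append(age)

    if not any_age:
        log.warning("%s: endpoint file has an empty data section", path)
        direction = "forward" if header_word.startswith("F") else "backward"
        return TrajectoryEnsemble([], direction, provenance="tdump")

    nonzero = [a for a in any_age if a != 0.0]
    if nonzero:
        direction = "backward" if min(nonzero) < 0 else "forward"
    else:
        direction = "forward" if header_word.startswith("F") else "backward"

    trajs = []
    for num in sorted(recs):
        pts = sorted(recs[num], key=lambda r: abs(r[0]))
        arr = np.array([(abs(a), la, lo, h) for a, la, lo, h in pts])
        trajs.append(Trajectory(f"traj{num}", init_times[num - 1], direction, arr))
    return TrajectoryEnsemble(trajs, direction, provenance="tdump",
                              sites=tuple(t.site_id for t in trajs))
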
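"""Trajectory-frequency rasters: count trajectories per grid cell.

Step 3 of the pipeline overlays a filtered trajectory ensemble on a blank
regular raster (default 0.1 degree) and records, per cell, the number of
distinct trajectories with at least one recorded point in the cell
(``nhits``).  A trajectory contributes at most 1 to any cell regardless of
how many of its hourly points fall there, so nhits is a trajectory count,
not a point count.

Cell membership uses half-open intervals [edge, edge + resolution) on both
axes; grid edges are snapped outward to multiples of the resolution from a
global (-90, -180) anchor so cell boundaries are reproducible across runs.
On disk the raster is an ESRI ASCII grid (integer counts, geographic
WGS84 coordinates), which round-trips counts and geometry losslessly and
diffs cleanly in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RasterGrid", "make_grid", "rasterize_trajectories",
           "write_raster", "read_raster"]


@dataclass
class RasterGrid:
    """Regular count raster; row 0 is the southernmost row."""

    lat0: float          # lower-left corner latitude
    lon0: float          # lower-left corner longitude
    resolution: float    # cell size, degrees
    nhits: np.ndarray    # int array (n_rows, n_cols)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        self.nhits = np.asarray(self.nhits)
        if self.nhits.ndim != 2:
            raise ValueError("nhits must be 2-D")
        if (self.nhits < 0).any():
            raise ValueError("nhits must be non-negative")

    @property
    def n_rows(self) -> int:
        return self.nhits.shape[0]

    @property
    def n_cols(self) -> int:
        return self.nhits.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lats, lons) of cell centers, 1-D per axis."""
        r = self.resolution
        lats = self.lat0 + (np.arange(self.n_rows) + 0.5) * r
        lons = self.lon0 + (np.arange(self.n_cols) + 0.5) * r
        return lats, lons

    def cell_index(self, lat, lon) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Row/col of each point plus an in-extent mask (half-open cells)."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        row = np.floor((lat - self.lat0) / self.resolution).astype(int)
        col = np.floor((lon - self.lon0) / self.resolution).astype(int)
        ok = (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)
        return row, col, ok


def make_grid(lat_min: float, lat_max: float, lon_min: float, lon_max: float,
              resolution: float = 0.1, snap: bool = True) -> RasterGrid:
    """Blank raster covering the bounds, edges snapped to the global anchor."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if lat_min >= lat_max or lon_min >= lon_max:
        raise ValueError("degenerate extent")
    if snap:
        lat0 = -90.0 + np.floor((lat_min + 90.0) / resolution) * resolution
        lon0 = -180.0 + np.floor((lon_min + 180.0) / resolution) * resolution
    else:
        lat0, lon0 = lat_min, lon_min
    n_rows = int(np.ceil((lat_max - lat0) / resolution - 1e-9))
    n_cols = int(np.ceil((lon_max - lon0) / resolution - 1e-9))
    return RasterGrid(float(lat0), float(lon0), float(resolution),
                      np.zeros((max(n_rows, 1), max(n_cols, 1)), dtype=np.int32))


def _densified(points: np.ndarray, densify: int) -> tuple[np.ndarray, np.ndarray]:
    """Trajectory (lat, lon) sequence with `densify` extra points per segment."""
    lat, lon = points[:, 1], points[:, 2]
    if densify <= 0 or len(lat) < 2:
        return lat, lon
    f = np.linspace(0.0, 1.0, densify + 2)[:-1]  # include segment start only
    la = (lat[:-1, None] * (1 - f) + lat[1:, None] * f).ravel()
    lo = (lon[:-1, None] * (1 - f) + lon[1:, None] * f).ravel()
    return np.append(la, lat[-1]), np.append(lo, lon[-1])


def rasterize_trajectories(ensemble, grid: RasterGrid,
                           densify: int = 0) -> RasterGrid:
    """Increment each cell once per trajectory that touches it.

    ``densify`` linearly interpolates that many extra points per hourly
    segment for users who want near-segment "passing through" semantics;
    the default counts the recorded points only.  Points outside the extent
    are ignored.  The input grid's counts are not modified; a fresh raster
    with the same geometry is returned.
    """
    out = RasterGrid(grid.lat0, grid.lon0, grid.resolution,
                     np.zeros_like(grid.nhits, dtype=np.int32))
    for traj in ensemble:
        la, lo = _densified(np.asarray(traj.points, dtype=float), densify)
        row, col, ok = out.cell_index(la, lo)
        if not ok.any():
            continue
        flat = np.unique(row[ok] * out.n_cols + col[ok])
        out.nhits.ravel()[flat] += 1
    return out


_NODATA = -9999


def write_raster(grid: RasterGrid, path) -> None:
    """ESRI ASCII grid; rows written north-to-south as the format requires."""
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.lon0!r}\n")
        fh.write(f"yllcorner {grid.lat0!r}\n")
        fh.write(f"cellsize {grid.resolution!r}\n")
        fh.write(f"NODATA_value {_NODATA}\n")
        for row in grid.nhits[::-1]:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_raster(path) -> RasterGrid:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = val
        data = np.loadtxt(fh, dtype=np.int64)
    data = np.atleast_2d(data)
    grid = RasterGrid(float(hdr["yllcorner"]), float(hdr["xllcorner"]),
                      float(hdr["cellsize"]), data[::-1].astype(np.int32))
    if grid.n_cols != int(hdr["ncols"]) or grid.n_rows != int(hdr["nrows"]):
        raise ValueError(f"{path}: header/data shape mismatch")
    return grid
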
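"""Gridded horizontal wind fields on a regular latitude-longitude-time lattice.

A :class:`WindField` is the advection medium for the trajectory integrator:
eastward (``u``) and northward (``v``) wind components in m/s, indexed
``[time, lat, lon]``, with an optional vertical velocity ``w``.  Fields are
sampled by bilinear interpolation in space and linear interpolation in time;
queries outside the declared domain raise :class:`DomainExit` so the
integrator can truncate a parcel instead of extrapolating fictitious winds.

Reanalysis-style grids (e.g. 2.5-degree daily winds) are one admissible
instance; synthetic analytic fields are built by :mod:`mothtraj.synth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

__all__ = ["WindField", "DomainExit", "sample_wind"]

_EPOCH = np.datetime64("1970-01-01T00:00:00", "s")


class DomainExit(Exception):
    """A sample was requested outside the wind field's space-time domain."""


def _check_regular(axis: np.ndarray, name: str) -> None:
    if axis.ndim != 1 or axis.size < 1:
        raise ValueError(f"{name} must be a 1-D array with at least one entry")
    if axis.size > 1:
        d = np.diff(axis)
        if np.any(d <= 0):
            raise ValueError(f"{name} must be strictly ascending")
        if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
            raise ValueError(f"{name} must have constant spacing")


@dataclass
class WindField:
    """Regular lat/lon/time wind grid.

    Parameters
    ----------
    lats, lons : ascending, regularly spaced coordinates in degrees.
    times : ascending timestamps (anything ``pandas.to_datetime`` accepts).
    u, v : wind components in m/s, shape ``(ntime, nlat, nlon)``.
    w : optional vertical velocity in m/s, same shape.
    """

    lats: np.ndarray
    lons: np.ndarray
    times: np.ndarray
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray | None = None
    _times_h: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.times = pd.to_datetime(np.asarray(self.times)).to_numpy()
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.w is not None:
            self.w = np.asarray(self.w, dtype=float)
        _check_regular(self.lats, "lats")
        _check_regular(self.lons, "lons")
        if np.any(np.abs(self.lats) >= 90.0):
            raise ValueError("domains containing or touching the poles are not supported")
        expected = (self.times.size, self.lats.size, self.lons.size)
        for name, arr in (("u", self.u), ("v", self.v)) + (
            (("w", self.w),) if self.w is not None else ()
        ):
            if arr.shape != expected:
                raise ValueError(f"{name} has shape {arr.shape}, expected {expected}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values inside the domain")
        th = self.times.astype("datetime64[s]").astype("int64") / 3600.0
        if th.size > 1 and np.any(np.diff(th) <= 0):
            raise ValueError("times must be strictly ascending")
        object.__setattr__(self, "_times_h", th)

    # -- domain -----------------------------------------------------------
    @property
    def lat_bounds(self) -> tuple[float, float]:
        return float(self.lats[0]), float(self.lats[-1])

    @property
    def lon_bounds(self) -> tuple[float, float]:
        return float(self.lons[0]), float(self.lons[-1])

    def contains(self, lat: float, lon: float, t) -> bool:
        th = _to_hours(t)
        return bool(
            self.lats[0] <= lat <= self.lats[-1]
            and self.lons[0] <= lon <= self.lons[-1]
            and self._times_h[0] <= th <= self._times_h[-1]
        )

    # -- sampling ---------------------------------------------------------
    def sample_many(
        self, lat: np.ndarray, lon: np.ndarray, t_hours: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray | None, np.ndarray]:
        """Vectorized sampler.

        Returns ``(u, v, w_or_None, ok)`` where ``ok`` flags queries inside
        the domain; out-of-domain entries hold NaN instead of raising.
        """
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        t_hours = np.asarray(t_hours, dtype=float)
        ok = (
            (lat >= self.lats[0]) & (lat <= self.lats[-1])
            & (lon >= self.lons[0]) & (lon <= self.lons[-1])
            & (t_hours >= self._times_h[0]) & (t_hours <= self._times_h[-1])
        )

        def axis_index(vals, axis):
            if axis.size == 1:
                return np.zeros_like(vals, dtype=int), np.zeros_like(vals)
            step = axis[1] - axis[0]
            pos = (vals - axis[0]) / step
            i = np.clip(np.floor(pos).astype(int), 0, axis.size - 2)
            return i, np.clip(pos - i, 0.0, 1.0)

        safe = np.where(ok, lat, self.lats[0])
        i, fy = axis_index(safe, self.lats)
        safe = np.where(ok, lon, self.lons[0])
        j, fx = axis_index(safe, self.lons)
        safe = np.where(ok, t_hours, self._times_h[0])
        k, ft = axis_index(safe, self._times_h)
        k1 = np.minimum(k + 1, self._times_h.size - 1)

        def interp(arr):
            def plane(kk):
                a = arr[kk, i, j]
                b = arr[kk, i, np.minimum(j + 1, self.lons.size - 1)]
                c = arr[kk, np.minimum(i + 1, self.lats.size - 1), j]
                d = arr[kk, np.minimum(i + 1, self.lats.size - 1),
                        np.minimum(j + 1, self.lons.size - 1)]
                return (a * (1 - fx) * (1 - fy) + b * fx * (1 - fy)
                        + c * (1 - fx) * fy + d * fx * fy)
            out = plane(k) * (1 - ft) + plane(k1) * ft
            return np.where(ok, out, np.nan)

        uu, vv = interp(self.u), interp(self.v)
        ww = interp(self.w) if self.w is not None else None
        return uu, vv, ww, ok

    # -- I/O --------------------------------------------------------------
    def to_dataset(self) -> xr.Dataset:
        data = {
            "u": (("time", "lat", "lon"), self.u),
            "v": (("time", "lat", "lon"), self.v),
        }
        if self.w is not None:
            data["w"] = (("time", "lat", "lon"), self.w)
        return xr.Dataset(
            data, coords={"time": self.times, "lat": self.lats, "lon": self.lons}
        )

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "WindField":
        ds = xr.open_dataset(path, engine="scipy")
        w = ds["w"].values if "w" in ds else None
        return cls(ds["lat"].values, ds["lon"].values, ds["time"].values,
                   ds["u"].values, ds["v"].values, w)


def _to_hours(t) -> float:
    if isinstance(t, (int, float, np.floating)):
        return float(t)
    ts = pd.Timestamp(t)
    return ts.value / 3.6e12  # ns -> hours


def sample_wind(field: WindField, lat: float, lon: float, height: float, t):
    """Sample (u, v[, w]) at a point, bilinear in space and linear in time.

    ``height`` is accepted for interface symmetry; the horizontal wind is a
    single-level field, so it does not enter the interpolation.  Queries at
    grid nodes and stored times return the stored value exactly.

    Raises
    ------
    DomainExit
        when (lat, lon, t) falls outside the field's domain.
    """
    th = _to_hours(t)
    u, v, w, ok = field.sample_many(
        np.array([lat]), np.array([lon]), np.array([th])
    )
    if not ok[0]:
        raise DomainExit(
            f"query (lat={lat}, lon={lon}, t={t}) outside wind-field domain"
        )
    if w is None:
        return float(u[0]), float(v[0])
    return float(u[0]), float(v[0]), float(w[0])
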
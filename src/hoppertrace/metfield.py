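"""Gridded wind/temperature fields and space-time interpolation.

A :class:`MetField` holds eastward wind ``u``, northward wind ``v`` (m/s)
and air temperature ``T`` (degC) on a regular (time, lat, lon) grid at a
single nominal flight level.  All timestamps are naive local clock time
(Beijing Time, UTC+8); the pipeline performs no timezone arithmetic.

Longitudes are degrees east in [-180, 180), latitudes degrees north.
Sampling is bilinear in space and linear in time, so values at grid
nodes are reproduced exactly and interpolated values are bounded by the
eight surrounding knot values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MetField",
    "MetFieldFormatError",
    "OutOfDomainError",
    "load_metfield",
    "sample",
]

_VARS = ("u", "v", "T")


class MetFieldFormatError(ValueError):
    """Raised when an input file does not describe a valid met field."""


class OutOfDomainError(ValueError):
    """Raised when a query point lies outside the field's domain.

    Carries the offending coordinate in :attr:`coord`.
    """

    def __init__(self, message: str, coord=None):
        super().__init__(message)
        self.coord = coord


@dataclass
class MetField:
    """Wind and temperature on a regular lat/lon/time grid, one level.

    Parameters
    ----------
    lats, lons : 1-d arrays, strictly ascending decimal degrees.
    times : 1-d array of ``numpy.datetime64``, strictly ascending.
    u, v : eastward / northward wind (m/s), shape (time, lat, lon).
    T : air temperature (degC), same shape.
    level_m : nominal altitude of the fields in metres (metadata only).
    """

    lats: np.ndarray
    lons: np.ndarray
    times: np.ndarray
    u: np.ndarray
    v: np.ndarray
    T: np.ndarray
    level_m: float = 1000.0

    def __post_init__(self) -> None:
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        for name in _VARS:
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
        self._validate()
        # seconds since the first timestamp, for interpolation arithmetic
        self._tsec = (self.times - self.times[0]) / np.timedelta64(1, "s")

    def _validate(self) -> None:
        for name, ax in (("lat", self.lats), ("lon", self.lons)):
            if ax.ndim != 1 or len(ax) < 2 or not np.all(np.diff(ax) > 0):
                raise MetFieldFormatError(
                    f"axis {name!r} must be 1-d, length >= 2 and strictly ascending"
                )
        if self.times.ndim != 1 or len(self.times) < 2 or not np.all(
            np.diff(self.times) > np.timedelta64(0, "s")
        ):
            raise MetFieldFormatError(
                "axis 'time' must be 1-d, length >= 2 and strictly ascending"
            )
        shape = (len(self.times), len(self.lats), len(self.lons))
        for name in _VARS:
            arr = getattr(self, name)
            if arr.shape != shape:
                raise MetFieldFormatError(
                    f"variable {name!r} has shape {arr.shape}, expected {shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise MetFieldFormatError(f"variable {name!r} contains missing values")
        if not self.level_m > 0:
            raise MetFieldFormatError("level_m must be positive")

    # -- domain helpers -------------------------------------------------
    def contains(self, lat: float, lon: float, t) -> bool:
        t = np.datetime64(t, "ns")
        return (
            self.lats[0] <= lat <= self.lats[-1]
            and self.lons[0] <= lon <= self.lons[-1]
            and self.times[0] <= t <= self.times[-1]
        )

    def sample(self, lat: float, lon: float, t, var: str) -> float:
        return sample(self, lat, lon, t, var)


def _bracket(ax: np.ndarray, x: float, name: str, coord) -> tuple[int, float]:
    """Index i and fraction f with ax[i] <= x <= ax[i+1]."""
    if x < ax[0] or x > ax[-1]:
        raise OutOfDomainError(
            f"{name}={x} outside domain [{ax[0]}, {ax[-1]}]", coord=coord
        )
    i = int(np.searchsorted(ax, x, side="right") - 1)
    i = min(i, len(ax) - 2)
    f = (x - ax[i]) / (ax[i + 1] - ax[i])
    return i, f


def sample(field: MetField, lat: float, lon: float, t, var: str) -> float:
    """Trilinear sample of ``var`` in {'u','v','T'} at (lat, lon, t).

    Bilinear in lat/lon, linear in time.  Raises
    :class:`OutOfDomainError` when the query leaves the grid.
    """
    if var not in _VARS:
        raise ValueError(f"unknown variable {var!r}; expected one of {_VARS}")
    coord = (lat, lon, t)
    tq = (np.datetime64(t, "ns") - field.times[0]) / np.timedelta64(1, "s")
    kt, ft = _bracket(field._tsec, float(tq), "time", coord)
    ki, fi = _bracket(field.lats, lat, "lat", coord)
    kj, fj = _bracket(field.lons, lon, "lon", coord)
    cube = getattr(field, var)[kt : kt + 2, ki : ki + 2, kj : kj + 2]
    wt = np.array([1 - ft, ft])
    wi = np.array([1 - fi, fi])
    wj = np.array([1 - fj, fj])
    return float(np.einsum("tij,t,i,j->", cube, wt, wi, wj))


def _normalize_axes(lats, lons, times, u, v, T):
    """Sort axes ascending, reordering the data arrays to match."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    times = np.asarray(times, dtype="datetime64[ns]")
    out = {"u": np.asarray(u, float), "v": np.asarray(v, float), "T": np.asarray(T, float)}
    for axis, ax in ((0, times), (1, lats), (2, lons)):
        order = np.argsort(ax, kind="stable")
        if not np.array_equal(order, np.arange(len(ax))):
            if axis == 0:
                times = times[order]
            elif axis == 1:
                lats = lats[order]
            else:
                lons = lons[order]
            for k in out:
                out[k] = np.take(out[k], order, axis=axis)
    return lats, lons, times, out["u"], out["v"], out["T"]


def load_metfield(path, format: str = "netcdf", level_m: float = 1000.0) -> MetField:
    """Read a :class:`MetField` from disk.

    ``format='netcdf'``: CF-style file with coordinates lat/lon/time and
    variables u, v, T (aliases latitude/longitude accepted).  Units are
    expected in m/s and degC; a temperature variable with a kelvin units
    attribute is converted.

    ``format='csv_grid'``: long-format CSV with columns
    ``time, lat, lon, u, v, T`` covering a complete rectangular grid.
    """
    if format in ("netcdf", "nc"):
        return _load_netcdf(path, level_m)
    if format in ("csv_grid", "csv"):
        return _load_csv_grid(path, level_m)
    raise ValueError(f"unknown met format {format!r}")


def _load_netcdf(path, level_m: float) -> MetField:
    import xarray as xr

    with xr.open_dataset(path) as ds:
        ds = ds.load()
    ren = {}
    for cand, target in (("latitude", "lat"), ("longitude", "lon")):
        if cand in ds.coords:
            ren[cand] = target
    if ren:
        ds = ds.rename(ren)
    for coord in ("time", "lat", "lon"):
        if coord not in ds.coords:
            raise MetFieldFormatError(f"coordinate {coord!r} absent")
    for name in _VARS:
        if name not in ds:
            raise MetFieldFormatError(f"variable {name!r} absent")
    arrs = {}
    for name in _VARS:
        da = ds[name].transpose("time", "lat", "lon")
        vals = np.asarray(da.values, dtype=float)
        units = str(da.attrs.get("units", "")).lower()
        if name == "T" and units in ("k", "kelvin"):
            vals = vals - 273.15
        elif name in ("u", "v") and units not in ("", "m/s", "m s-1", "m s**-1"):
            raise MetFieldFormatError(f"variable {name!r} has unsupported units {units!r}")
        arrs[name] = vals
    axes = _normalize_axes(
        ds["lat"].values, ds["lon"].values, ds["time"].values, arrs["u"], arrs["v"], arrs["T"]
    )
    lvl = float(ds.attrs.get("level_m", level_m))
    return MetField(axes[0], axes[1], axes[2], axes[3], axes[4], axes[5], level_m=lvl)


def _load_csv_grid(path, level_m: float) -> MetField:
    df = pd.read_csv(path)
    required = {"time", "lat", "lon", "u", "v", "T"}
    missing = required - set(df.columns)
    if missing:
        raise MetFieldFormatError(
            f"variable {sorted(missing)[0]!r} absent from CSV grid"
        )
    df = df.copy()
    df["time"] = pd.to_datetime(df["time"])
    times = np.sort(df["time"].unique())
    lats = np.sort(df["lat"].unique())
    lons = np.sort(df["lon"].unique())
    shape = (len(times), len(lats), len(lons))
    if len(df) != int(np.prod(shape)):
        raise MetFieldFormatError(
            f"CSV grid incomplete: {len(df)} rows for a {shape} grid"
        )
    ti = {t: k for k, t in enumerate(times)}
    li = {x: k for k, x in enumerate(lats)}
    lj = {x: k for k, x in enumerate(lons)}
    arrs = {name: np.full(shape, np.nan) for name in _VARS}
    tk = df["time"].map(ti).to_numpy()
    ik = df["lat"].map(li).to_numpy()
    jk = df["lon"].map(lj).to_numpy()
    for name in _VARS:
        arrs[name][tk, ik, jk] = df[name].to_numpy(dtype=float)
    for name in _VARS:
        if np.isnan(arrs[name]).any():
            raise MetFieldFormatError(f"variable {name!r} has missing grid cells")
    return MetField(lats, lons, times, arrs["u"], arrs["v"], arrs["T"], level_m=level_m)


def write_csv_grid(field: MetField, path) -> None:
    """Write a field in the long-format CSV dialect read by ``load_metfield``."""
    tk, ik, jk = np.meshgrid(
        np.arange(len(field.times)),
        np.arange(len(field.lats)),
        np.arange(len(field.lons)),
        indexing="ij",
    )
    df = pd.DataFrame(
        {
            "time": field.times[tk.ravel()],
            "lat": field.lats[ik.ravel()],
            "lon": field.lons[jk.ravel()],
            "u": field.u.ravel(),
            "v": field.v.ravel(),
            "T": field.T.ravel(),
        }
    )
    df.to_csv(path, index=False)


def write_netcdf(field: MetField, path) -> None:
    """Write a field as CF-style NetCDF (classic format)."""
    import xarray as xr

    ds = xr.Dataset(
        {
            "u": (("time", "lat", "lon"), field.u, {"units": "m/s"}),
            "v": (("time", "lat", "lon"), field.v, {"units": "m/s"}),
            "T": (("time", "lat", "lon"), field.T, {"units": "degC"}),
        },
        coords={"time": field.times, "lat": field.lats, "lon": field.lons},
        attrs={"level_m": field.level_m},
    )
    ds.to_netcdf(path, engine="scipy")
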
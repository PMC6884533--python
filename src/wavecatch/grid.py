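"""Gridded-field data model, NetCDF I/O, and geometric reductions.

A gridded field is an :class:`xarray.DataArray` over ``(time[, depth], lat,
lon)`` with NaN marking missing cells.  ``validate_field`` enforces the
package invariants (monotonic coordinates, gap-free monthly time axis,
canonical longitude dialect); every reader funnels through it.

Longitudes are held internally in the [0, 360) dialect.  Readers accept
either dialect and convert; the declared input dialect is recorded in the
``lon_convention`` attribute so writers can restore it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from ._time import check_monthly
from .exceptions import (
    AlignmentError,
    AxisError,
    DegenerateRegionError,
    DomainError,
    FormatError,
)

EARTH_RADIUS_M = 6.371e6
#: Kilometres per degree of latitude (and of longitude at the equator).
KM_PER_DEG = 111.32

SPATIAL_DIMS = ("lat", "lon")


def normalize_lon(lon):
    """Map longitudes to the canonical [0, 360) dialect."""
    return np.mod(np.asarray(lon, dtype=float), 360.0)


@dataclass(frozen=True)
class BoxSpec:
    """A lat/lon rectangle (degrees; longitudes in either dialect)."""

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float

    def __post_init__(self):
        lo, hi = normalize_lon(self.lon_min), normalize_lon(self.lon_max)
        object.__setattr__(self, "lon_min", float(lo))
        object.__setattr__(self, "lon_max", float(hi))
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise DomainError(f"degenerate box: {self}")


@dataclass(frozen=True)
class TransectSpec:
    """A grid-line section: ``zonal`` (fixed lat) or ``meridional`` (fixed lon).

    ``span`` gives the (start, end) range along the free axis, in degrees.
    """

    axis: str
    fixed_coord: float
    span: tuple[float, float]

    def __post_init__(self):
        if self.axis not in ("zonal", "meridional"):
            raise DomainError(f"transect axis must be zonal or meridional, got {self.axis!r}")
        lo, hi = sorted(float(v) for v in self.span)
        if self.axis == "meridional":
            object.__setattr__(self, "fixed_coord", float(normalize_lon(self.fixed_coord)))
        else:
            lo, hi = float(normalize_lon(lo)), float(normalize_lon(hi))
            if lo > hi:
                raise DomainError(f"zonal span {self.span} crosses 0/360 seam")
        object.__setattr__(self, "span", (lo, hi))

    @property
    def free_dim(self) -> str:
        return "lon" if self.axis == "zonal" else "lat"

    @property
    def fixed_dim(self) -> str:
        return "lat" if self.axis == "zonal" else "lon"


def validate_field(da: xr.DataArray, check_time: bool = True) -> xr.DataArray:
    """Normalize and validate a gridded field; returns the canonical array."""
    for dim in SPATIAL_DIMS:
        if dim not in da.dims:
            raise FormatError(f"field {da.name!r} lacks coordinate variable {dim!r}")
    lat = da["lat"].values
    if np.any(np.abs(lat) > 90):
        raise AxisError("latitudes must lie within [-90, 90]")
    if lat.size > 1 and not np.all(np.diff(lat) > 0):
        if np.all(np.diff(lat) < 0):
            da = da.isel(lat=slice(None, None, -1))
        else:
            raise AxisError("lat axis must be strictly monotonic")
    lon = normalize_lon(da["lon"].values)
    was_pm180 = bool(np.any(np.asarray(da["lon"].values) < 0))
    da = da.assign_coords(lon=lon)
    if not np.all(np.diff(lon) > 0):
        da = da.sortby("lon")
        if not np.all(np.diff(da["lon"].values) > 0):
            raise AxisError("lon axis must be strictly monotonic after dialect normalization")
    if "depth" in da.dims and not np.all(np.diff(da["depth"].values) > 0):
        raise AxisError("depth axis must be strictly increasing (metres positive down)")
    if check_time and "time" in da.dims:
        check_monthly(da["time"].values)
    da = da.astype(float)
    da.attrs.setdefault("lon_convention", "pm180" if was_pm180 else "0-360")
    return da


def read_field(path, varname: str) -> xr.DataArray:
    """Read one variable from a CF-style NetCDF file as a validated field.

    Fill values declared in the file become NaN.  Longitudes are converted to
    the canonical [0, 360) dialect regardless of the file's convention.
    """
    ds = xr.open_dataset(path, engine="scipy", mask_and_scale=True, decode_times=True)
    if varname not in ds:
        raise FormatError(f"{path}: no variable {varname!r} (has {sorted(ds.data_vars)})")
    da = ds[varname]
    for dim in da.dims:
        if dim not in ds.coords:
            raise FormatError(f"{path}: missing coordinate variable {dim!r}")
    return validate_field(da.load())


def write_field(
    da: xr.DataArray, path, varname: str | None = None, lon_convention: str | None = None
) -> None:
    """Write a field to NetCDF (classic format).

    The longitude dialect of the original input is preserved unless
    ``lon_convention`` ("0-360" or "pm180") overrides it.
    """
    da = da.copy()
    if lon_convention is not None:
        if lon_convention not in ("0-360", "pm180"):
            raise ValueError(f"lon_convention must be '0-360' or 'pm180', got {lon_convention!r}")
        da.attrs["lon_convention"] = lon_convention
    if da.attrs.pop("lon_convention", "0-360") == "pm180":
        lon = da["lon"].values
        da = da.assign_coords(lon=np.where(lon >= 180.0, lon - 360.0, lon)).sortby("lon")
    name = varname or da.name or "field"
    da.to_dataset(name=name).to_netcdf(path, engine="scipy")


def _box_selector(field: xr.DataArray, box: BoxSpec) -> xr.DataArray:
    sub = field.sel(
        lon=slice(box.lon_min, box.lon_max), lat=slice(box.lat_min, box.lat_max)
    )
    if sub.sizes["lat"] == 0 or sub.sizes["lon"] == 0:
        raise DegenerateRegionError(f"box {box} contains no grid cells")
    return sub


def box_average(field: xr.DataArray, box: BoxSpec, weighted: bool = True) -> xr.DataArray:
    """Average over the unmasked cells of a lat/lon box, per remaining index.

    With ``weighted`` (the default) cells are weighted by cos(lat), the usual
    area weight on a regular grid; boxes spanning a narrow latitude band are
    insensitive to the choice.
    """
    sub = _box_selector(field, box)
    if weighted:
        w = np.cos(np.deg2rad(sub["lat"]))
        mean = sub.weighted(w).mean(dim=SPATIAL_DIMS, skipna=True)
    else:
        mean = sub.mean(dim=SPATIAL_DIMS, skipna=True)
    if "time" in mean.dims:
        bad = np.nonzero(~np.isfinite(mean.values))[0]
        if bad.size:
            raise DegenerateRegionError(
                f"box {box} has no unmasked cells at time index {int(bad[0])}"
            )
    mean.attrs.update(field.attrs)
    return mean


def extract_transect(field: xr.DataArray, spec: TransectSpec) -> xr.DataArray:
    """Section a field along a grid line (nearest-line selection, no interpolation)."""
    coord = field[spec.fixed_dim].values
    if coord.size > 1:
        step = float(np.median(np.diff(coord)))
    else:
        step = np.inf
    lo, hi = float(coord.min()), float(coord.max())
    if not (lo - step / 2 <= spec.fixed_coord <= hi + step / 2):
        raise DomainError(
            f"{spec.fixed_dim}={spec.fixed_coord} outside grid domain [{lo}, {hi}]"
        )
    line = field.sel({spec.fixed_dim: spec.fixed_coord}, method="nearest")
    section = line.sel({spec.free_dim: slice(*spec.span)})
    if section.sizes[spec.free_dim] == 0:
        raise DomainError(f"span {spec.span} contains no {spec.free_dim} grid lines")
    return section


def _require_same_grid(a: xr.DataArray, b: xr.DataArray) -> None:
    for dim in ("time", "lat", "lon"):
        if (dim in a.dims) != (dim in b.dims) or (
            dim in a.dims and not np.array_equal(a[dim].values, b[dim].values)
        ):
            raise AlignmentError(f"fields disagree on the {dim} axis")


def wind_stress_curl(taux: xr.DataArray, tauy: xr.DataArray) -> xr.DataArray:
    """Vertical curl of surface wind stress on a regular lat/lon grid (N m^-3).

    curl = (1 / (a cos phi)) d(tau_y)/d(lambda) - (1 / a) d(tau_x)/d(phi)

    i.e. d(tau_y)/dx - d(tau_x)/dy in the local metric, with centred
    differences in the interior and one-sided differences at the edges.
    (The spherical metric term tau_x tan(phi)/a is dropped, as is common for
    stress-curl maps; it is below 1e-8 N m^-3 at subtropical latitudes and
    makes the curl of a constant stress identically zero.)
    """
    _require_same_grid(taux, tauy)
    lam = np.deg2rad(taux["lon"].values)
    phi = np.deg2rad(taux["lat"].values)
    cosphi = np.cos(phi)

    lat_ax = taux.dims.index("lat")
    lon_ax = taux.dims.index("lon")
    dtauy_dlam = np.gradient(tauy.values, lam, axis=lon_ax)
    shape = [1] * taux.ndim
    shape[lat_ax] = cosphi.size
    dtaux_dphi = np.gradient(taux.values, phi, axis=lat_ax)

    curl = dtauy_dlam / (EARTH_RADIUS_M * cosphi.reshape(shape)) - dtaux_dphi / EARTH_RADIUS_M
    out = xr.DataArray(curl, coords=taux.coords, dims=taux.dims, name="wind_stress_curl")
    out.attrs["units"] = "N m-3"
    return out


def nearest_index(values: np.ndarray, target: float) -> int:
    """Index of the grid line nearest to ``target``."""
    return int(np.argmin(np.abs(np.asarray(values) - target)))


def monthly_axis(start: str, n_months: int) -> pd.DatetimeIndex:
    """A month-start datetime axis of length ``n_months`` beginning at ``start``."""
    return pd.date_range(start=start, periods=n_months, freq="MS")
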
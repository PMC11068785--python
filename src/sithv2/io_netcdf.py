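"""Packed-NetCDF product I/O and the two preprocessing contracts.

Product files store physical values as 16-bit integers with a
``scale_factor`` attribute.  Two packing conventions exist in the wild and
both are supported:

* ``inverse`` (the product default): the stored integer is
  round(value * scale_factor) and a reader recovers value =
  stored * scale_factor**-1 (attribute value 100 for two decimal places);
* ``cf`` : the CF convention, value = stored * scale_factor (attribute 0.01).

Every file carries a ``packing_convention`` attribute naming which one was
used, and the reader refuses to guess when attributes are missing.

Files are written as NetCDF3 classic via xarray's scipy backend, which
handles int16 payloads and plain attributes.
"""
from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np
import xarray as xr
from scipy.interpolate import CubicSpline, RegularGridInterpolator

__all__ = [
    "FILL_INT16",
    "pack",
    "unpack",
    "product_filename",
    "parse_product_filename",
    "write_product",
    "read_product",
    "regrid_bilinear",
    "gapfill_spline",
]

FILL_INT16 = np.int16(-32768)
_INT16_MIN, _INT16_MAX = -32767, 32767
_VARIABLES = ("ET", "Tr", "Es", "Ei", "SM1", "SM2", "SM3")
_INTERVALS = ("Daily", "Monthly", "Annual")
_FNAME_RE = re.compile(r"^SiTH\.v2\.(?P<var>[A-Za-z0-9]+)\."
                       r"(?P<interval>Daily|Monthly|Annual)\.(?P<year>\d{4})\.nc$")


def pack(values, scale_factor: float = 100.0) -> np.ndarray:
    """Pack physical values into int16 as round(value * scale_factor).

    NaNs become the fill value.  Overflow is a hard failure naming the
    offending cells — silent wrap-around would corrupt the product.
    """
    if scale_factor <= 0.0:
        raise ValueError("scale_factor must be positive")
    arr = np.asarray(values, dtype=float)
    scaled = np.round(arr * scale_factor)
    bad = np.isfinite(scaled) & ((scaled < _INT16_MIN) | (scaled > _INT16_MAX))
    if bad.any():
        idx = np.argwhere(bad)[:10]
        raise OverflowError(
            f"{int(bad.sum())} value(s) overflow int16 at scale_factor="
            f"{scale_factor}; first offending indices: {idx.tolist()}")
    out = np.where(np.isfinite(scaled), scaled, float(FILL_INT16))
    return out.astype(np.int16)


def unpack(stored, scale_factor: float = 100.0) -> np.ndarray:
    """Recover physical values as stored * scale_factor**-1; fills become NaN."""
    if scale_factor <= 0.0:
        raise ValueError("scale_factor must be positive")
    arr = np.asarray(stored)
    out = arr.astype(float) / scale_factor
    return np.where(arr == FILL_INT16, np.nan, out)


def product_filename(variable: str, interval: str, year: int) -> str:
    """Product filename: ``SiTH.v2.<VV>.<XXXX>.<YYYY>.nc``."""
    if variable not in _VARIABLES:
        raise ValueError(f"unknown variable {variable!r}; expected one of {_VARIABLES}")
    if interval not in _INTERVALS:
        raise ValueError(f"interval must be one of {_INTERVALS}")
    return f"SiTH.v2.{variable}.{interval}.{int(year):04d}.nc"


def parse_product_filename(name: str) -> tuple[str, str, int]:
    m = _FNAME_RE.match(Path(name).name)
    if m is None:
        raise ValueError(f"{name!r} does not match the product filename template")
    return m.group("var"), m.group("interval"), int(m.group("year"))


def write_product(cube: xr.DataArray, variable: str, interval: str, year: int,
                  out_dir, scale_factor: float = 100.0, cf: bool = False,
                  overwrite: bool = False, config_hash: str = "") -> Path:
    """Write one variable-year cube as a packed product file.

    ``cube`` must have (time, lat, lon) dims in physical units.  With
    ``cf=True`` the scale_factor attribute follows the CF convention
    (value = stored * attribute); otherwise the attribute is the write-time
    multiplier and the reader divides.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / product_filename(variable, interval, year)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")

    packed = pack(cube.values, scale_factor)
    da = xr.DataArray(packed, dims=cube.dims,
                      coords={k: v for k, v in cube.coords.items()
                              if set(v.dims) <= set(cube.dims)},
                      name=variable)
    da.attrs["_FillValue"] = FILL_INT16
    da.attrs["units"] = cube.attrs.get("units", "")
    if cf:
        da.attrs["scale_factor"] = 1.0 / scale_factor
        convention = "cf"
    else:
        da.attrs["scale_factor"] = scale_factor
        convention = "inverse"
    ds = da.to_dataset()
    ds.attrs.update({
        "variable": variable, "interval": interval, "year": int(year),
        "packing_convention": convention,
        "model_version": "SiTH.v2", "config_hash": config_hash,
    })
    ds.to_netcdf(path, engine="scipy")
    return path


def read_product(path) -> xr.DataArray:
    """Read a product file back to physical units.

    Refuses to guess when the scale_factor or packing-convention attributes
    are missing.
    """
    with xr.open_dataset(path, engine="scipy", mask_and_scale=False) as ds:
        ds.load()
    var, interval, year = parse_product_filename(path)
    if var not in ds:
        raise ValueError(f"variable {var!r} not found in {path}")
    da = ds[var]
    if "scale_factor" not in da.attrs:
        raise ValueError(f"{path} lacks a scale_factor attribute; refusing to guess")
    convention = ds.attrs.get("packing_convention")
    if convention not in ("cf", "inverse"):
        raise ValueError(f"{path} lacks a recognised packing_convention attribute")
    sf = float(da.attrs["scale_factor"])
    scale = 1.0 / sf if convention == "cf" else sf
    out = xr.DataArray(unpack(da.values, scale), dims=da.dims, coords=da.coords,
                       name=var, attrs={"units": da.attrs.get("units", "")})
    out.attrs.update({"interval": interval, "year": year})
    return out


def regrid_bilinear(field: xr.DataArray, target_lat, target_lon) -> xr.DataArray:
    """Bilinear interpolation of a rectilinear (lat, lon) field to a target grid.

    ``field`` may carry extra leading dimensions (e.g. time); the last two
    must be (lat, lon).  Target points outside the source hull are clamped to
    the edge (nearest policy) with a warning.
    """
    if field.dims[-2:] != ("lat", "lon"):
        raise ValueError("field dimensions must end with (lat, lon)")
    lat = field["lat"].values.astype(float)
    lon = field["lon"].values.astype(float)
    target_lat = np.asarray(target_lat, dtype=float)
    target_lon = np.asarray(target_lon, dtype=float)

    lat_asc = lat if lat[0] < lat[-1] else lat[::-1]
    vals = field.values if lat[0] < lat[-1] else field.values[..., ::-1, :]
    # lat/lon first, any extra dims trailing, so the interpolator vectorises
    vals = np.moveaxis(vals, (-2, -1), (0, 1))
    if (target_lat.min() < lat_asc[0] or target_lat.max() > lat_asc[-1]
            or target_lon.min() < lon[0] or target_lon.max() > lon[-1]):
        warnings.warn("target grid extends beyond the source hull; "
                      "edge values are used (nearest policy)", stacklevel=2)
    tlat = np.clip(target_lat, lat_asc[0], lat_asc[-1])
    tlon = np.clip(target_lon, lon[0], lon[-1])

    interp = RegularGridInterpolator((lat_asc, lon), vals, method="linear")
    glat, glon = np.meshgrid(tlat, tlon, indexing="ij")
    pts = np.column_stack([glat.ravel(), glon.ravel()])
    out = interp(pts).reshape(len(target_lat), len(target_lon), *vals.shape[2:])
    out = np.moveaxis(out, (0, 1), (-2, -1))
    dims = (*field.dims[:-2], "lat", "lon")
    coords = {k: v for k, v in field.coords.items()
              if k not in ("lat", "lon") and set(v.dims) <= set(field.dims[:-2])}
    coords.update({"lat": target_lat, "lon": target_lon})
    return xr.DataArray(out, dims=dims, coords=coords,
                        name=field.name, attrs=dict(field.attrs))


def gapfill_spline(obs_days, obs_values, out_days, non_negative: bool = False) -> np.ndarray:
    """Fill a sparse series to daily resolution with a cubic spline.

    Passes through the knots exactly.  With fewer than 4 knots a linear
    interpolation fallback is used (with a warning); non-negative variables
    can be floored at zero after interpolation.
    """
    obs_days = np.asarray(obs_days, dtype=float)
    obs_values = np.asarray(obs_values, dtype=float)
    out_days = np.asarray(out_days, dtype=float)
    if obs_days.size != obs_values.size or obs_days.size < 2:
        raise ValueError("need at least two paired observations")
    if not np.all(np.diff(obs_days) > 0):
        raise ValueError("observation days must be strictly increasing")
    if obs_days.size < 4:
        warnings.warn("fewer than 4 knots: falling back to linear interpolation",
                      stacklevel=2)
        out = np.interp(out_days, obs_days, obs_values)
    else:
        out = CubicSpline(obs_days, obs_values)(out_days)
    if non_negative:
        out = np.maximum(out, 0.0)
    return out
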
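"""Seed-controlled synthetic forcing with the statistical structure the model expects.

The generator emulates what drives the simulator in production — seasonal
sinusoids for temperature, shortwave radiation and LAI, Bernoulli wet-day
occurrence with exponential depths for precipitation, vegetation optical depth
co-varying with LAI — for three contrasting climate regimes, on a 365-day
no-leap calendar.  It makes no attempt to reproduce the spectra of real
reanalysis data; it exists so every other module is testable without
downloads.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .radiation import SIGMA_SB, W_M2_TO_MJ_DAY

__all__ = [
    "ClimateRegime",
    "REGIMES",
    "generate_forcing",
    "generate_grid_fixture",
    "cell_seed",
]

DAYS_PER_YEAR = 365
_PEAK_DOY = 196  # mid-July temperature/radiation/LAI peak

# cumulative day counts of a no-leap calendar, for month labels
_MONTH_ENDS = np.cumsum([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


@dataclass(frozen=True)
class ClimateRegime:
    """Parameters of one synthetic climate."""

    name: str
    mean_temp: float        # degC, annual mean
    temp_amplitude: float   # degC, half peak-to-trough
    wet_day_prob: float
    mean_wet_depth: float   # mm, mean of the exponential depth distribution
    lai_min: float          # m2 m-2
    lai_max: float
    rad_amplitude: float    # MJ m-2 d-1
    rad_mean: float = 14.0  # MJ m-2 d-1
    vod_max: float = 0.8
    albedo_black: float = 0.18
    peak_doy: int = _PEAK_DOY

    def __post_init__(self) -> None:
        if not 0.0 <= self.wet_day_prob <= 1.0:
            raise ValueError("wet-day probability must be in [0, 1]")
        if not 0.0 <= self.lai_min <= self.lai_max:
            raise ValueError("require 0 <= lai_min <= lai_max")


REGIMES: dict[str, ClimateRegime] = {
    "arid": ClimateRegime("arid", mean_temp=18.0, temp_amplitude=10.0,
                          wet_day_prob=0.05, mean_wet_depth=4.0,
                          lai_min=0.2, lai_max=0.8, rad_amplitude=7.0,
                          rad_mean=20.0, vod_max=0.3, albedo_black=0.30),
    "temperate": ClimateRegime("temperate", mean_temp=10.0, temp_amplitude=12.0,
                               wet_day_prob=0.30, mean_wet_depth=6.0,
                               lai_min=0.5, lai_max=4.5, rad_amplitude=8.0,
                               rad_mean=13.0, vod_max=0.8),
    "humid_tropical": ClimateRegime("humid_tropical", mean_temp=26.0,
                                    temp_amplitude=2.0, wet_day_prob=0.60,
                                    mean_wet_depth=9.0, lai_min=3.5,
                                    lai_max=5.5, rad_amplitude=3.0,
                                    rad_mean=16.0, vod_max=1.0,
                                    albedo_black=0.13),
}


def _seasonal(doy: np.ndarray, mean: float, amplitude: float, peak_doy: int) -> np.ndarray:
    return mean + amplitude * np.cos(2.0 * np.pi * (doy - peak_doy) / DAYS_PER_YEAR)


def generate_forcing(regime: ClimateRegime, n_years: int, seed: int) -> pd.DataFrame:
    """Generate ``n_years`` of daily forcing for one location.

    Returns a DataFrame with one row per day and columns year, doy, month plus
    every forcing field; bit-identical for identical (regime, n_years, seed).
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(seed)
    n = n_years * DAYS_PER_YEAR
    doy = np.tile(np.arange(1, DAYS_PER_YEAR + 1), n_years)
    year = np.repeat(np.arange(1, n_years + 1), DAYS_PER_YEAR)
    month = np.searchsorted(_MONTH_ENDS, doy, side="left") + 1

    ta = _seasonal(doy, regime.mean_temp, regime.temp_amplitude, regime.peak_doy)
    swd = np.maximum(
        _seasonal(doy, regime.rad_mean, regime.rad_amplitude, regime.peak_doy), 0.5)
    lai_span = regime.lai_max - regime.lai_min
    lai = regime.lai_min + lai_span * 0.5 * (
        1.0 + np.cos(2.0 * np.pi * (doy - regime.peak_doy) / DAYS_PER_YEAR))

    wet = rng.random(n) < regime.wet_day_prob
    depth = rng.exponential(regime.mean_wet_depth, n)
    precip = np.where(wet, depth, 0.0)

    # cloudier wet days: lower direct-beam fraction
    direct_frac = np.where(wet, 0.35, 0.70)
    swd_direct = direct_frac * swd

    tskin = ta + 273.15
    # grey-sky downward longwave from air temperature, slightly higher when cloudy
    eps_sky = np.where(wet, 0.88, 0.78)
    lwd = eps_sky * SIGMA_SB * (ta + 273.15) ** 4 * W_M2_TO_MJ_DAY

    lai_ref = max(regime.lai_max, 1e-9)
    vod = regime.vod_max * np.sqrt(lai / lai_ref) + 0.02 * rng.standard_normal(n)
    vod = np.maximum(vod, 0.0)

    return pd.DataFrame({
        "year": year, "month": month, "doy": doy,
        "ta": ta, "pa": np.full(n, 100.0), "precip": precip,
        "swd": swd, "swd_direct": swd_direct, "lwd": lwd, "tskin": tskin,
        "albedo_black": np.full(n, regime.albedo_black),
        "albedo_white": np.full(n, regime.albedo_black + 0.05),
        "emissivity": np.full(n, 0.97),
        "lai": lai, "vod": vod,
    })


def cell_seed(seed: int, iy: int, ix: int, nx: int) -> int:
    """Deterministic per-cell sub-seed, distinct across cells, < 2**31."""
    return int((seed * 1_000_003 + iy * nx + ix) % 2**31)


def generate_grid_fixture(regime_map, n_years: int, seed: int) -> xr.Dataset:
    """Gridded forcing cube for small test grids (<= 20x20 cells).

    ``regime_map`` is a 2-D nested sequence of :class:`ClimateRegime` (or
    regime names); each cell's series reproduces :func:`generate_forcing`
    under a sub-seed derived from (seed, cell index).
    """
    rows = [list(r) for r in regime_map]
    if not rows or not rows[0]:
        raise ValueError("regime_map must be non-empty")
    ny, nx = len(rows), len(rows[0])
    if ny > 20 or nx > 20:
        raise ValueError("grid fixtures are limited to 20x20 cells")

    n = n_years * DAYS_PER_YEAR
    fields = ["ta", "pa", "precip", "swd", "swd_direct", "lwd", "tskin",
              "albedo_black", "albedo_white", "emissivity", "lai", "vod"]
    data = {f: np.empty((n, ny, nx)) for f in fields}
    ref = None
    for iy in range(ny):
        for ix in range(nx):
            regime = rows[iy][ix]
            if isinstance(regime, str):
                regime = REGIMES[regime]
            df = generate_forcing(regime, n_years, cell_seed(seed, iy, ix, nx))
            if ref is None:
                ref = df
            for f in fields:
                data[f][:, iy, ix] = df[f].to_numpy()

    lat = 50.0 - 0.1 * np.arange(ny)
    lon = 0.05 + 0.1 * np.arange(nx)
    ds = xr.Dataset(
        {f: (("time", "lat", "lon"), data[f]) for f in fields},
        coords={
            "time": np.arange(n),
            "lat": ("lat", lat, {"units": "degrees_north"}),
            "lon": ("lon", lon, {"units": "degrees_east"}),
            "year": ("time", ref["year"].to_numpy()),
            "month": ("time", ref["month"].to_numpy()),
            "doy": ("time", ref["doy"].to_numpy()),
        },
    )
    units = {"ta": "degC", "pa": "kPa", "precip": "mm d-1",
             "swd": "MJ m-2 d-1", "swd_direct": "MJ m-2 d-1",
             "lwd": "MJ m-2 d-1", "tskin": "K", "albedo_black": "1",
             "albedo_white": "1", "emissivity": "1", "lai": "m2 m-2",
             "vod": "1"}
    for f in fields:
        ds[f].attrs["units"] = units[f]
    return ds
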
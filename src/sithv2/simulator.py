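"""Point and grid simulation drivers: spin-up, time-series execution, aggregation.

Grid cells are fully independent, so parallel execution (joblib worker pool)
is bit-identical to serial execution; results never depend on traversal
order.  Spin-up repeats one forcing year until the prognostic state reaches a
fixed point, reporting the final year-over-year change.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from joblib import Parallel, delayed

from . import radiation as rad
from .constraints import optimum_temperature
from .forcing import DAYS_PER_YEAR
from .params import SiteParams
from .water_cycle import DailyFluxes, ModelState, step

__all__ = [
    "RunConfig",
    "SpinUpResult",
    "derive_traits",
    "initial_state",
    "spin_up",
    "run_point",
    "run_grid",
    "aggregate",
    "save_state",
    "load_state",
]

_FLUX_COLS = ["et", "e_i", "e_s", "t_r", "runoff", "recharge",
              "sat_extraction", "balance_residual", "e_ps", "e_pc", "t_p",
              "f_wet", "f_sm", "f_t", "f_v", "rn"]
_OUTPUT_VARS = ["ET", "Tr", "Es", "Ei", "SM1", "SM2", "SM3"]


@dataclass
class RunConfig:
    spin_up_years: int = 100
    seed: int = 0
    output_variables: tuple = tuple(_OUTPUT_VARS)
    aggregation_intervals: tuple = ("monthly", "annual")
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.spin_up_years < 0:
            raise ValueError("spin_up_years must be >= 0")


@dataclass
class SpinUpResult:
    state: ModelState
    year_deltas: list = field(default_factory=list)  # max |dtheta| per cycle
    converged: bool = False


def derive_traits(forcing: pd.DataFrame, params: SiteParams) -> SiteParams:
    """Fill the climatology-derived traits t_opt and VOD_max.

    t_opt is the air temperature on the day maximising LAI*Rn*Ta over the
    record; VOD_max is the per-location record maximum of VOD.  Both are
    traits computed once and held fixed through a simulation.
    """
    rn = np.array([
        rad.radiation_budget(r.swd, r.swd_direct, r.lwd, r.tskin, r.emissivity,
                             r.albedo_black, r.albedo_white, r.lai,
                             k_rn=params.k_rn, g_fraction=params.g_fraction).rn
        for r in forcing.itertuples()
    ])
    t_opt = optimum_temperature(forcing["ta"].to_numpy(),
                                forcing["lai"].to_numpy(), rn)
    vod_max = float(forcing["vod"].max())
    return params.with_traits(t_opt=t_opt, vod_max=vod_max)


def initial_state(params: SiteParams) -> ModelState:
    """Default pre-spin-up state: field capacity everywhere, table at the profile bottom."""
    fc = params.soil.theta_fc
    return ModelState(theta=(fc, fc, fc), z_gw=params.layer_bottoms[-1])


def spin_up(forcing_year: pd.DataFrame, params: SiteParams, n_years: int,
            state0: ModelState | None = None, tol: float = 1e-4) -> SpinUpResult:
    """Repeat one forcing year ``n_years`` times to equilibrate the state.

    Reports the max absolute year-over-year soil-moisture change per cycle;
    warns (never fails) if the final change is still above ``tol``.
    """
    if len(forcing_year) != DAYS_PER_YEAR:
        raise ValueError("spin-up forcing must cover exactly one 365-day year")
    state = state0 if state0 is not None else initial_state(params)
    if n_years == 0:
        return SpinUpResult(state=state, year_deltas=[], converged=False)
    rows = list(forcing_year.itertuples())
    deltas = []
    for _ in range(n_years):
        prev = state.theta
        for row in rows:
            state, _ = step(state, row, params)
        deltas.append(max(abs(a - b) for a, b in zip(state.theta, prev)))
    converged = deltas[-1] < tol
    if not converged:
        warnings.warn(
            f"spin-up not converged after {n_years} cycles: "
            f"final max |dtheta| = {deltas[-1]:.3e}", stacklevel=2)
    return SpinUpResult(state=state, year_deltas=deltas, converged=converged)


def run_point(forcing: pd.DataFrame, params: SiteParams,
              state0: ModelState) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the daily model over a contiguous forcing series.

    Returns (fluxes, states): one row per day, aligned with the forcing
    index.  States are end-of-day.  Bit-reproducible for identical inputs;
    resuming from any saved end-of-day state reproduces the unsplit run.
    """
    doy = forcing["doy"].to_numpy()
    gaps = np.diff(doy)
    if len(doy) > 1 and not np.all((gaps == 1) | (gaps == 1 - DAYS_PER_YEAR)):
        raise ValueError("forcing series has date gaps; gap-fill before running")
    state = state0
    flux_rows = []
    state_rows = []
    for row in forcing.itertuples():
        state, fx = step(state, row, params)
        flux_rows.append(tuple(getattr(fx, c) for c in _FLUX_COLS)
                         + fx.t_r_layers)
        state_rows.append((*state.theta, state.z_gw))
    fluxes = pd.DataFrame(flux_rows,
                          columns=_FLUX_COLS + ["t_r_1", "t_r_2", "t_r_3"],
                          index=forcing.index)
    for c in ("year", "month", "doy"):
        fluxes[c] = forcing[c].to_numpy()
    states = pd.DataFrame(state_rows, columns=["sm1", "sm2", "sm3", "z_gw"],
                          index=forcing.index)
    for c in ("year", "month", "doy"):
        states[c] = forcing[c].to_numpy()
    return fluxes, states


def _run_cell(forcing_cell: pd.DataFrame, params: SiteParams,
              spin_up_years: int) -> np.ndarray:
    p = derive_traits(forcing_cell, params)
    first_year = forcing_cell.iloc[:DAYS_PER_YEAR]
    state = spin_up(first_year, p, spin_up_years).state
    fluxes, states = run_point(forcing_cell, p, state)
    return np.column_stack([
        fluxes["et"], fluxes["t_r"], fluxes["e_s"], fluxes["e_i"],
        states["sm1"], states["sm2"], states["sm3"],
    ])


def run_grid(forcing_cube: xr.Dataset, params_grid, config: RunConfig) -> xr.Dataset:
    """Run every unmasked cell of a forcing cube independently.

    ``params_grid`` is either one :class:`SiteParams` applied everywhere or a
    dict mapping (iy, ix) to per-cell parameters; cells with no parameters
    are masked and emit NaN with a logged reason.  Serial and parallel
    execution produce bit-identical cubes.
    """
    ny = forcing_cube.sizes["lat"]
    nx = forcing_cube.sizes["lon"]
    nt = forcing_cube.sizes["time"]

    def cell_params(iy, ix):
        if isinstance(params_grid, dict):
            return params_grid.get((iy, ix))
        return params_grid

    fields = ["ta", "pa", "precip", "swd", "swd_direct", "lwd", "tskin",
              "albedo_black", "albedo_white", "emissivity", "lai", "vod"]
    tasks = []
    for iy in range(ny):
        for ix in range(nx):
            p = cell_params(iy, ix)
            if p is None:
                warnings.warn(f"cell ({iy}, {ix}) has no parameters; masked",
                              stacklevel=2)
                continue
            df = pd.DataFrame({f: forcing_cube[f][:, iy, ix].to_numpy()
                               for f in fields})
            for c in ("year", "month", "doy"):
                df[c] = forcing_cube[c].to_numpy()
            tasks.append((iy, ix, df, p))

    results = Parallel(n_jobs=config.n_jobs)(
        delayed(_run_cell)(df, p, config.spin_up_years)
        for _, _, df, p in tasks)

    out = {v: np.full((nt, ny, nx), np.nan) for v in _OUTPUT_VARS}
    for (iy, ix, _, _), block in zip(tasks, results):
        for j, v in enumerate(_OUTPUT_VARS):
            out[v][:, iy, ix] = block[:, j]

    ds = xr.Dataset(
        {v: (("time", "lat", "lon"), out[v]) for v in _OUTPUT_VARS},
        coords={k: forcing_cube.coords[k]
                for k in ("time", "lat", "lon", "year", "month", "doy")},
    )
    for v in ("ET", "Tr", "Es", "Ei"):
        ds[v].attrs["units"] = "mm d-1"
    for v in ("SM1", "SM2", "SM3"):
        ds[v].attrs["units"] = "m3 m-3"
    return ds


_FLUX_KIND = "flux"
_STATE_KIND = "state"


def aggregate(daily, interval: str, kind: str):
    """Aggregate daily output to monthly or annual resolution.

    Fluxes (mm d-1) are summed to period totals (mm); states (m3 m-3) are
    averaged.  Incomplete trailing periods are dropped with a warning.
    Accepts a DataFrame with year/month columns or an xarray Dataset with
    year/month coordinates on the time dimension.
    """
    if interval not in ("monthly", "annual"):
        raise ValueError("interval must be 'monthly' or 'annual'")
    if kind not in (_FLUX_KIND, _STATE_KIND):
        raise ValueError("kind must be 'flux' or 'state'")
    keys = ["year", "month"] if interval == "monthly" else ["year"]

    if isinstance(daily, xr.Dataset | xr.DataArray):
        df = daily.to_dataframe().reset_index()
        value_cols = [v for v in (daily.data_vars if isinstance(daily, xr.Dataset)
                                  else [daily.name])]
        grouped = _aggregate_df(df, keys, value_cols, kind,
                                extra_keys=["lat", "lon"])
        return grouped
    value_cols = [c for c in daily.columns if c not in ("year", "month", "doy")]
    return _aggregate_df(daily, keys, value_cols, kind)


def _expected_period_length(keys, group_key) -> int:
    month_len = {1: 31, 2: 28, 3: 31, 4: 30, 5: 31, 6: 30,
                 7: 31, 8: 31, 9: 30, 10: 31, 11: 30, 12: 31}
    if "month" in keys:
        month = group_key[keys.index("month")] if isinstance(group_key, tuple) else group_key
        return month_len[int(month)]
    return DAYS_PER_YEAR


def _aggregate_df(df: pd.DataFrame, keys, value_cols, kind, extra_keys=()):
    extra_keys = [k for k in extra_keys if k in df.columns]
    gb_keys = list(extra_keys) + keys
    counts = df.groupby(gb_keys, sort=True).size()
    complete = []
    dropped = set()
    for gk, n in counts.items():
        period = gk[len(extra_keys):] if extra_keys else gk
        if n == _expected_period_length(keys, period):
            complete.append(gk)
        else:
            dropped.add(period)
    if dropped:
        warnings.warn(f"dropping incomplete periods: {sorted(dropped)}",
                      stacklevel=3)
    agg = df.groupby(gb_keys, sort=True)[value_cols]
    result = agg.sum() if kind == _FLUX_KIND else agg.mean()
    result = result.loc[complete] if complete else result.iloc[0:0]
    return result.reset_index()


def save_state(state: ModelState, path) -> None:
    Path(path).write_text(json.dumps(
        {"theta": list(state.theta), "z_gw": state.z_gw}))


def load_state(path) -> ModelState:
    d = json.loads(Path(path).read_text())
    return ModelState(theta=tuple(d["theta"]), z_gw=d["z_gw"])
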
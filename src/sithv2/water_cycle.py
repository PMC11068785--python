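"""One-day advance of the prognostic state with exact mass accounting.

The daily step composes: radiation budget -> Priestley-Taylor potentials ->
canopy interception -> stress functions -> root-zone allocation and
saturated/unsaturated split -> actual fluxes -> sequential bucket update of
the three soil layers -> groundwater-table update.

Ordering within a day (the scheme is explicit): all evaporative demands are
computed on beginning-of-day moisture; throughfall infiltrates and extraction
is applied before saturation-excess spill and conductivity-limited drainage.
Saturated-zone transpiration is charged to groundwater, not layer storage,
consistent with its exemption from the soil-moisture stress.

Mass closure is enforced every step: the residual
precip - (ET + runoff + recharge + dS_layers) + sat_extraction
must stay below 1e-6 mm (groundwater acts as an external store that receives
recharge and supplies saturated-zone transpiration; with no saturated uptake
this reduces to the plain bucket balance).
"""
from __future__ import annotations

from dataclasses import dataclass

from . import constraints as cs
from . import pet as pt
from . import radiation as rad
from . import root_zone as rz
from .params import SiteParams

__all__ = [
    "ModelState",
    "DailyFluxes",
    "interception",
    "actual_fluxes",
    "soil_water_update",
    "update_groundwater",
    "step",
]

BALANCE_TOL = 1e-6  # mm


@dataclass(frozen=True)
class ModelState:
    """Prognostic state: layer soil moisture (m3 m-3) and water-table depth (cm)."""

    theta: tuple[float, float, float]
    z_gw: float

    def __post_init__(self) -> None:
        if self.z_gw < 0.0:
            raise ValueError("z_gw must be >= 0 (depth below surface)")
        if any(t < 0.0 for t in self.theta):
            raise ValueError("soil moisture must be >= 0")


@dataclass(frozen=True)
class DailyFluxes:
    """Diagnostics of one day.  All water fluxes in mm d-1."""

    et: float
    e_i: float
    e_s: float
    t_r: float
    t_r_layers: tuple[float, float, float]
    runoff: float
    recharge: float
    sat_extraction: float
    balance_residual: float
    # potentials and constraint values
    e_ps: float = 0.0
    e_pc: float = 0.0
    t_p: float = 0.0
    f_wet: float = 0.0
    f_sm: float = 0.0
    f_t: float = 0.0
    f_v: float = 0.0
    f_smv: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rn: float = 0.0


def interception(precip: float, lai: float, e_pc: float,
                 chi: float = 0.7) -> tuple[float, float, float]:
    """Canopy interception evaporation and throughfall.

    The canopy store is S_c = P * LAI; interception evaporation is the
    energy-, storage- and supply-limited minimum
    E_i = min(chi*S_c, E_pc, P), so throughfall P - E_i is never negative.
    Returns (e_i, throughfall, f_wet) with f_wet the realised wet fraction
    E_i / E_pc.
    """
    if precip < 0.0 or lai < 0.0 or e_pc < 0.0:
        raise ValueError("interception inputs must be >= 0")
    s_c = precip * lai
    e_i = min(chi * s_c, e_pc, precip)
    f_wet = e_i / e_pc if e_pc > 0.0 else 0.0
    return e_i, precip - e_i, f_wet


def actual_fluxes(e_i: float, e_ps: float, stresses: cs.StressSet,
                  t_ps: tuple, t_pg: tuple) -> tuple[float, float, tuple, tuple]:
    """Scale potentials to actual fluxes with the multiplicative constraints.

    e_s = f_sm * e_ps.  Transpiration applies the per-layer soil-moisture
    constraint only to the unsaturated share; the saturated share bypasses it
    (roots in the saturated zone are never water-limited) but both shares see
    the plant-health constraints f_v and f_t.
    """
    e_s = stresses.f_sm * e_ps
    fv_ft = stresses.f_v * stresses.f_t
    t_uns = tuple(fv_ft * fi * ti for fi, ti in zip(stresses.f_smv, t_ps))
    t_sat = tuple(fv_ft * ti for ti in t_pg)
    t_r = sum(t_uns) + sum(t_sat)
    return e_s, t_r, t_uns, t_sat


def soil_water_update(theta: tuple, throughfall: float, e_s: float,
                      t_uns: tuple, params: SiteParams):
    """Sequential top-down bucket update of the three layers.

    Demanded evaporation/transpiration is clipped to the water extractable
    above the residual floor (never a silent clamp: the clipped fluxes are
    returned so the caller recomputes ET and the balance stays exact).
    Water above saturation spills instantly as runoff; water above field
    capacity drains to the layer below at a rate capped by the saturated
    hydraulic conductivity; layer-3 drainage becomes groundwater recharge.

    Returns (theta', runoff, recharge, e_s_actual, t_uns_actual).
    """
    d = params.layer_thick_mm
    soil = params.soil
    floor = params.theta_r
    w = [theta[i] * d[i] for i in range(3)]

    w[0] += throughfall

    # clip extraction to available storage above the residual floor
    t_act = [0.0, 0.0, 0.0]
    e_act = e_s
    demand0 = e_s + t_uns[0]
    avail0 = max(0.0, w[0] - floor * d[0])
    if demand0 > avail0:
        scale = avail0 / demand0 if demand0 > 0.0 else 0.0
        e_act = e_s * scale
        t_act[0] = t_uns[0] * scale
    else:
        t_act[0] = t_uns[0]
    w[0] -= e_act + t_act[0]
    for i in (1, 2):
        avail = max(0.0, w[i] - floor * d[i])
        t_act[i] = min(t_uns[i], avail)
        w[i] -= t_act[i]

    # saturation-excess spill and conductivity-limited drainage, top-down
    runoff = 0.0
    for i in range(3):
        excess = w[i] - soil.theta_s * d[i]
        if excess > 0.0:
            runoff += excess
            w[i] = soil.theta_s * d[i]
        drain = min(max(0.0, w[i] - soil.theta_fc * d[i]), soil.k_sat)
        w[i] -= drain
        if i < 2:
            w[i + 1] += drain
        else:
            recharge = drain

    theta_new = tuple(w[i] / d[i] for i in range(3))
    if any(t < 0.0 for t in theta_new):
        raise RuntimeError(f"negative soil storage {theta_new}: internal accounting bug")
    return theta_new, runoff, recharge, e_act, tuple(t_act)


def update_groundwater(z_gw: float, recharge: float, sat_extraction: float,
                       specific_yield: float = 0.05,
                       z_gw_max: float = 3000.0) -> float:
    """Move the water table by the net groundwater flux.

    A net gain of 1 mm raises the table by 1/(10*Sy) cm.  Depth is floored at
    the surface and capped at a configured maximum.
    """
    if not 0.0 < specific_yield < 1.0:
        raise ValueError("specific yield must be in (0, 1)")
    dz = (recharge - sat_extraction) / (10.0 * specific_yield)
    return min(max(z_gw - dz, 0.0), z_gw_max)


def step(state: ModelState, forcing, params: SiteParams) -> tuple[ModelState, DailyFluxes]:
    """Advance the model one day.

    ``forcing`` is any object with attributes ta, pa, precip, swd,
    swd_direct, lwd, tskin, albedo_black, albedo_white, emissivity, lai, vod.
    ``params`` must carry climatology traits t_opt and vod_max
    (see :func:`sithv2.simulator.derive_traits`).
    """
    if params.t_opt is None or params.vod_max is None:
        raise ValueError("params lack climatology traits t_opt/vod_max; "
                         "call sithv2.simulator.derive_traits first")
    soil = params.soil

    # energy supply
    budget = rad.radiation_budget(
        forcing.swd, forcing.swd_direct, forcing.lwd, forcing.tskin,
        forcing.emissivity, forcing.albedo_black, forcing.albedo_white,
        forcing.lai, k_rn=params.k_rn, g_fraction=params.g_fraction,
    )
    delta = pt.svp_slope(forcing.ta)
    lam = pt.latent_heat(forcing.ta)
    gamma = (pt.psychrometric_constant(forcing.pa)
             if params.pressure_adjusted_gamma else params.gamma)
    e_ps = pt.potential_soil_evaporation(budget.rns, budget.g, delta, gamma,
                                         lam, params.alpha)
    e_pc, _ = pt.potential_canopy_and_transpiration(budget.rnc, 0.0, delta,
                                                    gamma, lam, params.alpha)

    # interception and the residual transpiration potential
    e_i, throughfall, f_wet = interception(forcing.precip, forcing.lai, e_pc,
                                           params.chi)
    t_p = (1.0 - f_wet) * e_pc

    # stresses on beginning-of-day moisture
    theta = state.theta
    f_sm = cs.soil_evap_stress(theta[0], soil.theta_fc, soil.theta_wp)
    f_t = cs.temperature_stress(forcing.ta, params.t_opt)
    f_v = cs.vegetation_stress(forcing.vod, params.vod_max)
    crit = cs.critical_moisture(soil.theta_fc, soil.theta_wp, e_ps + e_pc,
                                params.h_c_eff, params.w, params.h_c_min)
    f_smv = tuple(cs.transpiration_stress(t, crit.theta_c, crit.theta_wp_h, crit.k)
                  for t in theta)
    stresses = cs.StressSet(f_wet=f_wet, f_sm=f_sm, f_smv=f_smv, f_t=f_t, f_v=f_v)

    # root-zone allocation and saturated split
    bounds = (0.0, *params.layer_bottoms)
    theta_bar = tuple(
        rz.layer_mean_wetness(theta[i], soil.theta_s, state.z_gw,
                              bounds[i], bounds[i + 1])
        for i in range(3)
    )
    t_p_i = rz.allocate_transpiration(t_p, params.root_r, theta_bar,
                                      soil.theta_s, soil.b)
    splits = [rz.split_saturation(t_p_i[i], state.z_gw, bounds[i], bounds[i + 1],
                                  theta[i], soil.theta_s) for i in range(3)]
    t_ps = tuple(s[0] for s in splits)
    t_pg = tuple(s[1] for s in splits)

    # actual fluxes and the bucket update (which may clip extraction)
    e_s_dem, _, t_uns_dem, t_sat = actual_fluxes(e_i, e_ps, stresses, t_ps, t_pg)
    theta_new, runoff, recharge, e_s, t_uns = soil_water_update(
        theta, throughfall, e_s_dem, t_uns_dem, params)
    sat_extraction = sum(t_sat)
    t_r_layers = tuple(u + s for u, s in zip(t_uns, t_sat))
    t_r = sum(t_r_layers)
    et = e_i + e_s + t_r

    z_gw_new = update_groundwater(state.z_gw, recharge, sat_extraction,
                                  params.specific_yield, params.z_gw_max)

    d = params.layer_thick_mm
    d_storage = sum((theta_new[i] - theta[i]) * d[i] for i in range(3))
    residual = (forcing.precip - (et + runoff + recharge + d_storage)
                + sat_extraction)
    if abs(residual) > BALANCE_TOL:
        raise RuntimeError(f"water balance violated: residual {residual:.3e} mm")

    fluxes = DailyFluxes(
        et=et, e_i=e_i, e_s=e_s, t_r=t_r, t_r_layers=t_r_layers,
        runoff=runoff, recharge=recharge, sat_extraction=sat_extraction,
        balance_residual=residual,
        e_ps=e_ps, e_pc=e_pc, t_p=t_p, f_wet=f_wet, f_sm=f_sm, f_t=f_t,
        f_v=f_v, f_smv=f_smv, rn=budget.rn,
    )
    return ModelState(theta=theta_new, z_gw=z_gw_new), fluxes
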
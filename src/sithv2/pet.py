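"""Priestley-Taylor potential evaporation for soil and canopy.

Potential soil evaporation and potential canopy evaporation take the
radiation-driven Priestley-Taylor form alpha * Delta/(Delta+gamma) * E/lambda,
applied separately to the soil-allocated and canopy-allocated net radiation.
Potential transpiration is the canopy potential left over after interception:
T_p = (1 - f_wet) * E_pc.

The slope of the saturation vapour-pressure curve uses the FAO-56 closed form
and the latent heat of vaporisation the Harrison linear form; both are the
community-standard parameterisations.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PotentialFluxes",
    "svp_slope",
    "latent_heat",
    "psychrometric_constant",
    "potential_soil_evaporation",
    "potential_canopy_and_transpiration",
]

_TA_RANGE = (-60.0, 60.0)


@dataclass(frozen=True)
class PotentialFluxes:
    e_ps: float   # potential soil evaporation, mm d-1
    e_pc: float   # potential canopy evaporation, mm d-1
    t_p: float    # potential transpiration, mm d-1
    delta: float  # kPa degC-1
    gamma: float  # kPa degC-1
    lambda_: float  # MJ kg-1
    alpha: float


def _check_ta(ta: float) -> None:
    if not _TA_RANGE[0] < ta < _TA_RANGE[1]:
        raise ValueError(f"air temperature {ta} degC outside physical range {_TA_RANGE}")


def svp_slope(ta: float) -> float:
    """Slope of the saturation vapour-pressure curve, kPa degC-1 (FAO-56)."""
    _check_ta(ta)
    es = 0.6108 * math.exp(17.27 * ta / (ta + 237.3))
    return 4098.0 * es / (ta + 237.3) ** 2


def latent_heat(ta: float) -> float:
    """Latent heat of vaporisation, MJ kg-1 (Harrison linear form)."""
    _check_ta(ta)
    return 2.501 - 0.002361 * ta


def psychrometric_constant(pa: float) -> float:
    """Pressure-adjusted psychrometric constant, kPa degC-1 (gamma = 0.000665*P)."""
    if pa <= 0.0:
        raise ValueError("air pressure must be positive (kPa)")
    return 0.000665 * pa


def _priestley_taylor(energy: float, delta: float, gamma: float,
                      lambda_: float, alpha: float) -> float:
    if lambda_ <= 0.0:
        raise ValueError("latent heat must be positive")
    # negative available energy clamps to zero: the model has no dew pathway
    if energy <= 0.0:
        return 0.0
    return alpha * (delta / (delta + gamma)) * energy / lambda_


def potential_soil_evaporation(rns: float, g: float, delta: float, gamma: float,
                               lambda_: float, alpha: float = 1.26) -> float:
    """Potential evaporation from bare soil, mm d-1, on energy rns - g."""
    return _priestley_taylor(rns - g, delta, gamma, lambda_, alpha)


def potential_canopy_and_transpiration(
    rnc: float, f_wet: float, delta: float, gamma: float,
    lambda_: float, alpha: float = 1.26,
) -> tuple[float, float]:
    """Potential canopy evaporation and its dry-canopy residual.

    Returns ``(e_pc, t_p)`` with ``t_p = (1 - f_wet) * e_pc``: the wet
    fraction of the canopy evaporates intercepted water, the rest transpires.
    """
    if not 0.0 <= f_wet <= 1.0:
        raise ValueError(f"f_wet={f_wet} outside [0, 1]")
    e_pc = _priestley_taylor(rnc, delta, gamma, lambda_, alpha)
    return e_pc, (1.0 - f_wet) * e_pc
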
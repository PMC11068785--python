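"""Multiplicative stress functions constraining potential fluxes.

Five dimensionless constraints in [0, 1] scale the potential fluxes down to
actual ones: canopy surface wetness (f_wet), a soil-moisture ramp for bare
soil evaporation (f_sm), a per-layer soil-moisture curve for transpiration
(f_smv), a temperature optimum curve (f_t) and a vegetation water-content
constraint from microwave vegetation optical depth (f_v).

The transpiration constraint pivots on a *dynamic* critical soil moisture
theta_c that moves between an adjusted wilting point and field capacity with
the day's evaporative demand and the canopy height.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StressSet",
    "CriticalMoisture",
    "canopy_wetness",
    "soil_evap_stress",
    "temperature_stress",
    "vegetation_stress",
    "optimum_temperature",
    "critical_moisture",
    "transpiration_stress",
]


@dataclass(frozen=True)
class StressSet:
    f_wet: float
    f_sm: float
    f_smv: tuple[float, float, float]
    f_t: float
    f_v: float


@dataclass(frozen=True)
class CriticalMoisture:
    theta_c: float
    theta_wp_h: float
    p: float
    k: float
    w: float
    h_c: float
    e_p: float


def canopy_wetness(s_c: float, e_pc: float, chi: float = 0.7) -> float:
    """Relative wetness of the canopy surface.

    f_wet = min(chi * S_c / E_pc, 1) where S_c is the canopy water store
    (mm).  With no evaporative demand the canopy is fully wet if any water is
    stored and dry otherwise.
    """
    if s_c < 0.0:
        raise ValueError("canopy storage must be >= 0")
    if not 0.0 < chi <= 1.0:
        raise ValueError("chi must be in (0, 1]")
    if e_pc <= 0.0:
        return 1.0 if s_c > 0.0 else 0.0
    return min(chi * s_c / e_pc, 1.0)


def soil_evap_stress(theta_1: float, theta_fc: float, theta_wp: float) -> float:
    """Linear ramp of surface-layer wetness between wilting point and field capacity."""
    if theta_fc <= theta_wp:
        raise ValueError("require theta_wp < theta_fc")
    if theta_1 <= theta_wp:
        return 0.0
    if theta_1 >= theta_fc:
        return 1.0
    return (theta_1 - theta_wp) / (theta_fc - theta_wp)


def temperature_stress(ta: float, t_opt: float) -> float:
    """Gaussian-style temperature constraint exp(-((Ta - Topt)/Topt)^2)."""
    if t_opt <= 0.0:
        raise ValueError(
            "optimum temperature must be > 0 degC; the constraint is "
            "undefined for non-positive t_opt"
        )
    return math.exp(-(((ta - t_opt) / t_opt) ** 2))


def vegetation_stress(vod: float, vod_max: float) -> float:
    """Plant water-content constraint f_v = sqrt(VOD / VOD_max), clamped at 1."""
    if vod_max <= 0.0:
        raise ValueError("vod_max must be positive")
    if vod < 0.0:
        raise ValueError("vod must be >= 0")
    return math.sqrt(min(vod / vod_max, 1.0))


def optimum_temperature(ta_series, lai_series, rn_series) -> float:
    """Optimum plant-growth temperature from the forcing climatology.

    Taken as the air temperature on the day maximising the product
    LAI * Rn * Ta — a trait derived once per location, then held fixed.
    """
    ta = np.asarray(ta_series, dtype=float)
    lai = np.asarray(lai_series, dtype=float)
    rn = np.asarray(rn_series, dtype=float)
    if not (ta.shape == lai.shape == rn.shape) or ta.size < 365:
        raise ValueError("series must be equal length covering at least one year")
    product = lai * rn * ta
    if np.nanmax(product) <= 0.0:
        raise ValueError(
            "LAI*Rn*Ta never positive: cannot derive an optimum temperature"
        )
    return float(ta[int(np.nanargmax(product))])


def critical_moisture(theta_fc: float, theta_wp: float, e_p: float,
                      h_c: float, w: float = 0.1,
                      h_c_min: float = 0.1) -> CriticalMoisture:
    """Dynamic critical soil moisture for the onset of transpiration water stress.

    k = sqrt(H_c); the wilting point is relaxed to theta_wp/k for tall
    canopies; the regulation parameter p = 1/(1+E_p) - w/(1+H_c) slides
    theta_c between the adjusted wilting point and field capacity, so high
    evaporative demand pushes the stress onset up towards field capacity.
    theta_c is clamped into [theta_wp_h, theta_fc]; theta_wp_h is capped just
    below theta_fc so the stress interval never degenerates for very short
    canopies.
    """
    if e_p < 0.0:
        raise ValueError("potential ET must be >= 0")
    if h_c < h_c_min:
        raise ValueError(f"canopy height {h_c} below floor {h_c_min} m")
    k = math.sqrt(h_c)
    theta_wp_h = min(theta_wp / k, 0.95 * theta_fc)
    p = 1.0 / (1.0 + e_p) - w / (1.0 + h_c)
    theta_c = (1.0 - p) * (theta_fc - theta_wp_h) + theta_wp_h
    theta_c = min(max(theta_c, theta_wp_h), theta_fc)
    return CriticalMoisture(theta_c=theta_c, theta_wp_h=theta_wp_h, p=p, k=k,
                            w=w, h_c=h_c, e_p=e_p)


def transpiration_stress(theta_i: float, theta_c: float, theta_wp_h: float,
                         k: float) -> float:
    """Per-layer soil-moisture constraint on transpiration.

    Zero below the adjusted wilting point, one above the critical moisture,
    and 1 - ((theta_c - theta)/(theta_c - theta_wp_h))**k between.
    """
    if theta_c <= theta_wp_h:
        raise ValueError("require theta_wp_h < theta_c")
    if theta_i <= theta_wp_h:
        return 0.0
    if theta_i >= theta_c:
        return 1.0
    return 1.0 - ((theta_c - theta_i) / (theta_c - theta_wp_h)) ** k
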
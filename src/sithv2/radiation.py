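"""Daily surface net-radiation assembly and canopy/soil partitioning.

All radiative fluxes are in MJ m-2 d-1.  Net radiation is built from the four
components (downward/reflected shortwave, downward/upward longwave) and split
between canopy and bare soil with a Beer-law extinction on leaf area index, so
that the soil share and the canopy share always close exactly to the total.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SIGMA_SB",
    "W_M2_TO_MJ_DAY",
    "RadiationBudget",
    "blue_sky_albedo",
    "upward_longwave",
    "net_radiation",
    "partition_radiation",
    "radiation_budget",
]

SIGMA_SB = 5.670374419e-8  # Stefan-Boltzmann constant, W m-2 K-4
W_M2_TO_MJ_DAY = 86400.0e-6  # 1 W m-2 sustained over a day = 0.0864 MJ m-2 d-1


@dataclass(frozen=True)
class RadiationBudget:
    albedo_blue: float
    lwu: float
    rn: float
    rns: float
    rnc: float
    g: float


def blue_sky_albedo(albedo_black: float, albedo_white: float, direct_fraction: float) -> float:
    """Blend black-sky (direct) and white-sky (diffuse) albedo.

    The actual ("blue-sky") albedo is linearly weighted by the direct fraction
    of downward shortwave radiation.
    """
    for name, v in (("albedo_black", albedo_black), ("albedo_white", albedo_white),
                    ("direct_fraction", direct_fraction)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return direct_fraction * albedo_black + (1.0 - direct_fraction) * albedo_white


def upward_longwave(emissivity: float, tskin: float, lwd: float) -> float:
    """Upward longwave radiation, MJ m-2 d-1.

    Grey-body emission at skin temperature plus the reflected part of the
    downward longwave flux: ``eps*sigma*T^4 + (1-eps)*lwd``.  ``lwd`` is
    already daily MJ m-2; the emission term is converted from W m-2.
    """
    if not 0.0 < emissivity <= 1.0:
        raise ValueError(f"emissivity={emissivity} outside (0, 1]")
    if tskin <= 0.0:
        raise ValueError("skin temperature must be in kelvin (> 0)")
    emission = SIGMA_SB * tskin**4 * W_M2_TO_MJ_DAY
    return emissivity * emission + (1.0 - emissivity) * lwd


def net_radiation(swd: float, albedo_blue: float, lwd: float, lwu: float) -> float:
    """Four-component balance: ``swd*(1 - albedo) + lwd - lwu``."""
    if swd < 0.0:
        raise ValueError("downward shortwave must be >= 0")
    return swd * (1.0 - albedo_blue) + lwd - lwu


def partition_radiation(rn: float, lai: float, k_rn: float = 0.6) -> tuple[float, float]:
    """Split net radiation between bare soil and canopy by Beer's law.

    rns = exp(-k_rn * LAI) * rn reaches the soil; the complement rnc = rn - rns
    is absorbed by the canopy.  Closure rns + rnc = rn holds by construction.
    """
    if lai < 0.0:
        raise ValueError("lai must be >= 0")
    rns = math.exp(-k_rn * lai) * rn
    return rns, rn - rns


def radiation_budget(
    swd: float,
    swd_direct: float,
    lwd: float,
    tskin: float,
    emissivity: float,
    albedo_black: float,
    albedo_white: float,
    lai: float,
    k_rn: float = 0.6,
    g_fraction: float = 0.0,
) -> RadiationBudget:
    """Assemble the full daily budget from raw forcing.

    The direct fraction weighting the albedo blend is the day's ratio
    swd_direct/swd (zero on sunless days).  Ground heat flux defaults to zero
    at the daily scale and may be taken as a fixed fraction of the soil share.
    """
    direct_fraction = swd_direct / swd if swd > 0.0 else 0.0
    ab = blue_sky_albedo(albedo_black, albedo_white, direct_fraction)
    lwu = upward_longwave(emissivity, tskin, lwd)
    rn = net_radiation(swd, ab, lwd, lwu)
    rns, rnc = partition_radiation(rn, lai, k_rn)
    return RadiationBudget(albedo_blue=ab, lwu=lwu, rn=rn, rns=rns, rnc=rnc,
                           g=g_fraction * rns)
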
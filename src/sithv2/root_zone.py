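"""Vertical root distribution and layer-wise transpiration allocation.

Root mass follows the linear dose-response profile: the cumulative fraction
above depth z is F(z) = 1 / (1 + (z / D50)^c) with c < 0, where D50 and D95
are the depths above which 50% and 95% of root mass lie.  Potential
transpiration is shared across the three soil layers in proportion to root
fraction times a wetness factor (theta_bar/theta_s)^b, and each layer's share
is further split between the unsaturated and saturated zone when the
groundwater table sits inside the layer.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "RootProfile",
    "root_shape",
    "cumulative_root_fraction",
    "root_fractions",
    "layer_mean_wetness",
    "allocate_transpiration",
    "split_saturation",
]

# solves 1/(1+x^c) = 0.95 at x = d95/d50 given F(d50) = 0.5:
# c = log10(1/0.95 - 1) / log10(d95/d50) = -1.27875... / log10(d95/d50)
_DOSE_RESPONSE_NUM = math.log10(1.0 / 0.95 - 1.0)


@dataclass(frozen=True)
class RootProfile:
    d50: float
    d95: float
    c: float
    r: tuple[float, float, float]


def root_shape(d50: float, d95: float) -> float:
    """Shape parameter of the dose-response profile; negative by construction."""
    if not 0.0 < d50 < d95:
        raise ValueError("require 0 < d50 < d95")
    return _DOSE_RESPONSE_NUM / math.log10(d95 / d50)


def cumulative_root_fraction(z: float, d50: float, c: float) -> float:
    """F(z) = 1/(1 + (z/d50)^c); F(0) = 0 for c < 0."""
    if z <= 0.0:
        return 0.0
    return 1.0 / (1.0 + (z / d50) ** c)


def root_fractions(layer_bottoms: Sequence[float], d50: float, d95: float) -> tuple:
    """Per-layer root fractions r_i = F(z_i) - F(z_{i-1}).

    The fraction below the deepest layer, 1 - F(z_bottom), is deliberately
    ignored: the allocation normalises over the three layers anyway.
    """
    c = root_shape(d50, d95)
    bounds = [0.0, *layer_bottoms]
    if any(b >= a for b, a in zip(bounds[1:], bounds[2:])):
        raise ValueError("layer bottoms must be strictly increasing")
    F = [cumulative_root_fraction(z, d50, c) for z in bounds]
    return tuple(F[i + 1] - F[i] for i in range(len(layer_bottoms)))


def layer_mean_wetness(theta_i: float, theta_s: float, z_gw: float,
                       z_top: float, z_bot: float) -> float:
    """Thickness-weighted layer wetness given the groundwater table.

    The unsaturated part of the layer holds theta_i, the saturated part below
    the table holds theta_s; continuous in z_gw at both layer boundaries.
    """
    if z_gw <= z_top:
        return theta_s
    if z_gw >= z_bot:
        return theta_i
    return ((z_gw - z_top) * theta_i + (z_bot - z_gw) * theta_s) / (z_bot - z_top)


def allocate_transpiration(t_p: float, r: Sequence[float],
                           theta_bar: Sequence[float], theta_s: float,
                           b: float) -> tuple:
    """Share potential transpiration across layers by root density and wetness.

    Weights are r_i * (theta_bar_i / theta_s)^b, normalised to sum to one.
    If every weight vanishes (all layers at zero wetness) the allocation is
    all-zero and transpiration is fully suppressed downstream.
    """
    if t_p < 0.0:
        raise ValueError("t_p must be >= 0")
    weights = [ri * (tb / theta_s) ** b if tb > 0.0 else 0.0
               for ri, tb in zip(r, theta_bar)]
    total = sum(weights)
    if total <= 0.0:
        return tuple(0.0 for _ in weights)
    return tuple(t_p * wi / total for wi in weights)


def split_saturation(t_p_i: float, z_gw: float, z_top: float, z_bot: float,
                     theta_i: float, theta_s: float) -> tuple[float, float]:
    """Split one layer's demand between unsaturated and saturated zones.

    Three cases on the water-table depth z_gw (positive downward, cm):
    table above the layer -> all demand is met from the saturated zone;
    table below the layer -> all from the unsaturated zone; table inside the
    layer -> weights proportional to the water held in each zone,
    (z_gw - z_top)*theta_i versus (z_bot - z_gw)*theta_s.  The two parts
    always sum exactly to the layer demand.
    """
    if z_gw < 0.0:
        raise ValueError("z_gw is a depth below the surface and must be >= 0")
    if z_top >= z_bot:
        raise ValueError("require z_top < z_bot")
    if t_p_i < 0.0:
        raise ValueError("t_p_i must be >= 0")
    if z_gw <= z_top:
        return 0.0, t_p_i
    if z_gw >= z_bot:
        return t_p_i, 0.0
    w_uns = (z_gw - z_top) * theta_i
    w_sat = (z_bot - z_gw) * theta_s
    den = w_uns + w_sat
    if den <= 0.0:  # only possible with theta_i = 0 at the lower boundary
        return 0.0, t_p_i
    t_ps = t_p_i * w_uns / den
    return t_ps, t_p_i - t_ps
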
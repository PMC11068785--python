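"""Static site parameters: soil hydraulics, vegetation traits, model constants.

Soil-texture and land-cover lookup tables ship as editable YAML files under
``sithv2/data``; they are repository-supplied defaults, not measured values.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import yaml

from .root_zone import root_fractions, root_shape

__all__ = [
    "SoilTexture",
    "Vegetation",
    "SiteParams",
    "load_soil_textures",
    "load_vegetation",
    "make_site_params",
]


@dataclass(frozen=True)
class SoilTexture:
    """Soil hydraulic properties for one texture class.

    theta_s, theta_fc, theta_wp in m3 m-3; b dimensionless wetness exponent;
    k_sat saturated hydraulic conductivity in mm d-1.
    """

    name: str
    theta_s: float
    theta_fc: float
    theta_wp: float
    b: float
    k_sat: float

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_wp < self.theta_fc < self.theta_s < 1.0:
            raise ValueError(
                f"soil texture {self.name!r} violates "
                "0 < theta_wp < theta_fc < theta_s < 1"
            )
        if self.k_sat <= 0.0:
            raise ValueError("k_sat must be positive")


@dataclass(frozen=True)
class Vegetation:
    """Vegetation traits: canopy height (m) and root-depth quantiles (cm)."""

    name: str
    h_c: float
    d50: float
    d95: float

    def __post_init__(self) -> None:
        if not 0.0 < self.d50 < self.d95:
            raise ValueError("require 0 < d50 < d95")


def _load_table(fname: str) -> dict:
    with resources.files("sithv2.data").joinpath(fname).open() as fh:
        return yaml.safe_load(fh)


def load_soil_textures() -> dict[str, SoilTexture]:
    return {
        name: SoilTexture(name=name, **row)
        for name, row in _load_table("soil_textures.yaml").items()
    }


def load_vegetation() -> dict[str, Vegetation]:
    return {
        name: Vegetation(name=name, **row)
        for name, row in _load_table("vegetation.yaml").items()
    }


@dataclass(frozen=True)
class SiteParams:
    """Everything static the daily step needs at one location.

    Derived quantities (root shape ``c``, per-layer root fractions ``r``,
    canopy-height sensitivity ``k``) are precomputed once at construction so
    the step itself is pure scalar arithmetic.  ``t_opt`` and ``vod_max`` are
    climatology-derived traits; :func:`sithv2.simulator.derive_traits` fills
    them before a run.
    """

    soil: SoilTexture
    veg: Vegetation
    layer_bottoms: tuple[float, float, float] = (5.0, 50.0, 300.0)  # cm
    # process constants
    alpha: float = 1.26          # Priestley-Taylor coefficient
    gamma: float = 0.066         # psychrometric constant, kPa degC-1
    k_rn: float = 0.6            # canopy radiation extinction coefficient
    chi: float = 0.7             # daytime fraction of interception
    w: float = 0.1               # canopy-height weight in critical moisture
    h_c_min: float = 0.1         # m, floor before k = sqrt(h_c)
    g_fraction: float = 0.0      # ground heat flux as a fraction of rns
    specific_yield: float = 0.05
    z_gw_max: float = 3000.0     # cm
    theta_r: float = 0.01        # m3 m-3, residual extraction floor
    pressure_adjusted_gamma: bool = False
    # climatology-derived traits (set via derive_traits / with_traits)
    t_opt: float | None = None
    vod_max: float | None = None
    # precomputed (filled in __post_init__)
    c: float = field(init=False)
    root_r: tuple[float, float, float] = field(init=False)
    k: float = field(init=False)
    theta_wp_h: float = field(init=False)
    layer_thick_mm: tuple[float, float, float] = field(init=False)

    def __post_init__(self) -> None:
        z1, z2, z3 = self.layer_bottoms
        if not 0.0 < z1 < z2 < z3:
            raise ValueError("layer bottoms must be strictly increasing and positive")
        c = root_shape(self.veg.d50, self.veg.d95)
        r = root_fractions(self.layer_bottoms, self.veg.d50, self.veg.d95)
        h_c = max(self.veg.h_c, self.h_c_min)
        k = math.sqrt(h_c)
        # keep the stress interval [theta_wp_h, theta_c] non-degenerate for
        # very short canopies, where theta_wp / sqrt(h_c) can exceed theta_fc
        theta_wp_h = min(self.soil.theta_wp / k, 0.95 * self.soil.theta_fc)
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "root_r", r)
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "theta_wp_h", theta_wp_h)
        object.__setattr__(
            self, "layer_thick_mm", (z1 * 10.0, (z2 - z1) * 10.0, (z3 - z2) * 10.0)
        )

    @property
    def h_c_eff(self) -> float:
        return max(self.veg.h_c, self.h_c_min)

    def with_traits(self, t_opt: float, vod_max: float) -> "SiteParams":
        return replace(self, t_opt=t_opt, vod_max=vod_max)


def make_site_params(texture: str = "loam", landcover: str = "grassland", **kw) -> SiteParams:
    """Build :class:`SiteParams` from the shipped lookup tables."""
    soils = load_soil_textures()
    vegs = load_vegetation()
    if texture not in soils:
        raise KeyError(f"unknown soil texture {texture!r}; have {sorted(soils)}")
    if landcover not in vegs:
        raise KeyError(f"unknown land cover {landcover!r}; have {sorted(vegs)}")
    return SiteParams(soil=soils[texture], veg=vegs[landcover], **kw)
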
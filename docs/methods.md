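# Methods

## Model structure

The simulator advances a prognostic state — volumetric soil moisture in three
layers (default bottoms at 5, 50 and 300 cm) and the groundwater-table depth
z_gw — one day at a time.  Each step is an explicit scheme evaluated on the
beginning-of-day state:

1. **Radiation budget.**  Blue-sky albedo is the direct-fraction-weighted
   blend of black-sky and white-sky albedo, with the weight taken as the
   day's ratio of direct to total downward shortwave (zero on sunless days).
   Upward longwave is grey-body emission at the skin temperature plus the
   reflected fraction of downward longwave.  Net radiation
   `Rn = SWD(1−α_blue) + LWD − LWU` is split between bare soil
   (`Rns = e^(−k_Rn·LAI)·Rn`, k_Rn = 0.6) and canopy (complement), closing
   exactly.  Ground heat flux G defaults to zero at the daily scale; a
   fraction-of-Rns option exists behind `g_fraction`.
2. **Potentials.**  Priestley–Taylor with α = 1.26 on `Rns − G` (soil) and
   `Rnc` (canopy).  The vapour-pressure-curve slope Δ uses the FAO-56 closed
   form and the latent heat λ the Harrison linear form — both community
   standards, since no specific parameterisation is mandated by the scheme
   itself.  γ is fixed at 0.066 kPa °C⁻¹ by default; a pressure-adjusted
   γ = 0.000665·P is available behind `pressure_adjusted_gamma`.  Negative
   available energy clamps the potentials at zero: the model has no dew or
   condensation pathway.
3. **Interception.**  The canopy store is S_c = P·LAI and the wet fraction
   f_wet = min(χ·S_c/E_pc, 1) with χ = 0.7, evaluated against E_pc.  The
   defining relation for f_wet divides by potential transpiration, which is
   itself defined through f_wet; evaluating against E_pc removes that
   implicit equation and yields the closed form E_i = min(χ·S_c, E_pc).
   Because χ·S_c = χ·P·LAI can exceed the rain itself for LAI > 1/χ, E_i is
   additionally capped at P so throughfall is never negative.
4. **Constraints.**  f_sm is a linear ramp of surface-layer moisture between
   wilting point and field capacity.  f_t = exp(−((Ta−Topt)/Topt)²);
   T_opt is a per-location trait, the air temperature on the climatology day
   maximising LAI·Rn·Ta, computed once before a run and held fixed.  It is
   undefined for T_opt ≤ 0 °C and rejected as a configuration error rather
   than silently patched.  f_v = √(VOD/VOD_max) with VOD_max the full-record
   per-location maximum (values above it, possible across years, clamp f_v
   at 1).  The critical moisture θ_c = (1−p)(θ_fc−θ_wp^h) + θ_wp^h with
   p = 1/(1+E_p) − w/(1+H_c), w = 0.1, k = √H_c and θ_wp^h = θ_wp/k.  E_p is
   the day's E_ps + E_pc in mm d⁻¹, used dimensionlessly inside 1/(1+E_p).
   H_c is floored at 0.1 m (the expression is singular at H_c = 0) and
   θ_wp^h is capped at 0.95·θ_fc so the stress interval never degenerates
   for very short canopies.  θ_c is clamped into [θ_wp^h, θ_fc].
5. **Root zone.**  Root fractions per layer are differences of the
   cumulative dose-response profile F(z) = 1/(1+(z/D50)^c) with
   c = log₁₀(1/0.95−1)/log₁₀(D95/D50) < 0; the root mass below the deepest
   layer is ignored rather than renormalised, because the allocation weights
   normalise over the three layers anyway.  Layer demand weights are
   r_i·(θ̄_i/θ_s)^b where θ̄_i is the thickness-weighted mean of θ_i over the
   unsaturated part and θ_s over the saturated part of the layer — the only
   reading consistent with the saturated/unsaturated split weights.  If all
   weights vanish, allocation is zero and transpiration is suppressed.  Each
   layer's demand splits between zones with weights proportional to
   (z_gw−z_top)·θ_i and (z_bot−z_gw)·θ_s; the split is continuous in z_gw at
   both layer boundaries.
6. **Actual fluxes.**  E_s = f_sm·E_ps; transpiration applies f_smv only to
   the unsaturated share, and f_v·f_t to both shares.  Saturated-zone uptake
   is charged to groundwater, not layer storage, consistent with its
   exemption from soil-moisture stress.
7. **Bucket update.**  Depths positive downward in cm; storages in mm.
   Throughfall infiltrates into layer 1; demanded extraction is clipped to
   the water available above a residual floor (θ_r = 0.01 m³ m⁻³), with the
   clipped fluxes returned so ET is recomputed and the balance stays exact —
   never a silent clamp.  Water above θ_s spills instantly as
   saturation-excess runoff; water above θ_fc drains to the next layer at a
   rate capped by k_sat; layer-3 drainage is groundwater recharge.  The
   exact infiltration/runoff formulation of the original model lives in
   antecedent model descriptions and is not restated here; this bucket
   scheme is a documented stand-in and the module most likely to differ from
   the original code.
8. **Groundwater.**  z_gw moves by (recharge − saturated uptake)/(10·S_y)
   cm with specific yield S_y = 0.05, floored at the surface and capped at
   30 m.  Groundwater is treated as an external store: the per-step residual
   `P − (ET + runoff + recharge + Δstorage_layers) + saturated_uptake` must
   be ≤ 10⁻⁶ mm or the step hard-fails; with no saturated uptake this is the
   plain bucket balance.

## Simulation protocol

Spin-up repeats the first available forcing year (configurable to any
single-year climatology) from an initial state of field capacity in all
layers and the table at the profile bottom; the default is 100 cycles, after
which the year-over-year state change is reported and a warning (not a
failure) is raised if it exceeds 10⁻⁴ m³ m⁻³.  Grid cells are fully
independent; the joblib worker pool yields bit-identical results to serial
execution.  Daily fluxes aggregate by summation to monthly/annual totals and
states by averaging, on a 365-day no-leap calendar (leap-day branching is
removed from the whole synthetic path; a real-data pipeline may carry native
calendars up to the I/O boundary).  Incomplete trailing periods are dropped
with a warning.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| α | 1.26 | – | Priestley–Taylor coefficient |
| γ | 0.066 | kPa °C⁻¹ | psychrometric constant |
| k_Rn | 0.6 | – | canopy radiation extinction |
| χ | 0.7 | – | daytime fraction of interception |
| w | 0.1 | – | canopy-height weight in θ_c |
| θ_r | 0.01 | m³ m⁻³ | residual extraction floor |
| S_y | 0.05 | – | specific yield of the aquifer |
| z_gw max | 3000 | cm | water-table depth cap |
| layer bottoms | 5, 50, 300 | cm | soil discretisation (first fixed, rest configurable) |

Soil hydraulics per texture class (θ_s, θ_fc, θ_wp, b, k_sat) and vegetation
traits per land-cover class (H_c, D50, D95) ship as editable YAML tables in
`sithv2/data/`.  They are repository-supplied defaults following standard
published syntheses (Clapp–Hornberger-style soils, ecosystem root-profile
compilations), not values fixed by the model formulation.

## Synthetic forcing

The generator emulates the statistical structure of the production drivers:
annual sinusoids for temperature, shortwave radiation and LAI (peak day 196);
Bernoulli wet-day occurrence with exponentially distributed depths;
cloudier (lower direct-fraction, higher sky-emissivity) wet days; VOD as
`VOD_max·√(LAI/LAI_max)` plus small Gaussian noise floored at zero, which
guarantees f_v spans (0, 1] over a year.  Three regimes (arid, temperate,
humid-tropical) cover contrasting rainfall frequency, LAI range and
radiation seasonality.  What it does **not** emulate: multi-day weather
persistence, sub-daily structure, interannual climate modes, realistic
longwave/shortwave covariance, topographic or advective effects.  Passing
tests therefore demonstrate internal consistency, conservation and the
model's limit behaviours under realistic magnitudes — not skill against real
observations.

## Numerical choices

Everything in the step is scalar double-precision arithmetic; there is no
iteration, so results are bit-reproducible from (inputs, parameters) and a
run can be checkpointed at any day boundary.  Grid sub-seeds derive
deterministically from (seed, cell index).  Radiation closure
R_ns + R_nc = R_n holds to machine rounding (≤ a few ulp).  Product files
pack physical values as round(value·100) into int16 (quantisation error
≤ 0.005); the scale_factor attribute is written in the product convention
(reader divides) with a `packing_convention` attribute naming it, and a CF
mode (`cf=True`, reader multiplies) is available because the two conventions
are mutual inverses and silently mixing them corrupts data — the reader
refuses files that do not declare a convention.  Bilinear regridding uses
nodal-exact linear interpolation on cell centers with a nearest-edge policy
outside the source hull; temporal gap-fill uses a natural cubic spline
through the knots (linear fallback below 4 knots) with an optional
non-negativity floor.

## Evaluation tools

Pearson R, RMSE, Nash–Sutcliffe efficiency and the OLS fit of simulation on
observation, with pairwise deletion of missing values and the retained count
reported; NSE is flagged undefined (not zero) for constant observations.
Basin-scale reference ET from the water balance, ET_wb = P − Q − ΔS.  Annual
trends report an OLS slope by default (Sen's slope optional, since a linear
trend value paired with a Mann–Kendall test does not by itself pin the
estimator) with a two-sided Mann–Kendall p-value using tie-corrected
variance and continuity correction.

## Known limitations

No soil freeze–thaw physics, no lateral flow between cells, no irrigation,
no hydraulic redistribution or dynamic root growth, no stomatal-conductance
or vapour-pressure-deficit stress formulation, and no dew deposition.  The
infiltration/runoff bucket is a stand-in (above).  Cold locations where the
derived T_opt would be ≤ 0 °C are rejected rather than approximated.
Problem sizes in the test suite (39-year single-point runs across
3 regimes × 3 textures × 3 vegetation classes, 5×5 grids over 2 years,
100-cycle spin-ups) were chosen to exercise every seasonal branch and the
fixed-point behaviour while keeping the suite quick to run.
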
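# Repository-supplied vegetation/root parameters by land-cover class.
# h_c: canopy height (m); d50/d95: depths above which 50% / 95% of root
# mass lies (cm).  Editable defaults following published ecosystem syntheses.
grassland:
  h_c: 0.6
  d50: 15.0
  d95: 80.0
shrubland:
  h_c: 2.0
  d50: 25.0
  d95: 150.0
cropland:
  h_c: 1.2
  d50: 20.0
  d95: 90.0
deciduous_forest:
  h_c: 18.0
  d50: 20.0
  d95: 120.0
evergreen_forest:
  h_c: 25.0
  d50: 25.0
  d95: 180.0
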
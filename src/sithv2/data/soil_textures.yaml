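# Repository-supplied soil hydraulic lookup by texture class.
# Values follow standard Clapp-Hornberger-style syntheses; they are editable
# defaults, not measurements.  Units: theta_* m3 m-3, k_sat mm d-1, b dimensionless.
sand:
  theta_s: 0.395
  theta_fc: 0.135
  theta_wp: 0.045
  b: 4.05
  k_sat: 1500.0
loam:
  theta_s: 0.451
  theta_fc: 0.270
  theta_wp: 0.110
  b: 5.39
  k_sat: 250.0
clay:
  theta_s: 0.482
  theta_fc: 0.367
  theta_wp: 0.208
  b: 11.40
  k_sat: 30.0
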
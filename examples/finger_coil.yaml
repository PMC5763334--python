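# Reference finger-coil design: 34 mm winding diameter, 3 turns, 56 mm
# winding length, optimized segment angles alpha = beta = 80 degrees.
coil:
  winding_diameter_mm: 34.0
  n_turns: 3
  winding_length_mm: 56.0
  alpha_deg: 80.0
  beta_deg: 80.0
  current_A: 1.0
  segments_per_turn: 360
roi:
  radius_mm: 14.0        # inner housing bore radius
  z_half_extent_mm: 28.0 # winding half-length
  grid_spacing_mm: 1.0
solver:
  b1_proxy: magnitude    # magnitude | axial | transverse
profile:
  n_samples: 57          # odd, so z = 0 is sampled exactly
optimize:
  selection_rule: min-cv-on-pareto
output:
  formats: [csv]
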
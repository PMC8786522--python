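# Tepid-sponging fever scenario: forehead patch under a 7 C wet cloth.
# Geometry: 8 mm x 8 mm x 8 mm patch at 2 mm spacing (the 27-interior-unknown
# lattice); layers scalp 4.5 mm / skull 3.5 mm / CSF 2 mm.
# The published parameter table prints the surface exchange coefficient as
# 6.4e-1 W/m^2K; these presets use 6.4e+2 W/m^2K -- see docs/methods.md for
# the dimensional argument behind reading the printed value as an exponent
# slip.  Override `shared.he` to probe the printed value.
name: case1_38C_deep10mm
mode: steady
geometry:
  depth_mm: 10.0
  height_mm: 8.0
  width_mm: 8.0
  spacing_mm: 2.0
layers:
  scalp_mm: 4.5
  skull_mm: 3.5
  csf_mm: 2.0
materials:
  scalp: {k: 0.342, rho: 1070.0, c: 3600.0, qm: 0.0, qm_inner: 1800.0}
  skull: {k: 0.651, rho: 1520.0, c: 1590.0, qm: 0.0}
  csf: {k: 0.217, rho: 880.0, c: 2360.0, qm: 300.0}
shared:
  mb: 6.06e-3
  cb: 4010.0
  ta: 38.0
  qe: 0.0
  he: 640.0
  tw: 7.0
boundaries:
  surface: robin
  deep: dirichlet
  lateral: copy_face
  robin_order: 2
schedule:
  output_interval_s: 120.0
  end_time_s: 360.0
  reset_interval_s: 120.0
  reset_action: clamp_surface_dirichlet
solver:
  initial_condition: linear_depth
  safety_factor: 0.9
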
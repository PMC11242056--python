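materials:
  e_cartilage: 10.0
  e_fibrous: 3.0
  e_interface: 30.0
  e_lamellar: 10000.0
  e_nail: 1100.0
  e_woven: 4000.0
  mixture_exponent: 1.0
  nu_cartilage: 0.3
  nu_fibrous: 0.3
  nu_interface: 0.3
  nu_lamellar: 0.3
  nu_nail: 0.3
  nu_woven: 0.3
output:
  log_every: 20
  render_every: 0
  snapshot_every: 40
  solver: auto
  solver_rtol: 1.0e-08
  stop_on_union: false
  write_vtk: true
rules:
  destroy_hi: 0.3
  dil_compress: -0.002
  eta_min: 0.0005
  gamma_angio: 0.06
  k_chondro: 0.05
  k_destroy: 0.1
  k_endo: 0.04
  k_remodel: 0.02
  k_resorb: 0.01
  k_woven: 0.03
  low_hi: 0.05
  mid_hi: 0.15
  shoulder: 0.2
  v_min: 0.5
  v_rate: 0.3
scenario:
  axial_margin: 3.0
  body_weight: 750.0
  bone_type: tibia
  callus_diameter: 25.0
  canal_diameter: 13
  cortical_thickness: 4
  days: 240
  devascularize_fragment: null
  fracture_kind: transverse
  gap_width: 2.0
  nail_diameter: 10
  oblique_angle: 30.0
  oblique_azimuth: 0.0
  outer_diameter: 22
  seed: 0
  segment_length: 36
  voxel_size: 1.5
  wedge_center: -90.0
  wedge_height: 9.0
  wedge_span: 120.0
  weight_bearing: 1.0
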
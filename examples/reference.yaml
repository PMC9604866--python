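# Reference study conditions: 50-mm phantom, off-center 5-mm tumor,
# SAR-guided 3x3 aperture, 350x350 DAS image over the 100x100 mm footprint.
# Every key shown here is optional except `phantom`; unknown keys are rejected.
phantom:
  radius: 50.0
  skin_thickness: 2.0
  skin: {permittivity: 37.0, conductivity: 1.1}
  interior: {permittivity: 9.0, conductivity: 0.4}
  tumors:
    - center: [20.0, -13.0, 14.0]
      radius: 5.0
      tissue: {permittivity: 50.0, conductivity: 1.2}
pulse:
  center_frequency: 5.8e9
  time_shift: 0.5e-9
aperture:
  mode: sar_guided     # or full_ring (n_positions: 36)
  rows: 3
  cols: 3
  angular_step: 10.0
  standoff: 10.0
sar:
  source_position: [0.0, 0.0, 60.0]
  voxel_mm: 1.0
imaging:
  grid: [350, 350]
  permittivity: auto   # path-averaged; or a number such as 37.0
  intensity_exponent: 2
seed: 1
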
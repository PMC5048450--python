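design: hydralazine
n_kidneys: 6
seed: 7
b_values:
- 0.0
- 20.0
- 40.0
- 60.0
- 80.0
- 100.0
- 200.0
- 400.0
- 800.0
echo_times:
- 5.0
- 10.0
- 20.0
- 30.0
- 40.0
phantom:
  grid:
  - 32
  - 32
  ellipse_axes:
  - 13.0
  - 9.0
  snr_target: 20.0
  noise_sigma: null
  s0: 1000.0
  uniform_kidney: false
  expected_kidney_voxels: 91
  kidney_voxel_tolerance: 12
fitting:
  b_min: 200.0
  engine: grid
  n_grid: 40
  n_passes: 3
  d_bounds:
  - 0.0002
  - 0.005
  d_star_bounds:
  - 0.005
  - 0.3
fit_bold: true
output_dir: null
save_nifti: false
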
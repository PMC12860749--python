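# Demo pipeline: 10-patient synthetic cohort on 64^3 grids.
# Run:  marrowquant run --config examples/demo.yaml --out scratch/demo --seed 1
cohort:
  n_patients: 10
  ct:
    grid_shape: [64, 64, 64]
    voxel_spacing: [1.0, 1.0, 1.0]
    infiltration_pattern: mixed
    n_focal_lesions: 3
    fat_hu_sd: 12.0
    lesion_hu_sd: 10.0
    noise_sd_hu: 8.0
  pet:
    background_suv: 0.8
    mediastinum_suv: 1.5
    liver_suv_mean: 2.0
    liver_suv_sd: 0.15
    marrow_suv_slope: 3.0
    noise_sd_suv: 0.05
  infiltration_range: [0.1, 0.5]
  treatment_effect: 0.8
  plasma_cell_noise_sd: 8.0
  b2m_noise_sd: 0.5
ct_params:
  radii_mm: [3.0, 4.0]
  stride: 1
pet_params:
  erosion_mm: 2.0
stats:
  alpha: 0.05
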
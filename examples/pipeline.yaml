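# Example pipeline configuration for `cest-zspec --config pipeline.yaml`.
# Every key is optional; unknown keys are rejected.
seed: 1
output_dir: cest_run
grid_shape: [64, 64]
n_per_group: 4
groups: [vehicle, ART, nicotine, cotreat]
noise_sd: 0.005
b0_amplitude_ppm: 0.1
# group/region/pool -> multiplicative amplitude factor
effects:
  ART/thalamus/GLU: 0.7
  nicotine/thalamus/GLU: 0.75
  cotreat/thalamus/GLU: 0.7
  cotreat/hippocampus/NOE: 1.3
wassr:
  search_bound_ppm: 0.5
  grid_step_ppm: 0.01
fit:
  multistart_count: 3
stats:
  outlier_k: 1.5
  welch: false
fit_mode: voxel   # or roi_spectrum
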
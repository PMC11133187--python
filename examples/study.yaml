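# Full simulated study: subject analysis + group statistics.
out_dir: out
band: [0.01, 0.08]
max_lag: 3
uncorrected_threshold: 0.001
fdr_threshold: 0.01
cutoffs: {CESD: 22}
correlations:
  - [mean_pos_lag, CESD]
seed: 1
simulation:
  n_regions: 6
  voxels_per_region: 20
  n_venous_voxels: 12
  region_lags: [0, 1, -1, 2, -2, 3]
  shared_signal_weight: 0.5
  noise_sd: 0.8
  group_connectivity_offset: [1.2, 0, 0, 0, 0, 0]
  lag_jitter_sd: 1.0
  n_per_group: 10
  behavior_spec:
    - {score: CESD, region: 1, metric: lag, target_correlation: -0.5}
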
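# Synthetic cohort: 6 regions x 20 voxels, 12 venous voxels, 150 volumes
# at TR 2.32 s; patients get a connectivity deficit in region 1 and a
# depression score negatively correlated with region-1 lag.
n_regions: 6
voxels_per_region: 20
n_venous_voxels: 12
n_timepoints: 150
tr_seconds: 2.32
region_lags: [0, 1, -1, 2, -2, 3]
shared_signal_weight: 0.5
noise_sd: 0.8
group_connectivity_offset: [1.2, 0, 0, 0, 0, 0]
lag_jitter_sd: 1.0
n_per_group: 10
behavior_spec:
  - {score: CESD, region: 1, metric: lag, target_correlation: -0.5}
seed: 1
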
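# nvcoupling

Resting-state fMRI analysis chain for hemodynamic-lag / functional-connectivity
coupling studies:

- **Time-shift analysis (TSA)** — per-voxel integer lag (in TR units, window
  ±3 TR by default) of each cortical voxel's BOLD series against a venous-sinus
  reference signal; positive lags mark delayed perfusion (hemodynamic lag),
  negative lags mark hemodynamic lead.
- **Intrinsic connectivity contrast (ICC)** — per-voxel mean squared Pearson
  correlation with all other analysis voxels (a voxel-wise degree-centrality
  analogue), with a factorization-based fast path that never materializes the
  N×N correlation matrix and a brute-force reference path.
- **Conjunction masks** — four pairwise-disjoint lag-sign × ICC-quartile masks
  quantifying regional neurovascular coupling / uncoupling.
- **Region metrics** — per-region mean positive/negative lag, lag/lead voxel
  percentages, ICC quartile percentages, and conjunction percentages.
- **Statistics** — Welch two-sample group tests, zero-order and age-partialled
  Pearson brain–behavior correlations, Benjamini–Hochberg FDR within metric
  families, and cohort descriptive tables with clinical-cutoff percentages.
- **Synthetic data** — BOLD phantoms with known injected lags, region-shared
  connectivity signals, group effects, and behavioral scores with target
  correlations, so the full chain is testable without patient data.

## CLI

```bash
# write a synthetic cohort (NIfTI volumes + subject/ground-truth tables)
nvcoupling simulate --config examples/simulate.yaml --out cohort/ --seed 1

# analyze one subject from NIfTI files
nvcoupling subject --bold sub-C000_bold.nii.gz --mask venous_mask.nii.gz \
    --atlas atlas.nii.gz --out out/

# full study (simulation-backed or file-backed, see examples/study.yaml)
nvcoupling study --config examples/study.yaml --seed 1

# recompute statistics from persisted region tables
nvcoupling stats --config examples/study.yaml \
    --regions out/study/regions_all.tsv --subjects out/study/subjects.tsv
```

Exit codes: 0 success, 2 configuration error, 3 data/geometry error.

Output layout: `<out>/<subject>/maps/*.nii.gz` (lag in TR and seconds, peak
correlation, ICC, labelled conjunction masks), `<out>/<subject>/regions.tsv`,
and `<out>/study/*.tsv` (group tests per metric family, correlations, cohort
descriptives), all TSVs carrying a provenance header (config hash, seed,
version).

## Library use

```python
from nvcoupling import (SimulationConfig, simulate_subject, preprocess,
                        extract_reference, compute_lag_map, compute_icc_fast,
                        build_region_table)

cfg = SimulationConfig(n_regions=6, voxels_per_region=20, n_venous_voxels=10)
bold, atlas, venous, truth = simulate_subject(cfg, subject_seed=0)
pre = preprocess(bold)                      # detrend + 0.01–0.08 Hz band-pass
ref = extract_reference(pre, venous)        # mean venous series
lag = compute_lag_map(pre, ref, atlas.analysis_mask, max_lag=3)
icc = compute_icc_fast(pre, atlas.analysis_mask)
table = build_region_table(lag, icc, atlas)
```

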
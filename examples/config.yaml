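# Full workflow configuration for the bundled synthetic retention benchmark.
# Every block is optional; omitted settings fall back to the package defaults.

transform: log          # model log(minutes); errors reported on both scales
retention_threshold: 2.0
folds: 10               # CV folds for grid search and RFE
cv_mode: single         # or: nested (outer CV wraps selection + tuning)
seed: 0

split:
  n_test: 10
  stratify: false

cfs:
  max_features: 20

rfe:
  subset_sizes: [5, 10, 20, 40]

grids:                  # per-model hyperparameter grids (registry keys)
  SVR_CFS: {C: [1.0, 4.0, 16.0], gamma_factor: [0.5, 1.0], epsilon: [0.1]}
  SVR_RFE: {C: [1.0, 4.0, 16.0], gamma_factor: [0.5, 1.0], epsilon: [0.1]}
  Lasso: {alpha: [0.001, 0.0046, 0.0215, 0.1, 0.2154, 0.4642, 1.0]}
  RF: {n_estimators: [200], mtry: [sqrt, third]}
  GBM: {n_estimators: [100, 300], max_depth: [2], learning_rate: [0.05]}

stacking:
  mode: out_of_fold     # or: external (trains the meta-learner on the test
                        # set; emits a leakage warning, kept for comparisons)
  bases: [MLR_RFE, Lasso, SVR_RFE, RF, GBM]

ad:
  k: 5
  percentile: 95
  aggregate: any        # Out at any pH => Out overall

simulation:             # omit this block to load real data with --data-dir
  n_compounds: 97
  n_descriptors: 239
  n_informative: 6
  ph_levels: [2.7, 3.5, 5.0, 6.5, 8.0]
  block_size: 10
  intra_block_correlation: 0.7
  noise_sd: 0.08
  coefficient_drift: 0.1
  n_outliers: 1
  outlier_shift: 10.0
  low_retention_fraction: 0.206
  seed: 0
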
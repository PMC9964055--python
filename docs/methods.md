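# Methods

`qsrrkit` implements a quantitative structure–retention relationship (QSRR)
workflow for small molecules in reversed-phase liquid chromatography (RPLC):
given per-compound molecular descriptors computed at several mobile-phase pH
values and measured retention times, it selects features, tunes a panel of
regression models, combines them in a two-level stacked ensemble, and guards
predictions with a k-nearest-neighbor applicability domain. This note
documents the models, the defaults and why they were chosen, the synthetic
benchmark the tests run on, and the known limitations.

## Target and transform

Retention times are modeled on the natural-log scale by default
(`transform: log`). Gradient retention spans roughly two decades (a fraction
of a minute to ~20 min) and its errors grow with retention; the log transform
stabilizes both. All performance tables report RMSE/R² on the modeling scale
plus external RMSE in back-transformed minutes (`RMSE_test_min`), clearly
labeled, so users can compare on either scale. The transform is a
configuration switch, not a claim about any particular instrument.

## pH-dependent descriptors

An ionizable molecule at a given pH is a population of protonation states
(microspecies). The pH-aware descriptor for a compound is the
population-weighted average of its per-species descriptor values, with the
distribution coefficient logD at the same pH appended as one extra
descriptor column.

Species populations come from the sequential-macrostate
(Henderson–Hasselbalch ladder) model: with pKa values sorted ascending, the
state that has lost *j* protons has relative population
`10 ** Σ_{i≤j} (pH − pKa_i)`, normalized over states. This collapses the
`2^sites` microstates into `sites + 1` macrostates — the standard
reproducible approximation when full microstate distributions (a vendor
software product) are unavailable. Users who have externally computed
fractions can pass them directly to `weighted_descriptors`; `speciate` is a
default, not a gate. logD is always consumed as an input (it comes from
vendor tools in practice); the package never predicts pKa or logD.
Computing the raw per-species descriptor vectors from SMILES is an optional
RDKit adapter (`qsrrkit.rdkit_descriptors`); the core pipeline only needs
descriptor CSVs.

## Preprocessing

* **Low-retention filter**: a compound is removed iff its retention is below
  2 min at *every* pH (conjunctive rule). Such compounds elute near the dead
  time and carry no usable retention signal.
* **Zero-variance filter**: exactly-constant descriptor columns are dropped
  (names are logged).
* **Standardization**: per-feature mean 0 / sd 1 (1/n convention), with
  parameters estimated on the modeling compounds only and applied unchanged
  to the external set. During model selection the fold-training part is
  restandardized inside each CV fold, which is the leak-free reading of
  "standardize the final dataset". A leakage test asserts the scaler is
  byte-identical whatever the external rows contain.
* **Split**: the same seeded draw of external-test compounds (default 10) is
  used at every pH; optional stratification keeps test counts within ±1 of
  proportional allocation across retention quartiles. When the data come
  from the synthetic generator, planted structural outliers are placed in
  the external set, mirroring a study design in which the out-of-domain
  compound is among the externally validated molecules.

## Feature selection

* **CFS (filter)**: greedy forward search on Hall's merit
  `M(S) = k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)`, stopping when no candidate
  strictly increases the merit (or at `max_features`, default 20). A plain
  `|cor| ≥ τ` threshold filter is available as an alternative. Tie-breaks
  are lexicographic by feature name everywhere, for reproducibility.
* **RFE (wrapper)**: features are recursively dropped to each size in a
  candidate grid (caret-style direct drops rather than one-at-a-time),
  ranked by |coefficients| for linear learners or seeded permutation
  importance (10 shuffles) otherwise. Each size is scored by k-fold CV RMSE
  with the elimination re-run on every fold's training part; the smallest
  size achieving the minimum wins and the subset is refit on all data.
* **Embedded**: LASSO coefficients and RF/GBM impurity importances, exposed
  as ranked lists truncated to the top 20 for the consensus procedure.
* **Support identification** (`lasso_support`): the penalty rule is
  selectable — CV-minimum, 1-SE, BIC, or the default **adaptive LASSO**
  (ridge-pilot weights, penalty by BIC on the LARS path). CV-minimum LASSO
  is prediction-optimal but notoriously over-selects (its support precision
  on the package's sparse benchmark is ~0.3); the adaptive variant has the
  oracle property and recovers the exact support there. Prediction-oriented
  LASSO inside the model registry remains CV-tuned.
* **Consensus features**: the intersection of the CFS list, the RFE list and
  each embedded learner's top-20 list, per pH. An empty intersection warns
  rather than fails.

## Models and tuning

The registry mirrors the seven-model lineup of the per-pH performance
tables: `MLR_CFS`, `SVR_CFS`, `MLR_RFE`, `SVR_RFE`, `Lasso`, `RF`, `GBM`
(suffix = feature set; the embedded learners see all features). Unpenalized
MLR is deliberately not offered on the all-features set, where p exceeds n.

Hyperparameters are tuned by exhaustive grid search minimizing 10-fold CV
RMSE on a shared, seeded fold assignment; ties keep the first point in grid
order and the winner is refit on all modeling data. Library-wide defaults
are caret-like (LASSO λ log-spaced 1e-4…10, 25 points; SVR C ∈
{0.25…8}, γ as multiples {0.25…4} of the `scale` heuristic, ε ∈
{0.01, 0.1, 0.2}; RF 500 trees with mtry ∈ {p/3, √p, p/2}; GBM 100–1000
trees × depth 1–3 × rate 0.01–0.1). The bundled benchmark configuration
uses compact grids sized for a 67-compound study (see
`examples/config.yaml`); every grid is user-overridable. With folds seeded
and every estimator seeded, a fixed configuration reproduces byte-identical
outputs.

Cross-validation folds are a seeded random partition with sizes differing by
at most one (67 compounds in 10 folds → seven of 7 and three of 6). Both a
single-CV mode (`cv_mode: single`, the default: CV metrics come from the
grid search itself) and a nested mode (`cv_mode: nested`: an outer CV loop
wraps standardization, selection and inner-CV tuning) are exposed, since
small-n CV scores from the tuning loop are mildly optimistic.

## Stacking

Level 1 is the five-model lineup MLR(RFE), LASSO, SVR-RBF(RFE), RF, GBR;
level 2 regresses the target on their predictions, so the stacked prediction
is `intercept + Σ wᵢ · baseᵢ(x)`. Three design points matter:

1. **Out-of-fold meta training (default).** The meta-learner is fit on
   cross-validated level-1 predictions of the modeling set (default 5-fold,
   averaged over 2 repeated fold assignments in the pipeline; repeats reduce
   the variance of the level-1 matrix). The alternative `external` mode —
   training the meta-learner on level-1 predictions of the external test
   set — is retained for fidelity comparisons but always emits a
   `LeakageWarning`: it reuses the evaluation set for fitting and its
   external error is optimistically biased (a test asserts the direction).
2. **Fold-wise feature selection.** For selector-coupled bases the RFE/CFS
   selection is re-run inside every out-of-fold split. Selecting once on
   the full modeling set leaks the selection into the held-out folds and
   makes those bases' out-of-fold errors look far better than their true
   generalization error, which systematically misleads the meta-learner.
3. **Non-negative meta weights (default).** Base predictions are strongly
   collinear; unconstrained least squares on them yields erratic weights.
   The meta fit is least squares under non-negativity (free intercept), the
   classic stabilization for stacked regressions; an unconstrained `ols`
   solver is available and is what the normal-equations oracle test uses.

The meta-learner is refit per pH condition.

## Applicability domain (kNN, fixed k)

A query's AD statistic is the mean Euclidean distance to its k = 5 nearest
modeling compounds in the standardized all-features space. The threshold is
the 95th percentile (linear interpolation between order statistics) of the
modeling compounds' own leave-self-out statistics — self-distances are
excluded so k = 1 does not degenerate to a zero threshold. A query is `Out`
iff its statistic strictly exceeds the threshold (a tie is `In`). The report
carries per-pH errors in minutes, distances, flags and thresholds, plus an
aggregate column (default: `Out` at any pH ⇒ `Out`; `all` is available).

Two behavioral facts follow from the construction and are asserted by the
benchmarks: a structural outlier 10 training-sd from the cloud is flagged
essentially always, and in-distribution queries are flagged at roughly the
nominal 5% rate. That second fact is a property, not a defect — with nine
in-distribution external compounds one should *expect* ~0.5 false flags per
run, so a run in which only the true outlier is flagged is the likely but
not the guaranteed outcome.

## Evaluation and ranking

RMSE and R² (1 − SSE/SST, allowed negative) are the comparison metrics.
Models are ranked within each pH condition by external RMSE (rank 1 = best;
ties get the average rank) and ranks are averaged across conditions. When
judging the effect of removing an AD-flagged compound from the external set,
the package's tests compare external RMSE in minutes rather than R²: a
flagged compound whose own retention is extreme inflates the total sum of
squares, so R² can look better with the badly predicted compound left in.

## The synthetic benchmark

The generator (`qsrrkit.synthetic`) emulates the statistical shape of a
small in-house RPLC study so the whole pipeline is testable without any
dataset: 97 compounds × 239 descriptors at pH 2.7/3.5/5.0/6.5/8.0 on a
0–20 min gradient. Design choices, all seeded and recorded in a ground-truth
`Oracle`:

* **Descriptors**: equicorrelated Gaussian blocks (width 10, within-block
  correlation 0.7), the simplest structure exhibiting the multicollinearity
  that motivates the feature-selection stage. The same matrix is used at
  every pH — real microspecies-weighted matrices at neighboring pH are
  highly correlated, and the pH effect is carried by the coefficients.
* **Signal**: log-retention is a sparse linear combination of 6 informative
  descriptors whose coefficients drift by 10% per pH step, plus one
  quadratic (curvature) term in the strongest descriptor. The curvature
  echoes the bent retention–lipophilicity relationships of RPLC and gives
  tree/kernel learners a measurable edge over purely linear ones at this
  sample size; a pairwise-product interaction was tried first and proved
  unlearnable at n = 67 — it degraded the linear models without ever
  helping the nonlinear ones, leaving nothing for an ensemble to combine.
* **Scale**: the noiseless signal is affinely mapped into log([2.6, 13])
  min per pH, Gaussian noise (sd 0.08 log-units) is added, and log-retention
  is clipped to log([0.2, 19.9]) so nothing leaves the gradient window. The
  oracle applies the same clip, so with zero noise its predictions
  reproduce the generated retention exactly.
* **Low retention**: 20/97 compounds are overridden with retention drawn
  below 2 min at every pH (they are what the preprocessing filter removes,
  leaving 77 = 67 modeling + 10 external).
* **Outliers**: one compound's whole descriptor vector is shifted 10 sd in
  a random-sign direction — the miconazole-like analogue the AD must catch.

What the generator does **not** emulate: real descriptor marginals (heavy
tails, integer counts, mixed scales), chemistry-driven correlation between
descriptor blocks and retention mechanisms, or measurement artifacts.
Passing tests therefore demonstrate the statistical machinery — selection,
tuning, stacking, AD — not chromatographic accuracy on real compounds.

## Benchmark study sizes

Chosen so the full suite runs comfortably on one CPU:

* Support recovery: n = 500, p = 100, 5 true features, SNR 4, 20 seeds;
  RFE size grid (1, 2, 5, 10, 20, 50).
* Stacking gain: 20 replicates; training fixed at the study-sized 67
  compounds, generalization RMSE measured on a large fresh draw (~165
  compounds) from the same generative model, because a 10-compound external
  set estimates RMSE with ~25% noise and the "best base" is then the
  post-hoc minimum of five such noisy numbers — a comparison dominated by
  evaluation noise rather than by the models.
* AD rates: 100 replicates (n_train = 200, p = 10) for outlier detection;
  the false-alarm rate pools 20,000 in-distribution queries.
* The end-to-end run uses the full 97 × 239 × 5-pH configuration with the
  compact grids of `examples/config.yaml`.

## Known limitations

* The macrostate ladder ignores tautomer/microstate structure within a
  charge state; supply external fractions where that matters.
* Grid search treats the SVR kernel width through a single `scale`-heuristic
  multiplier; strongly anisotropic feature sets may need a custom grid.
* The stack's reported CV numbers reuse the out-of-fold level-1 matrix that
  trained the meta-learner (base-level honest, meta-level in-sample); the
  nested mode bounds the remaining optimism for the base models only.
* With a 95th-percentile AD threshold, ~5% of genuinely in-domain external
  compounds are flagged per condition; users screening small external sets
  should read the per-pH distances, not only the binary flag.
* Rows or columns with missing values are rejected, never imputed.
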
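# Methods

## Problem and data model

Each record is one nsSNV: coordinates (1-based, fully closed, strand-free
— the scores are allele-level), a gene symbol, and a 41-feature vector of
rank scores in [0, 1] in a fixed canonical order: x1–x30 functional-impact
scores, x31 a per-variant mean score, x32–x40 cross-species conservation
scores, x41 the gene-level indispensability (probability of essentiality,
derived in the literature from multi-network centrality; near 0 in
duplicated/mutation-tolerant genes, near 1 in essential genes). Rank
scores follow the dbNSFP convention 0 = benign-like, 1 = pathogenic-like.
Between 0 and 18 of the variant-level scores may be missing per row.
Optional fields: the alternative allele frequency (AAF), its
sub-population maximum (AAF_popmax), and a free-text ClinVar
clinical-significance string.

Labels are the five ordinal classes −2 Pathogenic … +2 Benign. The
compound review strings `Pathogenic/Likely_pathogenic` and
`Benign/Likely_benign` merge into the adjacent "Likely" class (this also
reduces class imbalance); all other significance strings — conflicting
interpretations, drug response, etc. — are treated as unlabelled and
excluded from training. The mapping is case-insensitive, tolerant of
spaces vs underscores, and config-extensible, because upstream exports
vary and no closed list of unlabelled strings exists.

## Preprocessing

1. **Mean score (x31).** The slot that held a mostly-missing score in the
   source layout is filled with the arithmetic mean of the available
   variant-level scores (x1–x30, x32–x40; never x31 itself or x41). Rows
   with no variant-level scores at all are dropped from training and
   flagged at prediction.
2. **Imputation.** Remaining missing cells are filled with per-column
   *training* means; the stored means are reused verbatim at prediction
   time. Tree learners can branch on missingness natively, but mean
   imputation keeps the three learner backends interchangeable behind one
   contract; the missingness mask is retained for diagnostics. A column
   with no observed training value is a hard error.
3. **Downsampling.** The `Uncertain_significance` class is randomly
   thinned seven-fold (uniformly, seeded). Whether thinning should happen
   before or after the train/test split is genuinely open; here it
   happens before splitting, so cross-validation folds see the thinned
   class consistently.
4. **Balancing.** Classes are equalized either by per-row weights
   (max_count/class_count; the default — replication inflates apparent n
   and slows tree fitting) or by seeded oversampling with replacement.
   Both give equal effective class totals.

One master seed drives downsampling and balancing, so the design is
reproducible end-to-end.

## Base learners

The three base learners sit behind a uniform contract (fit on a complete
design; per-class probabilities in fixed code order; non-negative
importance per feature):

* GLM = scikit-learn multinomial `LogisticRegression` (L2, lbfgs).
  Importance = mean absolute coefficient across the five class equations,
  scaled by the feature's standard deviation.
* GBM = LightGBM stage-wise boosted trees. Importance = total split gain.
* DRF = scikit-learn `RandomForestClassifier` (bootstrap rows,
  sqrt-feature columns). Importance = impurity decrease.

Hyperparameters (`ntrees`, `max_depth`, `learn_rate`, `sample_rate`,
`min_rows`, regularization) live in config with the defaults below; the
values used by the original analysis were selected by grid search but
never published, so these are package defaults, not claims. A
`grid_search` operation evaluates an explicit grid by k-fold
cross-validated mean logloss, breaking ties toward smaller `ntrees` then
smaller `max_depth` (prefer the cheaper model at equal skill).

| knob | GLM | GBM | DRF |
|---|---|---|---|
| ntrees | — | 150 | 150 |
| max_depth | — | 6 | 20 |
| learn_rate | — | 0.1 | — |
| sample_rate | — | 0.8 | 0.632 |
| min_rows | — | 20 | 1 |
| regularization | 1e-4 (L2) | — | — |

All fits are single-threaded and deterministic under the spec seed.

In the continuous mode the class codes are fit as real values
(Ridge / LGBMRegressor / RandomForestRegressor); predictions are clipped
into [−2, 2] and rounded to the nearest code only when a class is
explicitly requested.

## Stacking

Fold assignment is the "modulo" rule: a seeded permutation π of the row
ranks, then fold(i) = π(i) mod k (k = 5 by default). The permutation is
taken over rows sorted canonically by content, which makes the fold
multisets — and every downstream metric — bitwise independent of the
storage order of the training rows. If a fold's complementary training
set would miss a class entirely, assignment is redone per class
(stratified) with a warning.

Each base learner predicts its held-out fold, giving a complete
out-of-fold meta-feature matrix of 15 class probabilities (3 real
predictions in continuous mode). Probabilities rather than hard labels
are stacked, preserving calibration information. The meta-learner is a
multinomial GLM with **box-constrained nonnegative weights** (intercepts
free), optimized by L-BFGS-B on the weighted cross-entropy. The
nonnegativity constraint is stated behaviour; the optimizer is this
package's choice. Because the meta-model sits on few, highly collinear
probability columns, an unshrunk fit can drive weights to extreme logits
and overfit small out-of-fold matrices; the ridge penalty is therefore
chosen from a small grid (1e-6 … 1e-2) by inner k-fold logloss, which
keeps the combination calibrated at any sample size. In continuous mode
the meta-model is nonnegative least squares with a free intercept. For
deployment the base learners are refit on all rows.

Prediction applies the stored preprocessing state, streams in chunks
(bitwise identical to a single pass), and breaks exact argmax ties toward
the more pathogenic (lower) code — clinical triage favours sensitivity;
the convention is documented and the probabilities are always emitted so
users can re-threshold.

## Cross-validated reporting

`crossvalidate` emits one metric block per model (GLM, GBM, DRF,
Ensemble). Base learners are scored on their out-of-fold predictions. The
ensemble is scored by a second-level k-fold over the out-of-fold
meta-feature matrix — the meta-learner is refit with each fold held out —
the convention used by the established stacked-ensemble implementations
(e.g. H2O's), rather than fully re-nesting the whole stack per outer
fold. Categorical blocks: logloss, mse/rmse (between the
integer codes and the probability-weighted expected code — a documented
convention, since squared error for a classifier is not otherwise
defined), mpce, HR1–HR5, the confusion matrix and McFadden's pseudo-R².
Continuous blocks: mse, rmse, mae, mrd, Pearson's r.

Metric conventions:

* logloss is averaged per observation and probabilities are clipped at
  1e-15 before logging (standard practice; keeps degenerate zeros
  finite). An unclipped exact path exists for oracle checks.
* HRw uses ordinal adjacency, |predicted − true| ≤ w−1: "within the
  correct or nearest class". The alternative top-k-probability reading is
  provided as `hit_ratio_topk` behind its own name.
* mpce is the unweighted mean over classes of 1 − class accuracy;
  zero-support classes are excluded with a warning.
* mrd is implemented as the mean Gaussian residual deviance — the mean
  squared residual — an interpretation consistent with the gaussian fit
  of the continuous mode (no independent definition exists); it is
  numerically equal to mse.

## Analyses

* Single-feature ranking: each of the 41 features is fit alone in a
  weakly regularized multinomial GLM and scored by McFadden pseudo-R²;
  the table sorts descending. Constant features score 0 with a warning.
* Importance league tables per base learner, descending.
* Class-proportion summaries stratified by gene indispensability
  (default ranges (0, 0.3), (0.3, 0.7), (0.95, 1.0); the 0.7–0.95 gap is
  deliberate and configurable) or by gene symbol (case-normalized).
* Per-AAF-bin score means over six decadal bins [1, 0.1] … [1e-5, 1e-6];
  the gene-level indispensability is excluded from these variant-level
  means; AAF = 0 rows are excluded with a reported count.
* Per-class normalized histograms (20 × 0.05 bins for scores; 0.25-wide
  log10 bins for AAF), normalized by the grand total across classes and
  bins. All bin edges are half-open [lo, hi) with the final bin closed,
  avoiding double counting.
* A per-row flag marking variants both ultra-rare (AAF < 1e-4) and
  over-represented in some sub-population (AAF_popmax − AAF > 0,
  strictly); missing where either field is absent. Rows with
  AAF_popmax < AAF are logged and retained, not discarded — they are
  legitimate data points below the diagonal of the AAF/popmax plane.

## Synthetic data generator

The generator emulates the statistical structure the method exploits,
not the marginal distribution of any real score:

* class codes from priors; defaults proportional to the five training
  class sizes of the reference ClinVar-derived corpus
  (35,698 / 21,510 / 18,716 / 21,931 / 35,659 for −2…+2);
* latent pathogenicity u = (2 − code)/4 plus Gaussian noise
  (sd 0.05), so class-conditional score means increase with
  pathogenicity;
* each variant-level score = separation_j · u + (1 − separation_j) ·
  correlated beta noise (a shared per-row latent factor with loading 0.3
  plus independent Beta(2,2) noise), clipped to [0, 1]. Default
  separations: 0.65 for functional scores, 0.55 for conservation scores —
  chosen once so that synthetic single-feature discrimination and stacked
  accuracy sit in the regime reported for real data (single-feature
  pseudo-R² clustering high, conservation below functional, stacked HR1
  in the low-0.9s). A single shared factor is a deliberate simplification
  of the unquantified real inter-score correlation structure, exposed in
  config;
* per-row available-score counts uniform in 23–40 (of the 40
  variant-level slots; the mean slot is computed downstream and the
  indispensability and label are never masked);
* gene indispensability: genes split into a mutation-tolerant pool
  (Beta(1.2, 8)) and an essential pool (Beta(8, 1.2)); a variant's pool
  is drawn with log-odds proportional to its pathogenicity (default odds
  multiplier 6), so benign variants concentrate at low I — the direction
  of the observed class-proportion stratification;
* AAF: a rarity propensity (2u + noise) is rank-mapped onto a piecewise
  target for −log10 AAF with exactly the configured ultra-rare mass
  (default 0.85 below 1e-4), giving a steep spectrum anti-correlated with
  pathogenicity (configurable, on by default); popmax = AAF × (1 +
  |noise|), never below AAF.

What the generator does *not* emulate: real marginal score shapes,
per-score missingness patterns (missingness is uniform, not
score-specific), linkage between neighbouring variants, population
structure in AAF, and the label noise / reclassification churn of a real
clinical archive. Passing tests therefore demonstrate that the machinery
recovers planted structure under controlled conditions — not that any
particular real-data accuracy is attainable.

A separate frozen 30-row worked fixture (six rows per class, constant
per-row scores, one row with exactly 23 available scores) supports
hand-checkable oracles for the mean score, logloss and round-trips.

## Numerical choices and degenerate inputs

* Probability clipping 1e-15; prediction-row unit-sum tolerance 1e-9;
  written floats at 10 significant digits (write–read–write is
  byte-stable).
* Downsampling below one row retains one row with a warning; balancing a
  single class is a hard error; an all-zero confusion matrix is a hard
  error; zero variance makes Pearson undefined (reported missing).
* Rows failing per-row invariants on read (score outside [0, 1],
  ref = alt, unparseable numerics) are rejected individually with a
  logged reason — a bad row never fails the file. Missing mandatory
  columns do.
* Empty prediction input returns empty output without error.

## Problem sizes used in the test suite

Unit tests run at a few hundred rows with reduced tree counts (the
contracts are size-independent). The statistical acceptance suite runs
stacking dominance at n = 5000, 41 features, k = 5 over 20 seeds; signal
recovery at n = 4000–5000; ranking recovery at n = 1200 over 20 seeds —
sizes at which the stochastic properties are stable while the whole suite
remains a desk-scale run.

## Known limitations

* The mse/rmse convention for the categorical mode (expected code vs
  true code) is one of several defensible definitions.
* The ensemble's cross-validated metrics reuse the out-of-fold
  meta-features for the second-level folds; a fully nested re-stacking
  would be slightly more conservative at several times the cost.
* Chunked prediction is constant-memory per chunk, but the input matrix
  itself is currently materialized by the reader; truly streaming reads
  would need a chunked reader as well.
* At small training sizes (a few hundred rows) the stacked ensemble can
  trail its best base learner; stacking's advantage is a large-sample
  property.
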
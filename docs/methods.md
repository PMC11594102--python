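# Methods

## Problem and model

`thermoprot` frames thermostability prediction as binary classification
of a protein sequence (positive = thermophilic). The signal exploited
is overwhelmingly *compositional*: thermophilic proteomes are enriched
in hydrophobic and charged residues (I, E, K) and depleted in polar
uncharged ones (Q, N, S), and global composition features dominate
positional ones for this task. The feature representation therefore
mixes two views of the sequence:

1. **Protein descriptors** — 14 classical encodings (AAC, DPC, TPC,
   GAAC, GDPC, GTPC, DDE, CKSAAP, CKSAAGP, CTDC, CTDT, CTDD, CTriad,
   KSCTriad) covering residue/word composition, grouped physicochemical
   composition, transitions and positional distribution, codon-expected
   dipeptide deviation, and conjoint-triad classes.
2. **String features** — the sequence treated as text. The shipped
   default is signed feature hashing of character 1–3-grams into 1024
   buckets (vocabulary-free, so it needs no fit state beyond its
   parameters); n-gram counts, LSA/LDA/PCA/t-SNE reductions and
   skip-gram/subword/paragraph embeddings over 3-mer tokens are
   available alternatives.

The default classifier is gradient boosting; bagging, random forests
and a two-layer LSTM are provided for comparison.

## Descriptor definitions and conventions

- Composition families (AAC/DPC/TPC and grouped variants; each k-slice
  of CKSAAP/CKSAAGP) divide window counts by the number of windows, so
  every vector/slice sums to 1 exactly.
- **DDE**: for dipeptide (i, j), `Dc` is the observed fraction,
  `Tm = (C_i/61)(C_j/61)` with `C_x` the standard-genetic-code codon
  count, `Tv = Tm(1−Tm)/(L−1)` with `L−1` the dipeptide count, and the
  feature is `(Dc − Tm)/√Tv`.
- **CTD** uses the canonical 13-property, 3-group residue tables (the
  seven AAindex hydrophobicity scales, van der Waals volume, polarity,
  polarizability, charge, secondary structure, solvent accessibility),
  shipped as packaged data and asserted in tests to partition the
  alphabet. Distribution (CTDD) reports the positions of the first,
  25%, 50%, 75% and last residue of each group as percentages of
  sequence length, with the quantile occurrence index `ceil(q·n_group)`
  — deterministic and exact for any group size; absent groups yield 0.
- **CTriad/KSCTriad** count 7-class triples with gap k; each k-slice is
  divided by its maximum count (bounded features; an all-zero slice
  stays zero). Gap defaults: CKSAAP and CKSAAGP k_max = 5, KSCTriad
  k_max = 2 — moderate dimensionality, configurable.
- Validation precedes encoding: any record with a non-canonical
  character (B, J, O, U, X, Z, gaps, stops, digits) or fewer than 20
  residues is rejected and logged, so encoders never need imputation
  rules.

## Preprocessing

- **Scaling.** Min-max maps each column to [0, 1] using training
  minima/maxima (test values may fall outside; no clipping). Z-score
  uses the population standard deviation (divide by N). Constant
  training columns map to 0 under both and are logged in the scaler
  state. Statistics are always learned from training rows only.
- **SMOTE.** Synthetic minority rows are `x + u(x_nn − x)` with
  `u ~ U(0,1)` and `x_nn` among the k = 5 nearest minority neighbours
  (Euclidean); the output is exactly balanced, originals retained.
  SMOTE runs strictly after the train/test split and inside each CV
  training fold, never touching evaluation rows.
- **Selection.** chi² (requires non-negative features, i.e. after
  min-max), ANOVA F, and mutual information rank columns descending
  with ties broken by column order; variance threshold keeps columns
  with population variance above the cut. The default pipeline uses
  f_classif but keeps all columns unless the user sets a budget.
- **Cost-sensitive weights** `n_total/(2 n_class)` are provided as the
  alternative imbalance treatment.

## Classifiers

Tree families use scikit-learn defaults with a fixed seed, with one
deliberate exception: the shipped gradient-boosting configuration sets
`max_features="sqrt"`. The default feature space is ~14k columns, and
random feature subsampling at each split is the standard way to keep
exact-split boosting tractable and decorrelated in that regime; every
hyperparameter remains overridable. The LSTM backend is an in-package
numpy implementation (two stacked layers of 64 hidden units, scalar
sigmoid head, Adam on binary cross-entropy, 30 epochs, batch 32, fully
seeded). By default it consumes the engineered feature vector as a
length-1 sequence; a one-hot sequence mode (truncate/pad to 500
residues) exists for direct sequence input. The decision threshold is
fixed at 0.5; AUROC/AUPRC are reported threshold-free.

## Evaluation

Recall, Precision, Accuracy, F1, MCC and Specificity are computed from
exact confusion counts; a zero denominator yields 0 and a `degenerate`
flag rather than an exception (MCC is 0 when any factor of its
denominator vanishes). AUROC is the Mann-Whitney rank statistic with
ties counted half; AUPRC is step-interpolated average precision
(trapezoidal interpolation is optimistic in PR space and is not used).
The test suite checks all six threshold metrics against an independent
oracle on every confusion matrix with n ≤ 8 and the ranking metrics
against O(n²) pairwise / explicit threshold-sweep oracles.

## Ablation and importance

Ablation removes a named block's entire column set, re-fits scaling,
resampling, selection and the classifier from scratch on training rows,
and evaluates on held-out rows; `delta = metric(without) −
metric(baseline)`, so positive means removal helped. SHAP attributions
use an in-package exact path-dependent tree-SHAP (validated in tests
against brute-force Shapley enumeration on small trees, and against
additivity to the boosting decision function); sub-feature weights are
mean absolute attributions normalized to sum 1, and a block's
cumulative weight is the sum of its sub-features' weights. Permutation
importance (mean seeded-shuffle metric drop, clipped at 0) is the
fallback for non-tree models.

## Synthetic data: what it does and does not show

The generator draws residues i.i.d. from a class-specific distribution:
uniform 0.05 background, with the positive class shifted by the
configured effect (default: +e/3 on each of I/E/K, −e/3 on each of
Q/N/S, summing to zero). Lengths are uniform on [50, 300]; an optional
motif with per-class insertion probability provides positional signal
for the gapped/triad descriptors. Scenarios: `null` (e = 0), `weak`
(e = 0.02), `strong` (e = 0.15), each 300 + 300 sequences, and
`imbalanced_paper_ratio` (2213 positive vs 3439 negative with the
strong shift) matching the class imbalance of real
thermophile/mesophile training corpora.

Because residues are i.i.d., the generator has no phylogenetic
correlation, no domain structure, and no realistic length/composition
coupling. Passing the benchmarks therefore demonstrates that the
pipeline is leakage-free, calibrated at chance under the null, and able
to recover compositional signal and attribute it to the right feature
block — not that any particular accuracy will transfer to real
proteomes.

## Numerical and statistical choices

- All randomness (generation, splitting, SMOTE, selection, training,
  subsampling) flows from explicit integer seeds; two identical runs
  are byte-identical end to end.
- Benchmark problem sizes: scenarios use 600 sequences with a 25%
  stratified holdout; the null calibration averages 10 seeds and the
  effect-size sweep 5 seeds per effect.
- The planted-block ablation benchmark evaluates on 600 rows (300
  positives) with 2.5-sd class separation: threshold metrics move in
  steps of 1/n_pos per flipped sample, so the evaluation set is sized
  to make a 0.02 noise bound measurable (step ≈ 0.003) rather than
  dominated by discreteness.
- SHAP evaluation subsamples at most 200 rows (seeded) — attribution
  means stabilize well before that.
- Embedding training canonicalizes document order (sorted by content)
  so fitted vectors are invariant to input ordering.

## Known limitations

- t-SNE is transductive: it embeds the training set only and refuses
  unseen data.
- Pretrained transformer embeddings are not implemented; an external
  `id → vector` TSV can be supplied instead.
- The numpy LSTM is a reference implementation for moderate problem
  sizes, not a GPU-scale trainer; likewise the embedding trainer
  targets corpora of hundreds of sequences.
- Exact tree-SHAP covers decision-tree ensembles only; other models are
  directed to permutation importance.
- No hyperparameter search is performed anywhere; defaults are fixed
  and recorded in model bundles for provenance.
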
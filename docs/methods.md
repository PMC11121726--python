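# Methods

## Scope and data model

The package classifies small molecules as active or inactive against a
biological target from precomputed molecular descriptors.  Descriptor
computation itself (e.g. the Mold2 family of 777 1D/2D descriptors) and
docking are *external*: descriptor tables are ingested from CSV, and a
docking score, when present, is treated as one more candidate feature
column.  The in-memory containers are deliberately ordinary: compounds are
frozen `CompoundRecord` dataclasses, descriptor tables are pandas
DataFrames indexed by compound id, and a trained model is a single
`ModelBundle` serialized as versioned JSON (row-major nested arrays,
`repr`-precision floats, so save→load is bit-identical).

## Labelling potency

EC50 is continuous; classes are derived by 2-means clustering of
log₁₀(EC50/µM).  The log transform removes the strong right skew of
concentration data and makes the split scale-invariant: multiplying all
EC50 by a positive constant shifts both centroids but never changes the
partition.  Generic k-means needs random initialization, which would make
the *ground-truth labels* seed-dependent.  In one dimension with k = 2 the
globally optimal partition is always a contiguous interval of the sorted
values, so the implementation scans the n−1 split points and minimizes the
within-cluster sum of squares exactly — deterministic and never worse than
Lloyd's algorithm.  The lower-centroid cluster is labelled active.  All
EC50 values identical is a hard error (no signal to cluster).

## Pruning and standardization

Three pruning rules, with a removal log naming every dropped column and
the triggering rule:

* **near-constant** — the modal value covers strictly more than
  `near_constant_fraction` (default 0.8) of rows; a column with its mode
  in exactly 80 % of rows survives (strict inequality).
* **duplicate** — bit-identical to an earlier kept column; the first in
  file order survives.
* **low variance** — sample variance below `variance_threshold`
  (default 0.20) × the largest column variance in the table.  A relative
  cutoff is the default because descriptor columns live on wildly
  different scales, making any absolute variance cut arbitrary; an
  `absolute` mode exists for corpora already on a common scale.  The
  filter runs on the raw matrix, before standardization (after
  standardization every variance is 1 and the filter would be vacuous).

Both pruning passes are idempotent and order-preserving.

Standardization is per-column z-scoring with sample (n−1) standard
deviation.  By default the scaler is fitted on the **training partition
only** and applied to test and query data, so no test-set statistics leak
into the model.  `standardization_scope="full"` fits on the complete
dataset before splitting instead — the ordering used by some legacy
workflow tools — and is kept as an explicit, visible switch.  Because a
split requires a complete standardized matrix, the Kennard–Stone selection
always runs on the full-data-standardized matrix; under the default scope
the model's scaler is then refit on the raw training rows.

## Kennard–Stone split

Training compounds are selected by max–min Euclidean distance: seed with
the most distant pair, then repeatedly add the row maximizing the minimum
distance to the selected set, until round-half-up(0.70·n) rows are chosen
(136 → 95 train / 41 test).  The procedure is deterministic; ties (equal
max–min distances) break on the lowest row index, so shuffling the input
rows returns the same id set whenever pairwise distances are distinct.
The split spans descriptor space uniformly, which is what a distance-based
applicability domain needs from its training set.

## Feature selection

Best-first search over subsets: an open list ordered by merit, the best
open subset expanded by single-feature additions (and removals in
bidirectional mode), terminating after `stall_limit` (default 5)
consecutive expansions without a new global best.  The default merit is
the correlation-based (CFS) heuristic

    merit(S) = k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)

with r̄_cf the mean |Pearson r| between features and the 0/1 class and
r̄_ff the mean |Pearson r| within S — it favours class-correlated,
mutually non-redundant subsets and needs no inner model fit.  A
zero-variance feature contributes correlation 0 (with a warning).  Note
the closed form implies a perfect duplicate of a selected feature leaves
the merit exactly unchanged (r̄_ff = 1 gives k·r/√(k²) = r): duplication
is never rewarded, but it is the duplicate-pruning rule, not the merit,
that removes copies.  The alternative `wrapper_cv` merit scores subsets by
the mean accuracy of the package's own kNN classifier over seeded,
hand-rolled stratified folds (a fold assignment whose training part loses
a class is redrawn up to 3 times, then errors).  The search is fully
deterministic given (matrix, labels, config).

## Classifier and applicability domain

Classification is k-nearest-neighbours (k = 5, Euclidean) on the selected,
standardized features, with inverse-distance vote weights Σ 1/dᵢ per
class.  Distance ties break on the lowest training-row index.  An exact
match (d < 10⁻¹², below any realistic descriptor noise) would give an
infinite weight; it simply decides the class alone.  Uniform weighting is
available.  A tied vote predicts inactive — the conservative call for a
potency screen, and deterministic.  Every prediction carries its ranked
neighbour ids and distances: the read-across evidence.

The applicability domain uses all n(n−1)/2 pairwise training distances.
With m their mean, distances ≤ m are retained (the convention of the
distance-based APD family: the threshold characterizes the *typical close*
neighbourhood scale, and keeping only the far half would inflate it);
`retain="above_mean"` implements the opposite reading for comparison.
From the retained set, APD = z·σ + d̄ with sample-sd σ (0 if fewer than 2
retained) and default z = 0.5.  A query is reliable when its distance to
the nearest *training* compound is ≤ APD — the training set is the only
reference available at prediction time.  The threshold is 0 (with a
warning) when all training rows coincide.

## Validation

Confusion-matrix statistics with active as the positive class: accuracy,
sensitivity, precision, F1, MCC, Cohen's κ.  κ is computed as
(p_o − p_e)/(1 − p_e), which for a 2×2 table equals
2(TP·TN − FP·FN)/((TP+FP)(FP+TN) + (TP+FN)(TN+FN)); the test suite checks
both identities against scikit-learn.  Any statistic with a zero
denominator is reported as `None`, never coerced to 0.  Formatted output
rounds percentages half-up to one decimal and coefficients to three.

Y-randomization permutes the training labels with a seeded generator,
"retrains" (for a lazy learner: relabels) the model with features,
scaling and APD held fixed, and scores it on the untouched test set.
Holding the features fixed matches scrambling the targets of an
already-built model; re-selecting features per permutation would test a
stricter null and can be done by rerunning the pipeline on permuted
labels.  Same seed ⇒ bit-identical results.

## Synthetic data

`generate_dataset` emulates the statistical shape of a ~136-compound
potency screen: log-EC50 drawn from two Gaussian modes (defaults −1.674
and 0.224, sd 0.4 — two orders of magnitude apart, so the two-means
labelling recovers ≥ 95 % of true classes), a 78:58 active:inactive
balance, 3 informative descriptor columns with a 2-sd class shift, 50
noise columns, 5 near-constant and 3 duplicated columns to exercise the
pruning rules.  SMILES are valid placeholder alkanes.  What it does *not*
emulate: the heavy inter-descriptor correlation, discreteness and mixed
scales of real topological descriptor blocks, assay noise in EC50, or any
structure–descriptor consistency.  Passing tests therefore demonstrate the
pipeline's mechanics and statistical behaviour under its assumptions, not
predictive performance on real chemistry.

## Numerical choices and limitations

* Sample (n−1) estimators throughout (standardizer, APD σ, CFS
  correlations).
* Training-set size: round-half-up of fraction × n.
* Exact-match tolerance 10⁻¹²; merit-improvement tolerance 10⁻¹² in the
  search; serialization is full-precision.
* Problem sizes in tests and the acceptance script: 136-compound
  datasets, ≤ 61 descriptor columns, 200-query oracle comparisons,
  brute-force oracles at n ≤ 12 (labelling) and n ≤ 8 (APD) — sizes at
  which the independent enumeration oracles are exact and fast.
* Binary classes only; no probabilistic output beyond the vote weights;
  no ROC/AUC.  Euclidean metric only.  Best-first with CFS can miss
  features informative only through interactions, and kNN inherits the
  usual curse-of-dimensionality caveats if feature selection is skipped.
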
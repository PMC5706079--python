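# Methods

## Profile parsing and score conversion

A `.hhm` file is parsed by locating the `HMM` column-label line, skipping the
transition-label and begin-state lines, and reading every match-emission line
(residue letter, 1-based position, 20 integer score fields) until the `//`
terminator. Insert-state and transition lines, pseudo-count columns, and the
null model are read and discarded: the profile used downstream is exactly the
L × 20 match-emission grid. Scores convert to probabilities by
p = 2^(−N/1000); the literal `*` encodes −1000·log₂(0) and maps to p = 0.
Residues outside the 20-letter alphabet (X, B, Z) keep their rows; their
scores are parsed as-is.

ASCII PSSMs (the `-out_ascii_pssm` dialect) are parsed from the 40-letter
column-label line; only the first 20-column log-odds block is kept. No
standard inverse transform exists for PSSM log-odds, so the package adopts
the logistic map p = 1/(1 + e^(−x)) — the conventional squashing in the
PSSM-bigram feature literature — implemented as its own function so an
alternative strategy can be swapped in. PSSM columns arrive in BLAST order
(A R N D C Q E G H I L K M F P S T W V Y) and are re-mapped at parse time to
the canonical `.hhm` order (A C D E F G H I K L M N P Q R S T V W Y), making
features comparable across origins.

## Features

For the probability matrix H (L × 20):

* monogram m(j) = (1/L) Σ_{i=1..L} H[i,j] — per-column composition, 20 values;
* bigram b(j,k) = (1/(L−1)) Σ_{i=1..L−1} H[i,j]·H[i+1,k] — adjacent-position
  transition products, 400 values, flattened row-major.

The bigram sum runs over i = 1..L−1: the pair term references row i+1, and the
1/(L−1) normalizer counts exactly those L−1 adjacent pairs. Bigram therefore
requires L ≥ 2. The combined vector concatenates monogram first, then bigram
(420 values); the order is fixed because trained models depend on it. If every
row of H sums to 1, monogram and bigram each sum to 1 — a conservation
identity the tests exploit. No scaling happens in the feature module; any
standardization is the classifier pipeline's explicit choice. Feature tables
are serialized as TSV at 17 significant digits, which round-trips float64
exactly (reading uses the correctly rounded parser).

## Classifiers

The predictor is a soft-margin SVM (linear or RBF kernel); Random Forest and
AdaBoost serve as ensemble comparators. Fitting is delegated to scikit-learn
behind a typed spec. Hyperparameter defaults, chosen as conventional
reference settings and held fixed: C = 1.0 for both kernels; RBF width by the
variance-scaled `"scale"` rule (γ = 1/(d·Var(X)), a median-heuristic-style
default); 100 estimators for both ensembles; all random seeds explicit. An
optional inner-CV grid search over C ∈ {0.01..100} and γ ∈ {1e−4..1} is
provided (`classify.tune`) but off by default so reported numbers are
reproducible.

Feature standardization (zero mean, unit variance) defaults ON for SVMs and
OFF for tree ensembles; it is fitted inside the estimator pipeline, hence on
training folds only — held-out data never leaks into the scaler. SVM scores
are signed margins (threshold 0); ensemble scores are positive-class
probabilities (threshold 0.5); a score exactly at the threshold is assigned
to the positive class. Ranking metrics use the raw scores rather than
calibrated probabilities, avoiding an extra calibration step.

Models persist as a single joblib archive carrying the estimator, the spec,
the feature group/origin, the canonical column ordering, a SHA-256
fingerprint of the training data, and a format-version string checked on
load.

## Evaluation

Accuracy = (TP+TN)/(TP+TN+FP+FN); sensitivity = TP/(TP+FN); specificity =
TN/(TN+FP); MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)). Any ratio
with a zero denominator is reported as 0 with a `degenerate` flag (MCC is
undefined there; 0 is the standard convention). auROC uses the rank-statistic
(Mann–Whitney) formulation, counting tied scores as half-concordant, so
all-equal scores give exactly 0.5; auPR uses step-wise precision-recall
summation. Both are computed by scikit-learn and are cross-checked in the
tests against a brute-force pairwise-concordance oracle.

Cross-validation is stratified k-fold (default k = 10), shuffled by seed;
stratification is appropriate for the near-balanced designs this predictor
targets. The jack-knife is a deterministic leave-one-out loop; a round whose
training set collapses to one class is flagged and scored by majority vote.
Aggregate metrics come from the pooled out-of-fold predictions — the
canonical numbers, matching jack-knife semantics — and per-fold means are
emitted alongside, since "average over folds" is the other common convention
and the two can differ slightly.

## Synthetic data generator

The generator stands in for benchmark datasets whose construction needs
HHblits/PSI-BLAST runs against large databases. Each instance is an L × 20
row-stochastic profile: an instance composition is drawn from a Dirichlet
(sharpness 60) around its class composition, and each row from a Dirichlet
(sharpness `concentration`, default 50) around the instance composition.
Lengths are uniform on `length_range` (default 50–120, typical of domain-sized
benchmark sequences).

Class signal enters in two independent places so each feature family can be
ablated separately:

* composition: positives move `0.5 · effect` of composition mass from the
  natural amino-acid background toward K, R, N, G — mimicking the
  basic, DNA-contacting surface enrichment of real binders (monogram signal);
* transitions: positives carry round(effect·L/10) R→K adjacent-row motifs,
  each a pair of rows concentrated (90% mass) on the motif columns (bigram
  signal).

At `effect = 0` both mechanisms vanish and the classes are exchangeable, so
any classifier should sit at chance — verified over repeated draws. Defaults
(100 per class, effect 0.8, concentration 50) are the package's standard
study conditions: at that separation a linear SVM on combined features
recovers labels essentially perfectly, while effect ≈ 0.2–0.5 produces
intermediate accuracies, giving a monotone signal-strength curve.

What the generator does **not** emulate: phylogenetic correlation between
instances, position-dependent conservation structure, alignment-depth
(Neff) variation, gaps, or realistic HHblits pseudo-counts. Passing tests
therefore demonstrate that the pipeline's machinery is correct and can
recover a planted signal — not that any particular accuracy is attainable
on real proteins.

Fixture writers invert the probability transform with
N = round(−1000·log₂ p) (p = 0 → `*`) and integer-rounded logit for PSSMs,
emitting minimal-but-valid headers in each dialect; write→parse is exact on
integer records, and probability round trips are accurate to the half-step
quantization bound |Δp| ≤ p·(2^0.0005 − 1).

## Numerical and design choices

* Canonical column order is the `.hhm` emission order; everything else is
  re-mapped to it on load.
* Bigram flattening is row-major (b(j,k) at index 20j+k).
* Conservation tolerances: 1e−9 absolute on the sum identities; oracle
  equivalence asserted at 1e−12.
* k-fold requires k ≤ the smaller class size; jack-knife requires n ≥ 3.
* Degenerate inputs (empty matrices, single-class training sets, single-class
  label vectors for ranking metrics) raise typed errors rather than warning.
* Reported problem sizes: the standard study uses 200 instances (100 per
  class) for cross-validation and 60 for the jack-knife, sizes at which the
  full pipeline runs in seconds while the planted-signal and null behaviours
  are unambiguous.

## Limitations

Real-data accuracy depends on profile quality (database, iteration count)
and on hyperparameters this package deliberately leaves at fixed defaults;
published benchmark figures obtained with other datasets and unstated
settings are not expected to be bit-reproducible. The PSSM probability
transform is a convention, not a ground truth; swapping it changes PSSM-origin
features globally but consistently.
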
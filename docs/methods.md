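# Methods

## Problem and model

`pfastox` classifies chemicals into *high* vs. *low* acute oral toxicity
from a numeric molecular-descriptor table. The endpoint follows the EPA
acute-toxicity categories: a compound is low-toxicity iff its rat oral
LD50 is strictly greater than 500 mg/kg; a value exactly at 500 is high.
The classifier is instance-based: a query is assigned the majority class
of its k nearest training compounds by Euclidean distance in a selected,
z-scored descriptor space. The neighbour group doubles as a read-across
similarity group — the evidence a risk assessor inspects — which is why
the kNN model is implemented natively (neighbour identities and distances
are first-class outputs) while random forest, XGBoost and a fully
connected neural network are consumed through adapters around
scikit-learn and xgboost purely as grid-search competitors.

## Pipeline and its assumptions

Order of operations: stratified split → repeated-value column filter →
duplicate-row removal → z-score → Boruta → grid search → final fit → AD.
Every data-dependent parameter (filter decisions, means, sds, selected
features, hyperparameters, AD threshold) is a function of the training
partition only; the held-out 30% is touched exactly once.

**Stratified split.** Total test size is round-half-up of N×fraction;
per-class quotas are floor(n_c×fraction) with leftover slots assigned by
largest fractional remainder (ties to the larger class). This makes the
*sizes* deterministic arithmetic — 307 compounds at 195/112 always give
215 train / 92 test with 58 high + 34 low held out — while the seed
controls only which compounds move.

**Repeated-value filter.** A column is dropped iff its modal value
frequency strictly exceeds 20% of training rows. "Repeated values" is
read as modal frequency: it is the only reading under which constant and
near-constant descriptors are removed at scale while ordinary continuous
descriptors survive. The threshold is configurable.

**Duplicates.** Exact equality on the retained (filtered, unnormalised)
columns; first occurrence kept; conflicting labels are kept-first and
warned about. Float-tolerance matching is deliberately not attempted.

**z-score.** Sample (n−1) standard deviation by default (population
variant by flag). Zero-variance columns are an error that points the user
at the filter, rather than silently producing NaNs.

**Boruta.** From scratch, following the original algorithm: per
iteration, every undecided feature gets a shadow copy with its rows
independently permuted; the importance adapter (default: random forest
with 10 trees, feature fraction 0.9, min impurity decrease 0) scores real
and shadow features together; a real feature records a hit when its
importance strictly exceeds the *maximum* shadow importance. Decisions
use two one-sided binomial tails at p = ½, Bonferroni-corrected by the
number of currently undecided features; decided features leave the pool;
the budget is 100 iterations and survivors are reported tentative.
Tentative features are excluded from the final model by default (flag to
include); if nothing is confirmed the model falls back to tentative
features so a fit always exists. The "rough fix" tentative-resolution
heuristic is out of scope.

**Grid search.** Ranges expand inclusively from (min, max, step); for the
kNN family even k is not a valid candidate (two-class majority voting has
no tie rule — even k is rejected at fit time too), so a [3, 9; 1] range
enumerates k = 3, 5, 7, 9. All candidates share one stratified fold
assignment (scikit-learn's StratifiedKFold; per-class counts differ by at
most 1 across folds); the winner maximises mean validation accuracy with
ties going to the first candidate in enumeration order. The default
neural-network grid accepts epochs and learning rate as independent
parameters (epochs [50, 150; 50], learning rate {0.001, 0.01}, momentum
{0.8, 0.9}) with two hidden layers, ReLU and batch size 128 fixed.

**kNN distance ties** at the k-th neighbour break by training-row order
(stable argsort), so read-across groups are reproducible run to run.

## Validation

The six confusion-matrix statistics (ACC, SEN, SPE, PRE, F1, MCC) are
evaluated exactly; any statistic with a zero denominator is reported as 0
and flagged, never NaN, so batch reports cannot fail on degenerate folds.
The positive class defaults to *low* toxicity — the convention under
which the six statistics of the reference test-set report are mutually
consistent on a 34-positive/58-negative split — and every report states
it. 10-fold stratified CV reports per-fold metrics with mean and sample
sd. Y-randomisation permutes training labels uniformly (class counts are
preserved by construction), refits, and scores the untouched test set;
informative data should collapse to ACC near the class-prior baseline and
MCC near 0.

## Applicability domain

Let dᵢ be the Euclidean distances of normalised training rows to their
centroid and A their mean. The inner subset S = {dᵢ : dᵢ < A} (strict; if
empty — all rows identical — S is the full set) gives d̄ = mean(S) and
σ = sample sd of S (0 for singleton S). The threshold is thr = d̄ + Zσ
with Z = 0.5 by default; a query is reliable iff its centroid distance is
≤ thr (boundary inclusive). The AD is fitted in the selected, z-scored
space — the space the classifier actually operates in.

Note that thr ≥ d̄ always holds, but thr typically lies *below* A, so for
symmetric (e.g. Gaussian) distance distributions well under half the
training points fall inside the domain. Real descriptor data have
right-skewed centroid distances (a dense core plus a sparse tail), which
is the regime where this estimator flags only the tail as unreliable. On
the Gaussian synthetic fixtures the reliable fraction is therefore low
(~30–40%) by construction; this says nothing about a failure on real
tables. An alternative convention (mean distance to the query's k nearest
training neighbours) is available behind the same interface but off by
default.

## Explanation

Shapley values are computed by exact coalition enumeration with the
interventional value function v(S) = mean over background rows of the
model output with off-coalition features replaced by the background's.
The explained output is the continuous high-class vote fraction (classes
encoded low = 0, high = 1); hard labels would violate additivity. At the
≤ 15 features that survive selection, 2^m enumeration is cheap and equals
the quantity kernel-regression explainers approximate, so no sampling
solver is provided. The background defaults to the training matrix,
subsampled to 100 rows under the run seed. Global importance is the mean
|φ| per feature across explained queries; the beeswarm export is a
long-format table (feature, φ, feature value, query id) ordered by global
importance, ready for any plotting layer.

## Synthetic data

The generator emulates the statistical shape of the modelling table, not
its chemistry: configurable per-class sizes (defaults 195 high / 112 low,
the reference imbalance), a handful of informative features
(class-conditional Gaussians with mean separation `class_mean_shift` in
within-class sd units and equicorrelation ρ, defaults 2.0 and 0.3) among
independent standard-Gaussian noise features (default 6 + 44), LD50
values drawn log-uniformly on (500, 5000] mg/kg for low and (5, 500] for
high (toxicity endpoints are log-distributed), and single-fragment
perfluorocarboxylic-acid placeholder SMILES. What it does *not* emulate:
heavy-tailed and discrete descriptor distributions, inter-feature
correlation structure beyond equicorrelated informative blocks, and any
structure–descriptor coupling (the SMILES are decorative). Passing tests
therefore demonstrate the correctness of the machinery and its behaviour
under known signal/noise, not field performance on real descriptor
tables; defaults are sized so the full pipeline runs in seconds.

## Numerical choices and edge cases

- Class boundary LD50 = 500 mg/kg → high (strict "greater than" for low).
- Structure screening is syntactic (dot-fragment check) plus an RDKit
  parse; no desalting.
- Descriptor tables with missing cells are rejected naming the cell;
  mean-imputation is an explicit opt-in.
- Repeated-value threshold comparison is strict (modal fraction exactly
  at the threshold is kept).
- Round-half-up for the total test size.
- Shapley cap at 15 features (2^15 coalitions); beyond it the call errors
  with directions rather than silently approximating.
- All RNG flows from `numpy.random.default_rng(seed)`; per-iteration
  seeds for ensemble fits are drawn below 2^31.

## Known limitations

Descriptor calculation (Mold2 or otherwise) is out of scope — descriptors
arrive precomputed, so `predict` needs a descriptor CSV even when an SDF
or SMILES list identifies the batch. Only binary endpoints are supported
(EPA sub-categories are not retained). The AD estimator is the
centroid-distance rule described above; leverage/Williams-plot and
density-based variants are not implemented. Grid search is exhaustive —
no Bayesian or hyperband search — which is adequate at the reference grid
sizes (≤ 108 candidates).
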
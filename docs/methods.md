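# Methods

`lmscreen` implements a computer-assisted screening pipeline for childhood
speech disorders built on acoustic *landmarks*: timestamped events marking
abrupt articulatory changes, as emitted by a landmark detector from a short
recorded utterance. This note documents the models and procedures, the
defaults and why, the synthetic-data model, and the numerical choices.

## The representation

An utterance is a time-ordered stream of events `(time_s, label,
strength_pct)`. Labels are ten signed types — onset (`+`) and offset (`-`)
of `g` (voicing), `b` (burst), `s` (sonorant), `f` (unvoiced frication),
`v` (voiced frication). Strength is the detector's per-event magnitude,
carried on a 0–100 percent scale (an interface convention of this package,
not a claim about any particular detector's normalisation). Streams are
validated on ingest: labels must be one of the ten, times finite and
nonnegative, strengths within [0, 100]; out-of-order rows are sorted with
a warning rather than rejected, since detectors may emit per-band.

## Feature inventory

Twenty categories are computed per utterance (units in parentheses):

- n-gram counts (#), n = 1–3, on the single time-merged label sequence,
  with overlapping windows of stride 1. Merged-sequence (not per-kind)
  tokenisation is forced by the mixed-kind patterns the method selects
  (e.g. `+b+g+s`). n-grams may span silent gaps: no gap-based sequence
  break is defined, so the simplest reading of "n consecutive landmarks"
  is used.
- mean duration of all bigram / trigram instances (s) — instance-level,
  not per-type, averaging; the alternative reading is noted as ambiguous
  and instance-level chosen once.
- mean matched onset–offset pair duration per kind (s). Matching closes
  an offset against the nearest preceding unmatched onset of its kind;
  unmatched onsets are ignored. Crossing same-kind pairs are not expected
  from a valid detector.
- n-gram rates and speech rate (#/s). Utterance duration is last minus
  first landmark time; the denominator is otherwise undefined by the
  source material, and this choice is recorded in the feature dictionary.
- syllabic-cluster count (#): maximal `+g`…`-g` voiced spans of at least
  30 ms, each bundled with the unvoiced `b`/`f` events since the previous
  cluster. Only the 30 ms voiced-segment rule is implemented; full
  commercial cluster rule sets are proprietary, so absolute cluster counts
  are not comparable with those tools.
- strength features (%): per-type mean strength of each n-gram (an n-gram
  instance's strength is the arithmetic mean of its members — the source
  does not specify; the mean is chosen and fixed), grand means over all
  bigram/trigram instances, and mean absolute strength change between
  consecutive events.
- ratio features (unitless): count of each n-gram type divided by the
  count of each unigram type, exactly the three families
  unigram/unigram, bigram/unigram, trigram/unigram (denominators are
  unigrams only). These BMI-style ratios are the features intended to
  absorb within-speaker scale variation.

A value a sample cannot define (absent token, zero denominator, fewer
than n events) is marked NaN. Cohort assembly takes the union of
families over the cohort alphabet (tokens seen in ≥ 1 sample) and prunes
(a) any feature undefined in *any* sample — dropping cohort-wide rather
than imputing, which makes the surviving feature set cohort-dependent by
design; (b) all-zero columns; (c) duplicate names. The result is a
complete finite matrix. Self-ratios such as `+g/+g` are generated (value
1 wherever defined) and die at the constant-column check in selection.

## Feature selection

Step 1: Pearson redundancy filter at |r| ≥ 0.99, scanning columns in
feature-dictionary order; the first-seen column of a correlated group is
kept (determinism; the threshold treats strong negative correlates as
redundant too). Constant columns, for which r is undefined, are dropped
with a warning. Step 2: recursive feature elimination with
cross-validation (RFECV, delegated to scikit-learn) using an LDA
estimator whose absolute discriminant coefficients rank importance,
stratified 5-fold CV scored by accuracy, eliminating one feature per
step, keeping the smallest feature count that attains the maximal CV
score.

## SMOTE

Class imbalance (e.g. 39 normal vs 12 disordered) is addressed by a
from-scratch SMOTE: each synthetic minority row is
`x_new = x_a + λ(x_b − x_a)` with `λ ~ U[0,1]`, `x_a` a random minority
row and `x_b` one of its k = 5 Euclidean nearest minority neighbours
(brute-force all-pairs distances, index-stable ties; k is reduced with a
warning when the minority class is smaller than k + 1). Exactly
(majority − minority) rows are synthesised, fully balancing the classes:
38/11 training rows gain 27 synthetic rows. Count-category features
(n-gram and cluster counts, unit `#`) are rounded to the nearest integer,
half away from zero; ratio, rate, duration and strength features are left
unrounded. Distances are computed on raw feature values — any scaling
belongs to a pipeline stage fit on training data, not inside SMOTE.
SMOTE is applied strictly after the test split (see MCVT) so held-out
samples never influence the synthetic rows.

## Classifiers

LDA is implemented natively: class means, pooled within-class covariance
(scatter divided by n − K), and shrinkage toward a scaled identity,
`Σ_α = (1−α)Σ + α (tr Σ / d) I`, positive definite for α > 0 — the
standard target for this regulariser. Posteriors follow the Bayes rule
with a shared Gaussian likelihood, computed in the log domain with
log-sum-exp normalisation; a Cholesky factorisation gives the Mahalanobis
terms and log-determinant. A singular covariance at α = 0 raises an error
that names the remedy (nonzero shrinkage). Class priors enter the
posterior directly and are the screening trade-off knob; they are never
tuned automatically.

SVM (linear/poly/RBF/sigmoid), random forest and XGBoost are delegated
to scikit-learn/xgboost behind a uniform contract (fit, predict,
continuous score, fixed class weights). SVM backends are
standardiser+SVC pipelines because SVC is scale-sensitive; the scaler is
fit per training partition. Hyperparameters are tuned by stratified
10-fold CV — grid search for LDA/SVM, random search for the tree
ensembles — with small default grids documented in the code; the grids
are this package's defaults and are not claimed to match any published
configuration. Tuning selects with `refit=False` and walks the
score-ranked grid when refitting, so a parameter point that fits in every
fold but is singular on the full training set (LDA at α = 0) falls
through to the next-best point instead of failing.

## MCVT

One run of Monte-Carlo cross-validation and testing: hold out one sample
per class uniformly at random; assemble (and prune) the feature table
from the remaining samples only; SMOTE-balance; select features
(per-run mode) and tune hyperparameters by 10-fold stratified CV on the
balanced training set; predict the two held-out samples. Fifty runs are
aggregated; per-run sensitivity/specificity are 0/1 indicators, so their
across-run standard deviations are degenerate — they are stored but
flagged and not used. Run seeds derive from the master seed by a
counter-based SeedSequence spawn, making runs reproducible and mutually
independent.

Held-out samples are featurised against the training-defined columns and
alphabet; values they cannot define (absent token strength,
zero-denominator ratio) are imputed with the training-column mean — a
deterministic imputation fit on training data only. This case is not
specified by the protocol's description and is this package's choice.

Two selection modes exist: `per-run` (default, leakage-safe) re-selects
inside every training partition; `fixed-global` performs the two-step
selection once on the full cohort and reuses the list, reproducing the
workflow that reports a single global feature set. Which mode produced
any given published table is not asserted.

## ROC

The screening ROC is swept through LDA class priors: one full MCVT
aggregate per prior gives one (1 − specificity, sensitivity) point;
points are sorted, anchored at (0,0) and (1,1), and integrated by the
trapezoid rule. A conventional score-threshold ROC on scored samples is
provided for diagnostics (e.g. AUC endpoints: 1 for separated scores,
≈ 0.5 for label-independent scores).

## Synthetic-data model

No public corpus accompanies the method, so a generator supplies
cohorts. An utterance is 1–3 syllabic units; each unit is a voiced core
`+g`…`-g` with optional `s` and `v` pairs inside (interior positions
drawn in the central 90 % of the core) and optional `b` then `f` pairs in
the preceding silent gap (base gap uniform 50–300 ms, so inter-unit
bigrams exist and rates are finite). Voiced core durations are normal,
truncated at 5 ms; strengths normal, clipped to [0, 100]. Every onset is
closed by a matching offset, so the pairing grammar holds by
construction.

Class differences are one knob: disordered parameters are
`normal + δ · offset` with offsets −40 ms on the voiced-duration mean,
−0.15 on each pair probability, and −8 strength points, probabilities
clipped to [0, 1]. Defaults (normal voiced mean 150 ± 40 ms, pair
probabilities 0.4–0.7, strengths 70 ± 12) describe a preschooler's short
single word with consonant events in roughly half the units. δ = 0 makes
the class distributions literally identical (the null condition);
δ = 3 pushes the disordered voiced mean to the 30 ms syllabic-cluster
threshold and is exported as the "strongly separated" condition
(`HIGH_SEPARATION`). No published effect sizes exist for these channels,
so δ is not calibrated to any real cohort; it is a test dial, not a
clinical claim.

What the generator does **not** emulate: acoustic realism, detector
noise and missed/spurious landmarks, age effects, within-speaker
repetition structure, or the proprietary syllabic-cluster rule set.
Passing tests therefore demonstrate that the pipeline's bookkeeping,
leakage safety and statistical behaviour are correct under the assumed
stream grammar — not that the screening accuracy observed on synthetic
cohorts transfers to real children's speech.

## Numerical choices and degenerate inputs

- Undefined-feature marker is NaN throughout; pruning guarantees a
  finite matrix before any statistics.
- SMOTE rounding is half away from zero (counts are nonnegative, so this
  is ordinary half-up). Tie-stable argsort fixes k-NN order.
- Strictly increasing timestamps are enforced in the generator by a
  1 μs nudge on collisions.
- Pearson correlations use the population formula; the |r| ≥ threshold
  comparison is exact, so duplicated columns (r = 1) always drop.
- LDA posteriors: log domain, max-subtraction via log-sum-exp; agreement
  with a dense linear-domain Bayes evaluation is maintained to 1e-8.
- Empty streams, single-event streams, header-only files, empty
  manifests, and already-balanced tables are all legal inputs with
  defined (possibly trivial) outputs; impossible requests (one-sample
  classes in MCVT, fold counts exceeding class sizes, λ outside [0, 1])
  raise with explicit messages.

## Problem sizes

The packaged study conditions use a 39 normal / 12 disordered cohort,
50 MCVT runs, 5-fold RFECV and 10-fold tuning CV. At these sizes the
full pipeline evaluation (null plus strongly-separated conditions) runs
in a few minutes on one CPU; the acceptance script reports the problem
size `n` next to every quantity it computes.

## Known limitations

- Cluster counts implement only the 30 ms voiced-segment rule and are
  not numerically comparable with proprietary cluster analyses.
- The feature set is cohort-dependent (pruning rule (a)); feature lists
  selected on different cohorts are not directly comparable.
- Whether ratio-of-count features should also be integer-rounded in
  SMOTE is arguable; they are left unrounded here since they do not
  "only take integer values".
- Per-run selection inside MCVT is honest but high-variance at these
  cohort sizes; the fixed-global mode is lower-variance but leaks
  selection information and is provided for comparison only.
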
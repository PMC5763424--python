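# Methods

## Problem and model

`mirloop` separates real pre-miRNA precursors (stem-loop hairpins of
roughly 50–120 nt) from pseudo hairpins — genomic segments that fold into
hairpin-like shapes without being processed into mature miRNAs — and,
among predicted-real sequences, assigns a species. The classifier is an
AdaBoost ensemble of small back-propagation (BP) feedforward networks over
a fixed 98-dimensional sequence/structure feature vector.

## Feature vector (98 dimensions, frozen schema)

1. **Trinucleotide frequencies (64).** Overlapping 3-mer counts over the
   primary sequence, keys `AAA`…`UUU` in lexicographic order, divided by
   the window count `L − 2`. Normalization makes the block
   length-invariant and sum to 1.
2. **Triplet structure-sequence codes (32).** The dot-bracket string is
   *unified* — every `)` replaced by `(` — so each position is simply
   paired or unpaired. Every 3-window is coded by its first nucleotide
   plus the window's 3-character paired/unpaired pattern: 4 nucleotides ×
   8 patterns (`(((`, `((.`, `(.(`, `(..`, `.((`, `.(.`, `..(`, `...`) =
   32 codes, nucleotide-major order. Kept as raw counts (they sum to
   `L − 2`); windows slide over the whole sequence including the loop.
3. **MFE (1).** The folding backend's energy score, unnormalized: kcal/mol
   from the thermodynamic backend, negated pair count from the fallback.
4. **G-U wobble pairs (1).** Raw count of base pairs joining G with U, in
   either strand order.

Per-column z-scoring is fitted inside the classifier (training data only,
parameters stored with the model): frequencies, counts and kcal/mol live
on very different scales and would otherwise saturate the tanh hidden
units.

## Folding backends

The default backend is ViennaRNA's MFE folder (python bindings when
importable, else the `RNAfold` executable, parsing `structure ( MFE )`).
When neither is available the built-in fallback runs: a Nussinov-style
dynamic program maximizing Watson–Crick + G-U pairs with a minimum
hairpin loop of 3 unpaired nucleotides (a standard steric constraint).
Traceback is deterministic: the 5′-most position of each subinterval is
paired with the smallest admissible partner that achieves the optimal
pair count, pairing preferred over leaving it unpaired on ties. Every
structure records which backend produced it. The fallback is exact for
its objective (verified against exhaustive enumeration for all lengths
≤ 12 in the test suite) but is a pair-count model, not a thermodynamic
one: its energies are not comparable to kcal/mol across backends, so one
backend should be used consistently within a dataset.

Dot-bracket files supplied to `mirloop extract --structures` carry no
energy, so the MFE feature then falls back to the negated pair count.

## Weak learner

A single-hidden-layer feedforward network, tanh ("tansig") hidden layer
and linear ("purelin") scalar output. The hidden-layer size follows the
empirical formula `M = round(sqrt(N + L) + a)` with `a ∈ [1, 10]`;
N = 98 features, L = 1 output and a = 2 give the default 98–12–1
architecture. Defaults: 50 epochs maximum, early stop when MSE ≤ 0.01,
targets ±1, weights initialized uniformly in [−0.5, 0.5] from a seeded
generator.

Two trainers are provided. The default is Levenberg–Marquardt on the
full-batch MSE (the classical choice for nets this small): per epoch the
residual Jacobian is assembled analytically and the damped normal
equations `(JᵀJ + μI)δ = Jᵀr` are solved — through the dual `n × n`
system when parameters outnumber samples — with μ divided by 10 on an
accepted step and multiplied by 10 otherwise. Plain batch gradient
descent with learning rate 0.1 is the configurable alternative;
the learning rate plays no role in LM.

## Boosting

Discrete AdaBoost (the classical two-class weighting):

* sample weights start uniform at 1/n and stay on the probability simplex;
* each round trains a weak learner on a **weighted bootstrap** (n draws
  with replacement, probabilities = current weights) — the net has no
  native per-sample weighting, and resampling is the standard recipe;
* the round's weighted 0/1 error ε_t is measured on the *full* training
  set; α_t = ½ ln((1 − ε_t)/ε_t) with ε clamped to [1e−10, 1 − 1e−10] so
  a perfect learner still gets a finite weight;
* weights update as w_i ← w_i · exp(−α_t y_i h_t(x_i)) and renormalize,
  raising misclassified samples and lowering correct ones;
* a round with ε_t ≥ 0.5 is retrained once from a fresh seed; if it still
  fails, boosting stops early with the learners collected so far.

Prediction thresholds each network's score at 0 into a ±1 vote and takes
the α-weighted vote sum; a tie (score exactly at the threshold, default 0)
falls to the negative/pseudo class. Default 10 rounds. Binary labels are
0 = pseudo, 1 = real, mapped internally to ∓1.

**Species assignment** is one-vs-rest: one binary ensemble per species,
argmax over vote margins normalized by each ensemble's total α mass (raw
sums are not comparable across ensembles that kept different numbers of
learners); ties resolve to the lowest index in the sorted label order.
The intended protocol on real data is two-stage — binary real/pseudo
first, species assignment on predicted-real sequences — which is how the
CLI's `--task species` path filters its training data.

## Evaluation

Accuracy (TP+TN)/total, precision TP/(TP+FP), recall TP/(TP+FN),
specificity TN/(TN+FP). A zero denominator yields an explicit `None`
with a reason, never a silent NaN. Cross-validation is V-fold (default
V = 10), stratified by default because imbalanced data make small
unstratified folds degenerate; the estimator is cloned and refitted per
fold, so feature scaling is always fitted on the training portion only.
Per-fold metrics are averaged arithmetically over the folds where they
are defined. Multi-class reports give per-species accuracy
(correct-in-class / true-in-class), the pooled overall correct fraction
(`total`), and the unweighted per-class mean.

## Synthetic benchmark generator

Positives: a 22-nt 5′ arm sampled with a species-specific GC content, a
6-nt uniform loop, and the arm's reverse complement with independent
per-position mismatches at rate 0.05 — 50-nt records with one long,
low-energy stem. Negatives: mononucleotide shuffles of freshly generated
stem-loops — identical base composition, long stem destroyed (a
dinucleotide shuffle would be a harder negative set and can be built from
the same pieces, but the mononucleotide version keeps the structural
signal strong at desk scale). Species identity is injected **only**
through stem GC content, spread evenly over [0.1, 0.9]; at 7 species this
puts neighbours ≈ 1.8σ of the per-record GC sampling noise apart, chosen
so that every species stays recoverable above chance while neighbours
remain partly confusable. All sampling flows from one seed recorded in
the manifest.

What passing the synthetic recovery tests shows: the full pipeline
(folding → 98 features → scaling → boosting → CV) can learn a cleanly
separable structural contrast and a composition gradient at desk scale,
deterministically. What it does not show: performance on curated hairpin
collections, where positives and negatives differ far more subtly than
"perfect stem vs shuffle" — the generator makes no attempt to emulate
miRBase-like length/composition statistics.

## Problem sizes in the shipped checks

The binary recovery check uses 400 positives + 400 negatives, 10 boosting
rounds, 10-fold CV (mean ACC ≥ 0.9 expected; observed ≈ 0.99). The
species check uses 420 positives (60 per species) with predictions pooled
across stratified 5-fold CV, giving 60 test calls per species so the
above-chance comparison is statistically stable. Unit tests run on 60+60
records with the fallback folder for hermeticity.

## Numerical choices and degenerate inputs

* ε clamp 1e−10 (finite α); sample-weight simplex checked to 1e−12.
* Node-count rounding is half-up (`floor(x + 0.5)`) for determinism.
* Single-class training targets produce a constant model plus a warning
  diagnostic rather than an error; a CV fold whose training portion is
  single-class is skipped and reported.
* Sequences shorter than 3 nt cannot be featurized and are rejected;
  sequences that cannot pair legally fold to the all-dot structure with
  energy 0.
* Hypothesis-based property tests run derandomized; every stochastic path
  (weights, bootstraps, splits, generator) takes an explicit seed.

## Known limitations

* The fallback folder maximizes pair count, not free energy; its
  structures can differ from thermodynamic ones, and mixing backends
  within one feature table is not meaningful.
* The one-vs-rest species bank trains K full ensembles; with strongly
  imbalanced species it inherits boosting's sensitivity to tiny positive
  classes.
* Levenberg–Marquardt solves a dense 1201-parameter system per epoch;
  fine at the 98–12–1 scale but not intended for larger architectures.
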
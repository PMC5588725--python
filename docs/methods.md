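# Methods

## Model

A patient's repertoire is a bag of CDR3 sequences; only the bag's label is
observed.  The classifier assumes the *standard multiple-instance* structure:
a positive patient carries at least one "diagnostic" receptor, a negative
patient carries none.  Under that assumption the bag probability is the
maximum of the per-snippet probabilities (a special case of the generalized
mean), and the per-snippet model is an ordinary logistic unit over the
snippet's features with one shared weight vector.

Snippets are all overlapping k-mers of each CDR3 (step 1, never crossing
CDR3 boundaries); CDR3s shorter than k are excluded from analysis and
counted.  Three encodings are supported: Atchley factors (5 real features
per residue, position-major layout — residue 1's five factors first, which
fixes the weight-map indexing), amino-acid one-hot (20 per residue), and
nucleotide one-hot (4 per base, snippet lengths in whole codons).  The
Atchley constants are embedded verbatim as a data resource with a SHA-256
fingerprint; serialized models record the fingerprint and refuse to load
against a different table.  The embedded table's columns have mean ≈ 0 (to
the table's printed precision) but *not* unit spread — the published factor
scores have per-factor SDs of roughly (0.98, 0.98, 2.13, 0.96, 1.56) —
so the test suite freezes those SDs as a fixture rather than asserting
standardization that the table does not possess.

## Fitting

The negative log-likelihood of the labels under the max-pooled probability
is minimized by full-batch Adam (defaults: 2500 iterations, step 0.01,
β₁ = 0.9, β₂ = 0.999, ε = 1e−8).  The max is piecewise-differentiable; the
(sub)gradient flows through the argmax snippet, first index on exact ties.
`log p` and `log(1−p)` are always computed from the max *logit* via
softplus — max-pooled probabilities saturate quickly at these iteration
counts, and clipped probabilities would produce infinities.

The loss is non-convex (linear detector, nonlinear aggregation), so fitting
uses random restarts: b0 starts at 0, weights at N(0, 1/N_features) — read
as a variance; a config switch (`init_reading="sd"`) gives the other
reading of that convention.  The library default is 1000 restarts, a desk
scale chosen so a full fit stays in seconds-to-minutes on one CPU; the
recovery tests use 200 restarts per fold.  The best restart is chosen by
*unpenalized* training NLL.  Every restart's initial weights derive from
`SeedSequence((seed, *key, restart))`, where `key` namespaces the context
(fold index in cross-validation, permutation index, bag member), so results
are independent of execution order and of how much of the pipeline is run;
patients are canonically sorted by id inside `fit`, making the result
invariant to input ordering.

Two numerically equivalent engines implement the restart-vectorized
training loop in float32 (the per-restart diagnostics and all public
reference functions are float64): a dense path (one BLAS matmul per
iteration over the stacked snippet matrix) and a categorical path that
exploits the positional-categorical structure of all three encodings — a
snippet's logit decomposes into per-position symbol scores, so the forward
pass is k tiny matmuls building (position × symbol × restart) tables plus a
fused gather/max kernel (numba).  The engines agree to float32 rounding and
are cross-checked against the float64 reference loop in the tests; the
categorical path is selected automatically when available.

Supplementary regularization options — early stopping on a held-out
fraction of training patients (restart selection still by training NLL at
the best-held-out-iteration parameters), L1/L2 penalties (excluded from the
restart-selection criterion), and patient-level bagging (ensemble
probability = mean of member probabilities) — are exposed as configuration
with neutral defaults (off); no specific hyperparameter schedule is
canonical for them.

## Evaluation

Model selection runs exhaustive leave-one-out cross-validation per candidate
(snippet length × encoding) and reports exact fractions (n_correct /
n_total).  Candidates that cannot encode the data (a patient with every
CDR3 shorter than k, or missing nucleotide sequences) are kept in the table
marked infeasible.  Accuracy ties break toward fewer features, then toward
smaller (k, scheme); candidate seed keys derive from the candidate itself,
never its grid position, so the winner is invariant to row order.  A
probability of exactly 0.5 counts as a negative call (positive is strictly
> 0.5) and is flagged.

The permutation test shuffles the label vector uniformly (label counts
preserved) and reruns the *entire* LOOCV per permutation.  The p-value uses
the add-one estimator (1 + #{perm ≥ obs}) / (1 + n_perm) — with 20
permutations all below the observed accuracy this gives p = 1/21 < 0.05,
the finest resolution that permutation count supports.  ROC curves sweep
all probability thresholds (ties step simultaneously) with trapezoid AUC,
which equals the normalized Mann–Whitney U statistic; the tests assert that
identity against an independent implementation.

## Interpretation

The weight map is the bijective re-indexing of W into (position 1..k,
factor I..V).  Top-snippet reports locate each patient's argmax snippet in
its source CDR3.  Score histograms bin all snippet scores by diagnosis
group with exact count conservation.  Encoding degeneracy of an amino-acid
snippet is the product of per-residue codon multiplicities under the
standard genetic code (Met/Trp 1 … Leu/Ser/Arg 6; no alternative codes —
human BCR loci); "diagnostic" snippets are those scoring > 0.5 under the
full-cohort model.  Groups are compared with a two-sided Mann–Whitney U
test (asymptotic, tie-corrected), chosen because degeneracy counts are
discrete and heavily right-skewed; a Welch t-test is available behind a
flag, and the analysis defaults to unique snippet strings with an
occurrence-weighted option.

## Synthetic cohorts

The generator emulates the data model the classifier assumes: per-patient
bags of CDR3s with lengths 6–24 drawn from a shifted-binomial peaking at 14
(the human heavy-chain CDR3 length scale), i.i.d. background residues
(uniform by default; a skewed "CDR3-like" preset with CAR…W flanks and
G/S/Y/A/R enrichment is provided), and a k-mer motif planted at uniform
feasible offsets in a configurable fraction of case patients (1–5 plants
per carrier by default, echoing the rarity of above-threshold snippets in
real repertoires).  A biochemical mode plants single-residue variants
within a configurable Atchley-space radius instead of one literal k-mer.
Optional cross-patient contamination exercises shared-sequence removal, and
nucleotide sequences are back-filled with uniformly random synonymous
codons.  Everything is deterministic under the seed, and the emitted truth
records every plant.

Presets: `separable` (12+12 patients, 100 CDR3s each, exact motif, 2
plants/case — linearly separable in snippet space because each residue's
factor vector is an extreme point of the 20-residue cloud in some
direction), `null` (8+8 patients, 20 CDR3s, no plants; kept small because
its role is Monte-Carlo replication), `biochemical` (variant plants).

What passing tests on these cohorts shows: that the estimator recovers a
planted biochemical signal of realistic rarity, that cross-validation and
the permutation null are correctly wired (no leakage; chance-level behavior
without signal), and that interpretation read-outs trace predictions back
to the planted motif.  What it does not show: performance on real
repertoires, where no exact common motif exists, backgrounds are shaped by
V(D)J recombination and clonal structure, and class differences can be
subtler than any plant — accuracy numbers on synthetic presets say nothing
quantitative about patient data.

## Problem sizes and numerical choices

The recovery suite runs the separable preset at 200 restarts × 2500
iterations per fold (25 fits for LOOCV plus the full refit), and the null
calibration runs 20 replicate cohorts × (1 + 20 permutations) LOOCVs at 8
restarts × 200 iterations — sizes chosen so the whole suite completes in
minutes on a single CPU while leaving the model's per-fit settings at their
defaults where it matters.  The null calibration checks the observed LOOCV
accuracy against the central 95% band of the *pooled* permutation
distribution (20 permutations per replicate cannot resolve 2.5% tails on
their own) and requires non-significance in ≥ 90% of replicates.

Degenerate inputs are refused rather than defaulted: a patient with zero
snippets has no defined diagnosis; an empty snippet-score list, a
single-label cohort, and a fold that would lose a label all raise.  A
repertoire emptied by shared-sequence removal is retained but flagged, since
silently dropping a patient would bias cohort-level accuracies.

## Known limitations

- The max aggregator is brittle when every possible snippet occurs somewhere
  in a large repertoire; richer aggregators (soft-max, top-m) are out of
  scope here.
- Duplicate counts are carried through preprocessing but do not weight the
  likelihood; the model is count-agnostic by construction.
- With few patients the maximum-likelihood optimum can memorize
  patient-specific background snippets instead of a shared motif; this is a
  property of the model at small n (cross-validated selection exists to
  detect it), and the test fixtures are sized so the planted signal
  dominates.
- Nucleotide snippets step by single bases (the featurization contract),
  so codon-frame information is not preserved across offsets.
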
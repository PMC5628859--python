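# Methods

## The model

`foldkspec` classifies DNA sequences (putative cis-regulatory modules vs.
background) with a soft-margin linear SVM over an explicit *folded
k-spectrum* feature map that represents every gapped k-mer dependency model
simultaneously.

A dependency model over a k-mer window is a binary *gap mask*: position p is
either dependent (a fixed nucleotide) or a gap (any nucleotide, written N).
With position 1 as the most significant bit the mask is an odd decimal
(trailing gaps are excluded because a k-mer ending in a gap is the same
feature as a shorter k-mer shifted left), giving 2^(k-1) models: for k = 3
these are the monomer (001), dimer (011), one-gapped (101) and contiguous
(111) models. Model m (decimal 2m-1) contributes 4^popcount(mask) features;
the union over models has dimension

    N = sum over odd masks of 4^popcount = 4 * 5^(k-1)

(100 for k = 3, 12 500 for the default k = 6).

Each sequence chi is mapped in three steps:

1. **Count.** Overlapping contiguous k-mer counts over all |chi| - k + 1
   sliding windows. Windows containing an ambiguous base (N) contribute
   nothing; the window denominator keeps its printed value, a deliberate
   simplification that only affects degenerate inputs.
2. **Normalize.** phi_alpha = [count_alpha / (|chi| - k + 1)] divided by the
   background frequency of alpha, cancelling sequence-length and
   base-composition effects. The background is a k-mer count table built
   from a user-supplied genome FASTA, or — by default — from the union of
   the input sequences, with a Laplace pseudocount (default 1) so every
   frequency is strictly positive on small backgrounds; set the pseudocount
   to 0 to reproduce the plain ratio on a large genome.
3. **Fold.** The value of a gapped feature is the *unweighted sum* of the
   normalized values of every contiguous k-mer agreeing with it at the
   dependent positions, e.g. phi_ANA = phi_AAA + phi_ACA + phi_AGA +
   phi_ATA. Folding happens *after* normalization, and is implemented as a
   single sparse (4^k x N) matrix product, so the full map costs little
   more than ordinary k-mer counting. A direct gapped-window scanner
   (`spectrum.count_gapped_direct`) is provided for sensitivity checks; it
   is not the default because the fold-of-normalized definition is the one
   the rest of the pipeline assumes.

The SVM uses the linear kernel on these explicit features. The quadratic
program is solved by libsvm on a precomputed Gram matrix, and the primal
weights are reconstructed from the dual solution as w = sum_i y_i alpha_i
x_i. C defaults to 1 (exposed as a parameter); no feature standardization is
applied on top of the phi normalization. Ties at decision value exactly 0
are assigned to the negative class.

## Enrichment, motif fragments, and false-discovery elimination

For a trained model and a sequence x, the enrichment score of feature n is
r(n) = w(n) x(n); features with r(n) strictly above the cutoff (default
0.005) are that sequence's top-enriched gapped k-mers. Within one gap-mask
model they assemble into a motif fragment, rendered like `(A/T)NT` and
exportable as a MEME-minimal position frequency matrix (gap columns emitted
as uniform 0.25), suitable for external motif-database comparison. A
precomputed hit table (TSV: fragment_id, motif_id, p_value) can be imported;
the comparison tool itself is outside this package.

Composition alone can enrich features that are not binding sites. The
elimination step therefore trains a second SVM in which each positive is
replaced by its 10 scrambled copies (the "false" positive set), with fresh
scrambles of those copies (same multiplicity, separate seed stream) as
negatives — the composition of that negative set is not dictated by the
underlying method description, and this choice keeps the false-positive run
structurally identical to the main run. Features enriched above the cutoff
in a scrambled copy are flagged false; if a hit table is supplied, only
flagged features whose fragment has a significant database hit (p < 1e-3)
are *kept* as false (a flagged feature with no known-motif hit is treated as
an insignificant fluctuation and dropped from the false set). Elimination
then zeroes, in each positive's own profile, every feature whose gap mask
was implicated by that positive's own scrambled copies (`by_model`, the
default); `by_feature` mode zeroes only exact feature matches and is always
at least as permissive. The union of surviving selected features is the
high-confidence set Psi_k^h to which the final feature map is constrained.

## Cross-validation and group assignment

Evaluation uses stratified 10-fold cross-validation repeated (by default)
100 times with re-randomized folds. All scrambles of a positive are pinned
to their parent's fold — the conservative reading of stratification, since
splitting a positive and its permutations across train and test would leak
per-sequence composition. When feature elimination is enabled inside CV,
the false-feature filter and Psi_k^h are derived from the training folds
only; a pre-CV global filter is available but is not the default. Per
positive we accumulate the FN count (repeats in which it was classified
negative); a positive is *detected* when its FN call rate is not strictly
above the cutoff (default 10%; FN = 10/100 counts as detected). Comparing
detection under the folded and the contiguous kernel assigns each positive
to Group 1 (folded only), 2 (neither), 3 (both) or 0 (contiguous only,
structurally empty because the contiguous model is one block of the folded
space). ROC and precision-recall curves use threshold sweeps with
trapezoidal areas; ties share a threshold.

## Synthetic data

The generator emulates the intended use case at desk scale: i.i.d.
background sequences of a given base composition, a consensus motif (over
{A,C,G,T,N}; N positions stay background) planted at non-overlapping
uniform-random positions with an optional per-position substitution rate,
and 10 composition-preserving scrambled negatives per positive. Default
experiment conditions, fixed once: 60 positives of 600 bp, 3 plants per
positive, uniform composition, mutation rate 0. The gapped test consensus
is `GTNNAC` (two interior wildcards, base-balanced so the planted signal is
not confounded with mononucleotide composition, which scrambling preserves
exactly); the contiguous control is `GTCAAC`. Cross-validation in the
synthetic experiments uses 2 repeats per generator seed and ≥ 10 seeds,
which keeps a full two-kernel comparison to a few minutes on one CPU while
averaging fold noise across seeds.

What the generator does *not* emulate: clustered heterogeneous binding
sites of many factors, dinucleotide composition structure, repeats, or
strand symmetry (the pipeline is forward-strand only by default). Passing
recovery tests therefore demonstrates correctness of the machinery and the
expected folded-vs-contiguous ordering under planted gapped signal, not
performance on real regulatory sequences.

## Numerical choices and known limitations

- Feature order is deterministic (ascending mask decimal, then
  lexicographic dependent word), so weight vectors and feature matrices are
  portable across runs; numeric output is printed with 9 significant
  digits.
- Scramble randomness derives per copy from (seed, parent id, copy index),
  so negative sets are reproducible sequence by sequence and independent of
  how many copies are requested.
- Enrichment cutoff comparisons are strict (>); detection-rate comparisons
  are done on the rate with a 1e-12 guard so that cutoffs like 0.3 at 10
  repeats behave as intended in floating point.
- libsvm tolerance defaults to 1e-6; training is deterministic given data
  and tolerance, and example order changes decisions by < 1e-6.
- Because folding is unweighted, features of low-popcount models are sums
  of up to 4^(k-1) contiguous frequencies and dominate the kernel norm.
  These coordinates are nearly composition-determined, hence almost
  identical between a positive and its scrambles: they carry little signal
  but rescale the kernel, which can cost the folded kernel a small amount
  of accuracy relative to the plain contiguous kernel when the true motif
  is fully contiguous and the signal is mid-strength. In our synthetic
  contiguous-motif control this deficit is about 0.02 in mean AUC; it
  vanishes as either kernel approaches ceiling performance. This behaviour
  is inherent to the unweighted fold with no standardization; an optional
  per-model rescaling would remove it but would change the published
  feature map, so it is not applied.
- The false-discovery step at full multiplicity (10 scrambles, 10
  counter-scrambles) multiplies the training set by ~100x and is the
  slowest stage; inside cross-validation it is recomputed per fold, so
  enable it on small datasets or reuse a cached filter via the CLI.
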
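# Methods

This note records the modeling assumptions, parameter choices and numerical
conventions behind the package, and what its synthetic benchmarks do and do
not demonstrate.

## Co-expression corpus

Per-study preprocessing is log2 (when the input is linear-scale intensity)
followed by quantile normalization. Quantile normalization maps each
column's order statistics onto the row means of the column-sorted matrix;
we break within-column ties by stable row order rather than averaging the
reference values over tied entries. The two conventions differ only on tied
values; stable assignment is the one that preserves the defining contract —
after normalization every column holds *exactly* the same value multiset —
and it is what limma's `normalizeQuantiles(..., ties = FALSE)` computes,
against which our implementation was cross-checked.

Probe-to-gene collapse keeps, per gene, the probe with the largest sample
variance (ddof = 1); variance ties break to the lexicographically smallest
probe id so the result is independent of input order. Pair selection uses
the Pearson correlation of gene rows with an inclusive threshold
(default 0.9). Genes with zero variance in a given study are skipped there
with a warning — a gene flat in one study may vary in another, so exclusion
is per dataset, not global. Correlation is computed on the preprocessed
(log, normalized) values, i.e. the preprocessing order is log → quantile
normalization → PCC. Pair sets from all studies are merged without regard
to biological condition; a pair's multiplicity is the number of
contributing studies, which is how repeated co-expression gets more
training weight.

One small-fixture artifact is worth knowing: with very few genes (tens),
quantile normalization itself absorbs a noticeable share of a planted
shared factor, because the module dominates each sample's value
distribution (on a 60-gene fixture, mean within-module correlation drops
from 0.96 to ≈ 0.68). At realistic gene counts the effect is negligible.
Pipeline tests at the standard 200-gene scale therefore feed the
generator's (already log-scale, distributionally exchangeable) matrices to
pair selection directly.

## Embedding model and trainers

The model scores a gene pair by the inner product of their vectors and
normalizes with a full softmax over the vocabulary:
Pr(g_i | g_j) = exp(v_i·v_j) / Σ_j′ exp(v_i·v_j′). The corpus loss is the
negative log-likelihood of all pair occurrences. Because stored pairs are
unordered while the per-pair term is directional, each occurrence
contributes the mean of its two directional terms; this convention makes
the loss symmetric and gives the uniform-embedding value N·log d used as a
sanity anchor. The analytic gradient treats the score matrix S = W Wᵀ
elementwise (dL/dW = G W + Gᵀ W with G = dL/dS) and is verified against
central finite differences.

Two trainers share this objective:

- **Negative sampling** (the production path): each occurrence yields two
  (center, context) events; each event contrasts the true context against
  5 negatives drawn from the unigram^0.75 distribution over vocabulary
  frequencies. Input weights start uniform in ±0.5/k, output weights at
  zero, and the learning rate decays linearly from 0.025 to 1e-4 across
  all scheduled occurrences. The input matrix is exported as the
  embedding. Training is single-threaded and fully seeded: one generator
  drives initialization, per-epoch shuffles and negative draws, so equal
  configs give bitwise-equal weights. Epochs re-shuffle the occurrence
  sequence but never change the multiset.
- **Exact mode** (small vocabularies): full-batch gradient descent with
  backtracking on the tied-weight full-softmax loss, for testing the
  printed objective directly; it reaches within 1% of an L-BFGS
  minimization of the same loss on toy corpora.

Genes with multiplicity-weighted frequency below 5 are removed before
training, along with every pair touching them. Default hyperparameters are
k = 200 and 9 epochs — the grid-search optimum at production scale — while
tests use k = 50 on the 200-gene fixture.

A caution about comparing the two trainers by clusteredness: at the
full-softmax optimum on module-structured corpora, between-module inner
products are driven negative far enough that the *mean background inner
product crosses zero*, so the clusteredness ratio becomes unstable
(arbitrarily large or negative) for exact-mode embeddings. This is a
property of the ratio statistic, not of either trainer. The meaningful
shared property — both trainers separate planted modules, with
within-module mean inner product exceeding the between-module mean — is
what the suite asserts.

## Clusteredness and the hyperparameter grid

Clusteredness divides the mean within-pathway inner product by the mean
inner product over a random-pair background. Pathways are filtered to
2..50 genes; pathway genes missing from the vocabulary are dropped per
pathway, and pathways left with fewer than 2 in-vocabulary genes are
skipped. Each retained pathway enters the numerator with equal weight
(mean of pathway means), so large pathways do not dominate. The background
enumerates all unordered pairs among a without-replacement sample of
vocabulary genes (1000 genes → 499,500 pairs at production scale; the
sample seed is recorded in the grid result). The statistic is invariant
under global orthogonal rotation and under global rescaling of all vectors
(numerator and denominator both scale by c²); a background mean within
1e-12 of zero raises rather than returning a meaningless ratio.

The grid search exploits that epochs are cumulative: one training per
dimension, checkpointed at every epoch, fills an entire row of the
dimension × iteration table. This is equivalent in expectation to
independent per-cell runs and about an order of magnitude cheaper. Ties on
the maximum break toward smaller dimension, then fewer iterations.

For a *random* embedding with mean-zero vectors, numerator and denominator
are both near-zero averages, so individual clusteredness draws are heavy
tailed around 1; the suite therefore checks the random baseline as a mean
over 20 seeds against its own standard error rather than as a pointwise
value.

## Pair datasets and the GGIPNN classifier

Positive pairs share at least one retained annotation: evidence code in
{IDA, IMP, IPI, IGI, TAS}, term not in the configurable exclusion list
(defaults: GO:0007165, GO:0006468, GO:0046777, GO:0006470), and term level
strictly greater than 3, where a term's level is its minimum depth from
the root (root = 0). Negative pairs are genes whose descendant-closed
annotation sets (all evidence codes, all levels) are disjoint — sharing
even a child of an annotated term disqualifies. These two definitions are
mutually exclusive by construction. Negatives are downsampled to the
positive count (seeded) before splitting; genes are then partitioned 7:1:2
by largest-remainder rounding of a seeded shuffle, and a pair is retained
only if both endpoints land in the same block. A block may legitimately
retain zero pairs when it holds very few genes (one validation gene at
10-gene scale); only a block with zero genes is an error.

The classifier embeds both genes through a shared lookup matrix
(pretrained rows, or seeded uniform ±0.05 random rows), concatenates them,
and applies fully connected layers 2k → 100 → 100 → 10 → 2 with ReLU,
inverted dropout 0.5 on the first two hidden layers, and a 2-unit softmax
(equivalent to a sigmoid for this binary task) trained with mean
cross-entropy. Optimization is Adam at 1e-3, batch 256, up to 20 epochs
with early stopping on validation AUC (patience 5, best weights restored)
— conventional defaults, all exposed in the config. In frozen mode the
lookup matrix is asserted bitwise unchanged after training. AUC is the
Mann–Whitney statistic of the positive-class score with midranks for ties,
cross-checked in tests against both an O(n²) pairwise count and
scikit-learn.

## Visualization

The map pipeline is PCA (centered, top-variance components, to
min(50, k)) followed by Barnes–Hut t-SNE (θ = 0.5, perplexity 30, learning
rate 200) with a seeded, single-job run for determinism. The iteration
default is 1000 — appropriate for fixture-scale maps; genome-scale maps
of real embeddings want far more (1e5) for stability. A vocabulary of at
most 3 × perplexity points is rejected with the rule spelled out. Tissue
z-scores standardize a gene's per-tissue mean against its cross-tissue
mean using the sample (n−1) standard deviation; flat genes get an all-zero
row and are listed rather than producing NaNs, and expression is
log2(x + 1)-transformed first by default (flag-controlled).

## Synthetic compendium generator

Each dataset draws, per module and sample, a latent activity
f ~ N(0, 1); a member gene's value is latent_strength · f plus
N(0, noise_sd²) private noise, and background genes are N(0, 1). Under
this single-factor model the expected within-module Pearson correlation is
latent_strength² / (latent_strength² + noise_sd²), which makes threshold
behavior analytic. Defaults — 200 genes, 4 modules of 40, 3 datasets of
100 samples, latent_strength 1, noise_sd √(1/24) — put the expected
within-module correlation at 0.96, comfortably above the 0.9 selection
threshold, with 40 background genes that form no pairs. All randomness
derives from one seed through spawned generator streams (one per dataset),
so fixtures are bit-reproducible. Module memberships double as pathway
sets and as an annotation table whose module terms sit at level 5 under a
synthetic chain to the root (so the level filter never removes them, and
positive pairs are exactly within-module pairs); background genes carry
private terms on a separate branch and only ever appear as negatives.

What the generator does *not* emulate: batch and platform artifacts,
saturation, probe cross-hybridization, overlapping or hierarchical
modules, heavy-tailed expression, and incomplete/noisy annotation. Passing
tests therefore demonstrate that the algorithms recover clean planted
structure under the stated statistical model — not that real compendia
yield embeddings of any particular quality.

## Problem sizes in the test suite

The suite and the acceptance script run the full pipeline at the standard
fixture scale (200 genes, 9-epoch k = 50 embeddings, 6240 balanced pairs,
5–10 classifier seeds), which the package completes in tens of seconds;
exact-mode oracles use 6-gene corpora where the full softmax is
enumerable.
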
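# Methods

This note records the modelling decisions, defaults and numerical
details behind `scmod`, and what the synthetic study does and does not
establish.

## Input model and preprocessing

The input is a non-negative genes × samples matrix (FPKM-like) plus a
sample → subtype map with T classes; the control/normal group is
treated as one of the T classes throughout. Values are transformed as
log2(x + 1); the pseudocount handles zeros. The mean-expression filter
(default threshold 10) is applied to the **raw** scale, because a
threshold of 10 is only meaningful for FPKM-like units; the
variability ranking uses the mad of the working (log) values and keeps
ceil(0.9 · n) genes, ties at the boundary broken by gene id so runs
are reproducible. mad carries no 1.4826 consistency factor — it is
used as a ranking statistic, not a variance estimate.

## Subsampled co-expression networks

Each subtype's network is an aggregate over F subsamples ("folds") of
Ns samples: fold correlations are Spearman (average ranks on ties,
two-sided p from the t approximation), combined by arithmetic mean for
the correlations and geometric mean for the p-values. Folds are drawn
independently without replacement within a fold; if a sample is never
drawn, unseen samples are swapped into the last folds so coverage is
guaranteed. Defaults: Ns = (smallest subtype size − 1) capped at 50 —
Ns must be below every subtype size so all subtypes use the same fold
size, which is the point of subsampling: Spearman significance depends
on n, and equal fold sizes make edge significance comparable across
imbalanced subtypes. F = ceil(3·n/Ns) makes expected coverage
near-certain before the repair step.

The combined p is a significance *score*, not a calibrated p-value
(the geometric mean of dependent fold p-values has no clean null
distribution); it is only compared against the edge threshold
alpha = 0.01. Fold p-values of exactly 0 are clamped to machine
epsilon so one saturated fold cannot zero the product. Correlations
are combined **signed**; absolute values appear only in the weighted
adjacency and in the perturbation features. After thresholding, genes
without any significant edge are dropped.

## Module detection

Modules come from a WGCNA-style pipeline reimplemented on the pruned
network: unsigned adjacency a = |cor|^β gated by the significance
mask, topological overlap TOM_ij = (Σ_u a_iu a_uj + a_ij) /
(min(k_i,k_j) + 1 − a_ij), average-linkage clustering of 1 − TOM and a
static cut at height 0.95. Clusters below 10 genes fall into Module0,
the residual bin; surviving modules are renumbered by decreasing size.

Two details differ from a naive transcription and matter at the scale
of a few-hundred-gene network:

- **Soft-threshold selection.** The scale-free fit R² (signed, ten
  equal-width connectivity bins) is unreliable here: it tends to rise
  monotonically toward large β, where adjacency collapses and the
  static cut can no longer form modules at all. Candidate powers are
  therefore capped where the lower-quartile significant edge keeps an
  adjacency of at least 2 × (1 − cut height) — i.e. the weakest
  plausible module must stay clusterable — and the smallest capped β
  reaching R² ≥ 0.8 is chosen, falling back to the canonical unsigned
  default β = 6 when none does.
- **Membership cleanup.** A static cut bounds a cluster's merge
  height, not each member's fit. Two one-sided cleanups run per
  cluster: genes whose mean in-cluster dissimilarity exceeds the cut
  height are peeled iteratively, and genes whose intramodular
  connectivity (mean |cor| to cluster peers) falls more than 15 %
  below the cluster median are removed in a single pass. The second
  rule targets background genes that ride into a module through a few
  borderline-significant edges amplified by shared-neighbour
  topological overlap — their connectivity is far below the module's
  typical level — while a uniformly weak but coherent module keeps
  all members, since the comparison is relative to the module's own
  median. Both margins (the 2× adjacency factor and the 0.85
  connectivity ratio) are structural safety factors; they were fixed
  once against simulated block networks and are not data-fitted at
  run time.

Dynamic tree cut and module-eigengene merging are deliberately out of
scope; the static cut plus cleanups serves the same purpose at this
scale with far less machinery.

## Specific modules and specific edges

Two per-module scores are ranked and summed. Score 1 (aggregation
specificity): the maximum overlap ratio |M ∩ M'|/|M| of the module
against every module of every other subtype, ranked ascending —
Module0 of target subtypes is excluded, since membership in a residual
bin is not co-clustering. Score 2 (correlation gap): the module's mean
significant-edge correlation in its own subtype minus the mean over
the same gene pairs in each other subtype's network — substituting 0
for pairs that are absent or not significant there — taking the
minimum (worst case) over subtypes and ranking descending. The module
with the smallest rank sum is the subtype's specific module; ties go
to the better score 2, then the smaller module index.

Specific edges are the significant in-module pairs ranked by
Δcor = corˢ − max over other subtypes of corˣ (signed maximum; the
absent-as-0 rule again), top E kept, ties broken lexicographically.
Requesting more edges than the module holds is an error rather than a
silent truncation, because downstream feature vectors must have the
same length for every subtype. E defaults to 100; the synthetic study
uses E = 50, matched to its 25-gene planted modules (max 300 pairs).

## Network-perturbation features

A reference network set holds, per subtype, the Spearman correlations
at its E specific edges over P randomly drawn **training** samples of
that subtype (P = smallest training subtype − 1, capped at 30;
n_sets = 10 sets drawn). Featurizing a sample against one set
recomputes, per subtype, the edge correlations with the sample
appended and records |cor′ − cor| per edge; the T blocks concatenate
to a length-T·E vector with entries in [0, 2].

One correction matters for small subtypes: a training sample is often
*inside* a reference draw (with 11 training samples and P = 10, almost
always). Appending it again would measure the perturbation of a
network that already contains the sample, systematically understating
own-subtype perturbations in training relative to unseen test samples
and shifting the two feature distributions apart. Such samples are
instead scored leave-one-out — the draw without the sample is the
reference, the full draw the expanded network — which restores the
train/test match.

Training augmentation pairs each sample with enough reference sets
(seeded round-robin) that every subtype contributes about as many
vectors as the largest one; test samples are featurized against all
sets so each yields n_sets votes. Reference sets are rebuilt from the
training portion only — an audit helper asserts no test id ever enters
a reference.

## Classifier

A fully connected network with hidden layers (50, 10), ReLU, softmax
output and categorical cross-entropy, optimised by SGD (learning rate
0.1, mini-batches of 32, at most 500 epochs) with early stopping on a
stratified 10 % validation split (patience 20). The backing
implementation is scikit-learn's `MLPClassifier`; its early stopping
monitors validation score rather than validation loss, which serves
the same purpose. Learning rate and batch size were chosen so the
optimiser actually reaches the training optimum at the few-hundred-
vector scale; with near-full-batch updates at rate 0.01 SGD stalls far
from it.

Because the feature dimension (T·E = 200) exceeds the number of
training vectors, a single run is visibly sensitive to weight
initialisation. The classifier therefore trains 5 identically
configured members from consecutive seeds and averages their softmax
outputs; prediction and voting operate on the ensemble probabilities.
Prediction uses an in-package forward pass over the exported weights
(including the single-logistic-unit binary case), so a model
serialised to JSON reproduces probabilities bitwise.

Votes: each of a sample's vectors predicts its argmax class; the modal
class wins, ties broken by highest mean softmax probability, then
class order. Metrics: accuracy, macro-precision and macro-recall
(per-class zero-division counts as 0, logged), and macro-F1 as the
harmonic mean of macro-P and macro-R — deliberately *not* the mean of
per-class F1 scores. Stratified k-fold cross-validation rebuilds
reference sets and classifier per fold from that fold's training
portion.

## Synthetic data generator

Per subtype, a block of `module_size` genes follows a one-factor model
g = baseline + load·z_sample + noise_sd·ε within that subtype only
(population Pearson correlation load²/(load² + noise_sd²) = 0.90 at
the defaults; Spearman on Gaussians slightly lower, ≈ 0.89); in other
subtypes those genes are independent unit-spread noise. A shared block
uses one factor across all samples, emulating housekeeping-like
co-expression that must *not* be called subtype-specific. Remaining
genes are independent with spread 0.6 — below the co-regulated genes'
≈ 0.95 marginal spread, so the mad filter ranks them last, as it would
rank flat genes on real data. Values sit on a log-like scale around
baseline 8 and are clipped at 0; pipeline runs on synthetic data use
`log_transform=False` and `min_mean=0` (the FPKM-scale mean floor has
no meaning here). Defaults: T = 4, sizes (20, 60, 12, 25) — an
imbalance profile echoing breast-cancer subtype frequencies — 300
genes, module size 25, one shared block of 30, load 0.9, noise 0.3.

What the generator does **not** emulate: count-based noise (negative
binomial), batch effects, dropout, correlated noise between blocks,
or any overlap between subtype signatures. Passing the synthetic
acceptance checks therefore shows the pipeline recovers planted
rank-correlation structure and classifies under imbalance; it does not
certify performance on real tumour data.

## Reproducibility and numerics

Every stage seed derives deterministically from the master seed as
crc32(f"{seed}:{stage}") masked to 31 bits, so stages can be re-run in
isolation and a full re-run reproduces every artifact bitwise. Other
conventions: constant genes in a fold get correlation 0 / p 1;
Spearman matrices fall back to an in-package rank-then-Pearson
computation when scipy collapses the output (two genes, or any
constant gene); TOM is clipped to [0, 1] and its dissimilarity
symmetrised before linkage; the test split takes round(f·n) samples
per subtype with a minimum of 1 when f > 0.

## Problem sizes

The test suite and the acceptance script run the full pipeline on the
default synthetic study (300 genes, 117 samples, five seeds); one run
takes a few seconds, the whole suite well under a minute. These sizes
were chosen to exercise every stage — including the smallest-subtype
pathologies — at interactive speed; nothing in the implementation is
specific to them, and the per-stage costs grow as genes² per fold for
networks and genes² log genes for clustering.
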
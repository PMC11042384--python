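# Methods

## Problem setting

A CRISPRi screen assigns each guide RNA a per-task outcome: a log2 fold
change and an FDR-adjusted p-value for cell fitness and for nearby gene
expression, and a mean count across four wild-type replicates for
baseline abundance. `guidescreen` models these outcomes from two inputs:
the 20-bp protospacer sequence and a vector of functional annotations of
the targeted site (epigenetic marks such as H3K27ac/H3K4me3/ATAC, TF
ChIP signals, thermodynamic energies ΔG_H and ΔG_B, gene-essentiality and
ploidy covariates).

## Labels and filtering

Guides with adjusted p < 0.05 are labelled significant and p > 0.2
insignificant; the closed gray zone [0.05, 0.2] is excluded from both
training and testing, since borderline calls are the most likely to be
mislabelled. For the fitness task, guides with total counts < 125 are
removed before labelling: below that depth the screen lacks power and the
adjusted p-value is uninformative. The count filter applies to the
fitness task only (a config override extends it to other tasks).
Promoter/enhancer classification uses an explicit rule — a guide is a
promoter guide iff its midpoint lies within ±2 kb (closed interval) of a
TSS on the same chromosome — with the window tunable. For the expression
task, each guide keeps only its most significant gRNA-gene pair; ties on
adjusted p break by larger |log2FC|, then lexicographic gene id, making
the selection deterministic.

## Sequence features

Positions are 1-based from the 5' end (PAM-distal = position 1); the
protospacer string is used as given, with no reverse complementing. The
one-hot matrix is 4×20 with rows in A,C,G,T order. The bag-of-words
vector has four blocks in a fixed, documented order: 80 positional
mononucleotide indicators, 304 positional dinucleotide indicators (a
dinucleotide at position p spans bases p and p+1, so 19 start positions ×
16 dinucleotides), 4 mononucleotide counts and 16 dinucleotide counts —
404 features with block sums (20, 19, 20, 19) for every valid guide.
Lowercase input is uppercased; N and other ambiguity codes are rejected
rather than imputed, because a one-hot column must contain exactly one 1.

## Annotation features

Read-derived signals are counted into non-overlapping 1-kb half-open
genome tiles; each read is assigned to the tile containing its 5' end
(start for +, end−1 for −). Missing values are zero-imputed except the
ploidy covariate, which takes the mode of observed values (ties to the
smallest). Continuous features are winsorized by capping at the 95th
percentile; caps are fit on the training folds only and re-applied to
held-out data to avoid leakage (a `winsorize_scope` choice of global
fitting is available via `fit_index=None`). ΔG_H can be supplied as a
precomputed column or approximated by a nearest-neighbour sum of stacking
free energies over the 19 dinucleotide steps (the Sugimoto 1995 RNA/DNA
hybrid table ships as an optional default); with no parameter table the
feature is declared missing rather than fabricated. ΔG_B has no
computable definition here and is accepted only as a precomputed column.

## Convolutional model

Architecture as in the README: four parallel valid 1-D convolution
groups (kernel 2 × 50 filters with stride 2 and no pooling; kernels 3, 5,
7 with 100, 70, 40 filters, each max-pooled by 2), dropout 0.4 after
every group, flattened concatenation of 2,240 values (10·50 + 9·100 +
8·70 + 7·40), an 80-node layer with dropout 0.3 as the sequence
embedding, a single size-1 kernel giving the 20-dimensional
mononucleotide path (one filter, because the path must be
20-dimensional), then 80/60/40-node layers with dropout 0.4 and one
output node; ReLU on all hidden layers. The dropout-after-every-group
reading includes the 2-nt group: the stride-2 exception is taken to
concern pooling only. Ablation variants: `no57` keeps kernels {2, 3}
(flattened 1,400), `no357` keeps kernel 2 only (flattened 500).

Training uses Adam with the per-task defaults (learning rate 1e-4 for
fitness and wild-type counts, 5e-5 for expression; batch 256 for fitness,
512 otherwise; cross-entropy for binary targets, MSE for counts).
Because epoch counts are an open choice, the default is at most 100
epochs with early stopping on validation loss (patience 10) and
best-weights restore; the validation split is 10% of the training folds,
grouped by DHS where applicable. Weight initialization is He-scaled with
a fixed seed; given a seed, training is exactly reproducible. The
network and its backpropagation are implemented directly in NumPy; at
these input sizes (4×20) a CPU handles full training runs in minutes.

For the synthetic ablation and attribution studies in the tests and the
acceptance script, training uses a learning rate of 1e-3 with up to 150
epochs (patience 40). At the published 1e-4 the motif-discovery plateau
on planted-5-mer data is long enough that early stopping can fire before
the signal is found; the larger rate reaches the same solutions in a
desk-scale budget. Because Adam occasionally stalls on that plateau
altogether, `train_cnn_restarts` trains from several initializations
(default 3) and keeps the model with the best validation loss — selection
never touches test data. Regression targets are log1p-transformed and
standardized before MSE training (rank metrics are unaffected); the raw
mean-count scale remains available.

The kernel-ablation comparison is run in a deliberately sample-limited
regime (2,000 training guides). With abundant data every variant
eventually recovers the planted 5-mer — the 2-nt stride-2 windows tile
the sequence losslessly, so even `no357` retains full information and
converges to near-parity — and the comparison degenerates to optimizer
noise. With limited data the long kernels' matched-filter inductive bias
shows as a genuine generalization gap (full > no57 > no357), which is the
property the ablation is meant to exhibit.

## Gradient-boosting model

Inputs are the 404 BoW features concatenated with the annotation vector.
The hyperparameter protocol samples 57 configurations uniformly without
replacement (seed-controlled) from the grid {depth 3, 5, 7, unbounded} ×
{min child weight 8, 12, 16, 20} × {row subsample 0.5–1.0} × {column
subsample 0.5–1.0} × {L1 penalty 10, 30, 50, 70, 90} × {learning rate
0.3, 0.2, 0.1, 0.05}; how the original 57 were chosen from this grid is
not documented, so uniform sampling is the package's choice. Each
configuration is scored by internal 5-fold CV on the training data (AUC
for binary tasks, RMSE for counts) and the winner is refit. "Unbounded"
depth maps to `max_depth=0` under loss-guided growth with the histogram
method, i.e. trees grow until leaves are pure. Boosting runs a fixed 150
rounds (package choice; the round count is not part of the searched
grid).

## Evaluation

Folds are built by assigning whole groups (chromosome, DHS, or target
region) to folds: groups are shuffled with the seed, then placed
largest-first into the currently smallest fold. This guarantees zero
group leakage and approximately balanced folds. AUC is the Mann-Whitney
probability with midrank ties; model families are compared by paired
t-tests across fold-level metrics with Benjamini-Hochberg adjustment
(identical vectors give t = 0, p = 1; a constant nonzero difference has
zero variance and is reported as p = 0 with a warning). Within-DHS
prioritization keeps DHSs with ≥ 3 significant guides (one passage of the
source describes ≥ 1; the threshold is configurable), ranks guides by
predicted probability (ties: larger |log2FC|, then guide id) and compares
top-k vs the remainder on the significant fraction, Wilcoxon rank-sum
tests (exact for ≤ 50 per group, normal approximation above) and third
quartiles of |log2FC|. The fitness/expression association builds a 2×2
table at the gRNA-gene-pair level by default (guide level available),
reports OR = ad/bc with a Haldane-Anscombe 0.5 correction when a cell is
zero (flagged), and a chi-square test without Yates correction by default
(`yates=True` available, since the original software default is
ambiguous). Cross-context transfer scores every (train, test) cell-line
pair on the test context's held-out region-grouped folds, refitting per
fold on the diagonal.

## Interpretation

Tabular attributions use exact TreeSHAP as implemented inside XGBoost
(`pred_contribs`), on the margin scale; per-instance attributions sum to
the margin prediction exactly (tested to 1e-3). Sequence-model
attributions use expected gradients: integrated gradients along the
straight path from each of 100 seed-sampled background instances to the
explained instance, averaged. Because the network is piecewise linear up
to its output, the midpoint quadrature converges at rate 1/steps; the
step count starts at 128 and doubles until per-instance completeness —
attributions sum to f(x) minus the mean background output — holds within
1e-3. Position-resolved summaries average attributions over the explain
set into a 4×20 base-by-position matrix, with mean and standard deviation
across the five folds. The top-6 annotation selection ranks annotation
features by across-fold mean of mean |attribution| computed on training
folds only, freezing the selection before test-fold evaluation; ties
break lexicographically.

## Synthetic screens

The simulator emulates the data layout of a pooled screen: `n_dhs` DHSs
(default 500) with a fixed or Poisson number of guides each (default 10),
a promoter fraction of 0.3, uniform-random protospacers, log-normal
signal-like annotations, normal thermodynamic energies, a Beta-distributed
essentiality proportion and a categorical ploidy, with 5% missingness
injected to exercise imputation. A guide's true-effect probability is
logistic in the base identities at positions 1, 3 and 18 (coefficient 3.0
for guanine) and in two standardized informative annotations (H3K27ac
and ΔG_H, coefficient 2.5, sign flipped for energies so lower ΔG_H means
more effect), intercept −3.5. These effect sizes put the generative model
in a strong-signal regime — Bayes-optimal AUC ≈ 0.95 with ≈ 36% of guides
affected — so that a correct pipeline can demonstrably recover the signal
while a broken one cannot hide behind noise. An alternative `motif` mode
plants a fixed 5-mer (default GCGTA) at a random position in 40% of
guides; presence of the motif anywhere in the protospacer drives the
outcome, probing sensitivity to k-mers longer than the BoW vocabulary.
The remaining guides carry a one-mismatch decoy of the motif at a random
position: without decoys, dinucleotide and trinucleotide composition
alone separates the classes well enough that short-kernel models converge
to near-parity given a long training budget, whereas exact-versus-decoy
discrimination genuinely requires matching the full 5-mer.

Counts are negative binomial with mean 300 and dispersion 0.3
(variance = m + 0.3 m²), typical of screen count data and chosen so the
< 125 total-count filter removes a small but nontrivial minority. Four
wild-type replicates define the abundance target; in the default mode
guanine at position 1 halves the expected wild-type count, in motif mode
the planted 5-mer does. Adjusted p-values are drawn U(0, 0.05) for
true-effect guides and U(0.2, 1) for null guides, with an explicit 10%
borderline fraction drawn U(0.05, 0.2) so the gray-zone exclusion rule is
exercised; |log2FC| is drawn larger for true-effect guides. The
expression task emits a fixed number of gRNA-gene pairs per guide
(default 3) emulating a ±1 Mb neighbourhood.

What the simulator does not model: chromatin-state spatial structure,
correlated annotations along the genome, sequencing-depth variation
between replicates, off-target effects, and the dCas9-KRAB mechanism
itself. Passing recovery tests therefore shows the pipeline is correct
and sensitive under its stated generative assumptions — not that the
published real-data accuracies transfer to any particular screen.

## Problem sizes in tests and the acceptance script

Recovery checks run at roughly 12,000 guides (1,200 DHSs × 10), with one
DHS-grouped fold (~2,000 guides) held out; the permuted-label control
uses 5,000 guides; the kernel-ablation study 4,000 guides (2,000 for
training, best of three restarts per variant); attribution checks explain
12–40 instances against 40–100 backgrounds. These sizes
were chosen so the whole suite trains every model it evaluates on one
CPU in minutes while keeping binomial error bands narrow.

## Known limitations

- ΔG_B is input-only; the ΔG_H nearest-neighbour stand-in ignores
  position-dependent and Cas9-specific contributions.
- The CNN does not bit-reproduce any previously trained weights; only
  the architecture, losses and optimizer settings are fixed.
- The expected-gradients attribution is a quadrature approximation with a
  verified completeness bound, not an exact Shapley computation.
- Real screens arrive with adjusted p-values already computed
  (DESeq2/MAST upstream); the package does not re-derive them from raw
  counts.
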
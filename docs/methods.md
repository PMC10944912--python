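# Methods

## The model

`seqexpress` predicts cell population-specific gene expression from two
inputs per gene: the one-hot encoded DNA sequence of a window anchored at
the transcription start site (default 7,000 bp upstream and 3,500 bp
downstream, so position `up_len` of the window is the TSS base), and five
mRNA half-life covariates derived from transcript structure. A
one-dimensional convolutional network processes the sequence — repeated
(convolution → ReLU → max-pool) blocks — and the flattened convolutional
features are concatenated with the five half-life features before a fully
connected head with linear outputs. The multitask head (one linear layer)
emits one output per cell population of a tissue, so all populations are
predicted simultaneously from shared sequence features; single-task
(tissue-level) models add one hidden layer. Windows of minus-strand genes
are reverse-complemented, so "upstream" always means transcript-upstream
and one orientation convention covers both strands. Ambiguous IUPAC bases
are encoded fractionally (uniform mass over the compatible bases, e.g.
N → 0.25 on each channel), so every column of the 4×L input sums to 1.

The network, its backward pass and the Adam optimizer are implemented
directly in NumPy (`model/layers.py`): same-padding convolution as an
im2col matrix product, non-overlapping max-pooling, inverted dropout.
The backward pass is verified against central-difference numerical
gradients in the test suite (float32 tolerance ~2e-3 relative).

## Targets: pseudobulk expression

Single-cell counts are library-size normalized — counts per million for
Smart-seq2, counts per ten thousand for 10X, TPM (using exonic gene
lengths) for bulk — averaged over the cells of each population, and
log10-transformed without a pseudocount. Genes with zero counts in every
cell of a population have no defined log-mean and receive a fixed sentinel
(default −4; −5 in the deep motor-cortex-style preset) chosen to continue
the low tail of the log-expression distribution; the sentinel is
configurable because its appropriate value depends on sequencing depth.
Each population column is then z-scored over all genes (sentinels
included), and the per-population (mean, sd) pairs are stored so that
predictions are mapped back to the log10 scale before any evaluation or
comparison across populations. All reported correlations are computed on
that unstandardized log scale.

## Half-life covariates

Five features per gene, computed from the representative transcript
(canonical if a mapping is supplied, otherwise the transcript with the
longest summed CDS): 5′ UTR length and 3′ UTR length as exonic (spliced)
distances from the transcript ends to the first/last coding base; ORF
length as the summed CDS length; intron length as the genomic span minus
the three exonic pieces; and exon junction density as exons per kilobase
of ORF. Each feature is log10(x + 0.1)-transformed and z-scored across
genes; the scaler is persisted for reuse on new genes. A zero-variance
feature (possible on toy annotations) is set to 0 with a warning rather
than producing NaNs. The z-scaling statistics are computed over all genes;
computing them on training genes only would change the features by a
per-feature affine map, which the network absorbs, so the distinction is
immaterial to the fitted function.

## Training protocol

Adam on mean-squared error against the standardized targets; initial
learning rate 5e-4, divided by 10 whenever validation loss has not
improved for 5 consecutive epochs; at most 40 epochs; the parameters with
the lowest validation loss are kept (earliest epoch wins ties). Because
training is stochastic, an ensemble of replicates (default 5) is trained
from consecutive seeds and predictions are averaged. Training is fully
deterministic given the seed, which drives initialization, minibatch
shuffling and dropout; two runs with the same configuration reproduce
histories and predictions bit-for-bit on the same hardware. Batch size
defaults to 128; the synthetic benchmarks use 16 because their training
sets are ~100× smaller than a mammalian gene complement and the smaller
batches provide correspondingly more optimizer steps within the fixed
40-epoch budget.

Cross-validation splits genes into k folds (default 20); each fold tests
one block, validates on the next block cyclically, and trains on the rest,
so every gene is tested exactly once and the fold plan is shared across
model variants being compared. A cross-chromosome scheme assigns whole
chromosomes to folds (greedy largest-first balancing) to exclude
within-chromosome leakage.

## Architecture defaults and benchmark sizing

The package-default convolutional trunk follows the Xpresso-lineage
promoter-CNN design: block 1 with 128 filters of width 6 and pool 30,
block 2 with 32 filters of width 9 and pool 10, dropout 0.5 before the
head. Those defaults are appropriate at genome scale (~20k genes, 10.5-kb
windows). The synthetic benchmarks in this repository run at a much
smaller scale (≤1,500 genes, 0.4–2-kb windows), where we found positional
fully connected heads memorize positions instead of learning
translation-invariant motif detectors, and heavy dropout costs substantial
accuracy. The benchmark model configuration is therefore a single
convolution block of width-10 filters with a global max-pool and no
dropout; the 2-kb benchmark uses 96 filters because motif discovery from a
random start is a lottery over initial filters — with fewer filters, one of
the two planted motifs is regularly never found within the fixed 40-epoch
budget — while the 400-bp experiments get away with 32. All of these
choices are plain `ModelConfig` fields, not code paths. An oracle-initialization experiment (planting the consensus as a
filter) confirmed that the training implementation, not the architecture
definition, is what limits cold-start motif discovery at small sample
sizes.

## In-silico saturation mutagenesis

Every window position is substituted to each of the three alternative
bases and re-scored by the full replicate ensemble; half-life features are
held fixed. The effect of a substitution is defined as (mutant prediction
− wild-type prediction) on the unstandardized log10 scale, so positive
means the mutation is predicted to increase expression. (The sign
convention is stated because the opposite one — wild-type minus mutant —
is equally common; all outputs of this package use mutant-minus-wild-type.)
Per position, the substitution with the largest absolute effect summarizes
the profile, with ties broken in fixed A<C<G<T order; averaging that
quantity over a gene set (e.g., highly variable genes, selected upstream)
gives the positional importance profile. Single variants are accepted in
VCF-style 1-based forward-strand coordinates, mapped into the oriented
window (complementing alleles for minus-strand genes), validated against
the genome base, and scored identically; a percentile rank against the
gene's full ISM distribution contextualizes the effect. Positions whose
reference base is ambiguous have no defined "three alternatives" and are
flagged missing. When two populations' profiles are differenced, positions
where the two disagree in sign are masked and reported separately rather
than subtracted.

## The synthetic data generator

The generator emulates a small 10X-like experiment. Latent log10
expression is `y[g,p] = beta0 + sum_k c[g,k]*beta[k,p] + gamma·z[g] +
eps[g,p]`: `c[g,k]` counts planted copies of motif k (consensus strings
written into the window at recorded offsets, in transcript orientation,
on either strand of the genome as the gene's strand dictates),
`beta[k,p]` gives each motif a per-population effect (zeros make it
population-specific), `gamma` weights the gene's z-scored log half-life
features (a shared, population-independent degradation component), and
`eps` is Gaussian noise. Defaults: 1,500 genes on 5 chromosomes, 2-kb
windows (1,500/500), three populations of 80 cells, two
population-specific motifs with effect 0.9 (log10 units), `gamma = (0,
−0.2, −0.3, −0.1, 0.25)`, noise sd 0.25, negative-binomial counts with
dispersion 0.1 around lognormal library sizes centred on 10k. One percent
of genes are silenced in the first population to exercise the sentinel
path. Every gene receives a 1–3-exon transcript with CDS so the half-life
module operates on realistic structures, and outputs are written in the
exact formats the real-data path consumes (FASTA, GTF, MTX, TSV).

What the generator does not emulate: enhancer–promoter looping or any
long-range regulation, chromatin state, batch effects, doublets, ambient
RNA, or realistic motif syntax (density, cooperativity, degenerate
instances). Passing the benchmark therefore demonstrates that the
pipeline recovers planted promoter-proximal signal under controlled
conditions — not that it reaches any particular accuracy on real tissue.

Because library-size normalization only preserves relative abundance,
pseudobulk values recover the latent `y` up to one additive constant per
population; tests and metrics are invariant to that constant.

## Benchmark problem sizes

The end-to-end recovery benchmark trains 2 replicates for 40 epochs on one
20-fold split of the default fixture and evaluates the 75 held-out genes;
ISM motif-recovery metrics are computed on 6 sampled held-out genes that
carry planted motifs (each contributes ~6,000 scored mutants, which is
ample for the site-vs-background contrast). The shuffled-label negative
control averages several independent label permutations: a single
permutation does not concentrate near zero here, because a control model's
half-life pathway still outputs a random projection of five features that
genuinely correlate with expression; averaging permutations estimates the
permutation-null mean, whose expectation is exactly zero. The
resolution-comparison experiment uses a deliberately
population-heterogeneous fixture (motifs with opposite-sign effects in
different populations, so pooled tissue signal partially cancels) at 400-bp
windows, 5 folds, comparing per-population fold-wise correlations of the
multitask population model against broadcast single-task tissue
predictions with a one-sided Wilcoxon rank-sum test.

## Numerical and degenerate-input choices

Pearson correlation returns NaN with a warning on constant input (and
requires n ≥ 3); a gene whose true profile is flat across populations
yields NaN in per-gene correlation rather than an arbitrary number.
Standardization refuses zero-sd columns (degenerate targets). Coordinates
are 0-based half-open internally; GTF input is converted from 1-based
inclusive at the parser boundary, and variant positions are accepted
1-based. Out-of-contig window positions pad with `N` instead of erroring,
keeping gene sets stable near contig ends. Transcript selection ties
(equal summed CDS) break lexicographically by transcript id; checkpoint
selection ties break toward the earliest epoch. Mutant batches in ISM are
evaluated in fixed-size chunks to bound memory.

## Known limitations

- The NumPy training stack is single-device and CPU-oriented; genome-scale
  training (20k genes × 10.5-kb windows × 5 replicates × 20 folds) is
  out of reach at interactive timescales and would motivate a GPU port.
- Alternative TSSs per cell population are not modelled; one transcript
  represents each gene everywhere.
- The ISM percentile rank is within-gene; no cross-gene calibration is
  attempted.
- Bit-level reproducibility holds on one BLAS/hardware configuration;
  across platforms, results agree only to floating-point accumulation
  order.
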
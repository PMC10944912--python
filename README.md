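# seqexpress

Predicting **cell population-specific gene expression from genomic
sequence**. Most sequence-to-expression models (Xpresso, ExPecto and
relatives) are trained on bulk RNA-seq and therefore predict one value per
tissue. `seqexpress` trains on single-cell RNA-seq instead: counts are
aggregated into per-population *pseudobulk* targets, and one multitask
convolutional network predicts the expression of every cell population of
a tissue simultaneously from the DNA sequence around the transcription
start site plus five mRNA half-life covariates. In-silico saturation
mutagenesis of the input window then ranks every possible single-base
substitution by its predicted expression change per population — a way to
prioritize regulatory (e.g., GWAS) variants at cell-population resolution.

The package is aimed at computational biologists who want to train such
models on their own annotated scRNA-seq data, probe what the models
learned, or benchmark the approach end to end on fully synthetic data with
known ground truth.

## The model

For gene *g* and population *p*, the target is the standardized pseudobulk
expression

> t(g, p) = z-score over genes of log10( mean over cells in p of
> library-normalized counts ), with a sentinel (−4 by default) for genes
> detected in no cell of p,

and the prediction is

> ŷ(g, ·) = FC( concat( CNN(one-hot window around TSS_g), h_g ) ),

where the window spans 7 kb upstream to 3.5 kb downstream of the TSS by
default (minus-strand genes reverse-complemented), `h_g` holds the five
half-life covariates (5′ UTR, 3′ UTR, ORF and intron lengths, exon
junction density; log-transformed and z-scored), the CNN is a stack of
convolution → ReLU → max-pool blocks, and the multitask head is a single
linear layer with one output per population. Training minimizes MSE with
Adam (initial learning rate 5e-4, reduced 10× after 5 stagnant epochs, 40
epochs, best-validation checkpoint), and an ensemble of replicate networks
(default 5) is averaged at prediction time. Evaluation is the Pearson
correlation between true and predicted expression on the unstandardized
log10 scale: per population across held-out genes, and per gene across
populations. The network stack (conv/pool/dense layers, backward passes,
Adam) is implemented in NumPy and gradient-checked in the test suite.

See `docs/methods.md` for the full model description, parameter meanings,
defaults, and the design choices behind the synthetic benchmark.

## Worked example

`examples/train_and_evaluate.py` simulates 400 genes with two
population-specific promoter motifs, trains a 2-replicate ensemble on one
cross-validation fold (about a minute on one CPU), and prints:

```
simulated 400 genes, 150 cells, 3 populations

held-out Pearson r on 40 test genes (log10 expression scale):
  pop1: r = 0.722
  pop2: r = 0.813
  pop3: r = 0.871
```

Each r is the correlation between true and predicted log10 pseudobulk
expression over genes the model never saw; values this far above 0 mean
the model recovered the planted motif and half-life signal for that
population.

`examples/ism_and_variants.py` continues into interpretation (about two
minutes): it mutates every window base of held-out genes and checks where
the model is sensitive:

```
ISM localization: mean |effect| inside planted motif sites is 4.2x the background mean
per-motif mean |ISM effect| by population (rows = planted motifs):
              pop1    pop2    pop3
TGACTCAGCG  0.0549  0.0283  0.0392
CACGTGATCC  0.0130  0.2363  0.0129
```

The second motif was planted with an effect only in pop2, and its ISM
effect is ~18× larger there than elsewhere — the model learned a
population-specific regulatory element. The script ends by scoring a
single VCF-style variant inside a planted site, reporting its per-
population effect and its percentile among all 3L possible substitutions
of that gene's window.

The other examples (`pseudobulk_basics.py`, `annotation_and_halflife.py`)
are quick, self-contained walkthroughs of the data layers.

## Command line

A thin CLI wraps the library for shell use:

```bash
seqexpress simulate --seed 1 --out sim/
seqexpress prepare-windows --gtf anno.gtf --fasta genome.fa --up 7000 --down 3500 --out prep/
seqexpress pseudobulk --counts counts.mtx --labels labels.tsv --protocol tenx --sentinel -4 --out pb/
seqexpress run --config experiment.yaml          # full pipeline from one YAML
seqexpress ism --gene GENE --ensemble run/ensemble_fold0 --windows prep/windows.fa --halflife prep/halflife.tsv --out ism/
seqexpress variant-effect --variants vars.tsv --ensemble run/ensemble_fold0 --windows prep/windows.fa --halflife prep/halflife.tsv --out effects.tsv
```

`run` executes prepare → pseudobulk → folds → per-fold ensemble training →
prediction → evaluation and writes every artifact plus a manifest (config
hash, derived seeds, versions) into the run directory.

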
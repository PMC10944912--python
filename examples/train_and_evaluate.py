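"""Train the multitask CNN on simulated data and evaluate held-out genes.

Simulates a small cohort with two population-specific promoter motifs,
aggregates counts into pseudobulk targets, trains a 2-replicate ensemble on
one cross-validation fold, and reports the held-out Pearson correlation per
population. Runs in about a minute on one CPU.
"""

import numpy as np
import pandas as pd

import seqexpress as sx
from seqexpress.model import TrainConfig

cfg = sx.SimConfig(
    n_genes=400, n_chromosomes=4, up_len=450, down_len=150, n_cells=50, seed=1,
)
res = sx.simulate(cfg)
print(f"simulated {cfg.n_genes} genes, {len(res.barcodes)} cells, "
      f"{len(cfg.populations)} populations")

counts = pd.DataFrame(res.counts.toarray(), index=res.gene_ids, columns=res.barcodes)
pb = sx.standardize(
    sx.aggregate(sx.normalize_counts(counts, "tenx"), res.labels["population"])
)
pb_log = pd.DataFrame(
    pb.standardizer.inverse(pb.values.to_numpy()),
    index=pb.values.index, columns=pb.values.columns,
)
hln, _ = sx.normalize_halflife(res.truth.halflife_raw)

plan = sx.make_folds(res.gene_ids, k=10, seed=2)
fold = plan.folds[0]
model_cfg = sx.ModelConfig(
    up_len=cfg.up_len, down_len=cfg.down_len,
    conv_blocks=((32, 10, cfg.up_len + cfg.down_len),),  # near-global pooling
    dropout=0.0, n_tasks=3,
)
ens = sx.train_ensemble(
    sx.make_dataset(res.windows, hln, pb.values, fold.train),
    sx.make_dataset(res.windows, hln, pb.values, fold.validation),
    model_cfg, TrainConfig(batch_size=16),
    task_names=list(pb.values.columns), standardizer=pb.standardizer,
    n_replicates=2, base_seed=3,
)

test = sx.make_dataset(res.windows, hln, None, fold.test)
preds = sx.predict(ens, test.x_seq, test.x_hl, unstandardized=True)
print(f"\nheld-out Pearson r on {len(fold.test)} test genes "
      f"(log10 expression scale):")
for j, pop in enumerate(ens.task_names):
    r = sx.pearson(pb_log.loc[fold.test, pop], preds[:, j])
    print(f"  {pop}: r = {r:.3f}")
print("\nr near 1 means the model recovered the planted motif and half-life")
print("signal for that population; ~0 would mean no sequence-expression link.")
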
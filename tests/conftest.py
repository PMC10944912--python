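import numpy as np
import pandas as pd
import pytest

import seqexpress as sx
from seqexpress.model import TrainConfig


TOY_GTF = """\
chr1\ttest\tgene\t1001\t1300\t.\t+\t.\tgene_id "gA"; gene_name "GENEA";
chr1\ttest\ttranscript\t1001\t1300\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";
chr1\ttest\texon\t1001\t1100\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";
chr1\ttest\texon\t1201\t1300\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";
chr1\ttest\tCDS\t1051\t1100\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";
chr1\ttest\tCDS\t1201\t1250\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";
chr2\ttest\tgene\t501\t900\t.\t-\t.\tgene_id "gB"; gene_name "GENEB";
chr2\ttest\ttranscript\t501\t900\t.\t-\t.\tgene_id "gB"; transcript_id "gB.t1";
chr2\ttest\texon\t501\t900\t.\t-\t.\tgene_id "gB"; transcript_id "gB.t1";
chr2\ttest\tCDS\t601\t800\t.\t-\t.\tgene_id "gB"; transcript_id "gB.t1";
chr2\ttest\tgene\t501\t900\t.\t-\t.\tgene_id "gB2"; gene_name "GENEB2";
chr2\ttest\ttranscript\t501\t900\t.\t-\t.\tgene_id "gB2"; transcript_id "gB2.t1";
chr2\ttest\texon\t501\t900\t.\t-\t.\tgene_id "gB2"; transcript_id "gB2.t1";
chr1\ttest\tgene\t2001\t2200\t.\t+\t.\tgene_id "gNoCds";
chr1\ttest\ttranscript\t2001\t2200\t.\t+\t.\tgene_id "gNoCds"; transcript_id "gNoCds.t1";
chr1\ttest\texon\t2001\t2200\t.\t+\t.\tgene_id "gNoCds"; transcript_id "gNoCds.t1";
chrY\ttest\tgene\t101\t400\t.\t+\t.\tgene_id "gY";
chrY\ttest\ttranscript\t101\t400\t.\t+\t.\tgene_id "gY"; transcript_id "gY.t1";
chrY\ttest\texon\t101\t400\t.\t+\t.\tgene_id "gY"; transcript_id "gY.t1";
chrY\ttest\tCDS\t151\t350\t.\t+\t.\tgene_id "gY"; transcript_id "gY.t1";
"""
# gB2 shares gB's coordinates but has no CDS -> filtered; gB retained.


@pytest.fixture(scope="session")
def toy_gtf(tmp_path_factory):
    path = tmp_path_factory.mktemp("anno") / "toy.gtf"
    path.write_text(TOY_GTF)
    return path


@pytest.fixture(scope="session")
def toy_fasta(tmp_path_factory):
    rng = np.random.default_rng(42)
    path = tmp_path_factory.mktemp("genome") / "toy.fa"
    with open(path, "w") as fh:
        for chrom, n in [("chr1", 4000), ("chr2", 2000), ("chrY", 1000)]:
            fh.write(f">{chrom}\n")
            seq = "".join(rng.choice(list("ACGT"), size=n))
            for i in range(0, n, 80):
                fh.write(seq[i : i + 80] + "\n")
    return path


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulation shared across test modules."""
    cfg = sx.SimConfig(
        n_genes=120, n_chromosomes=4, up_len=300, down_len=100,
        n_cells=30, seed=7,
        motifs=(sx.Motif("TGACTCAGCG", (0.9, 0.0, 0.0)),
                sx.Motif("CACGTGATCC", (0.0, 0.9, 0.0))),
    )
    return cfg, sx.simulate(cfg)


@pytest.fixture(scope="session")
def small_pseudobulk(small_sim):
    cfg, res = small_sim
    counts = pd.DataFrame(
        res.counts.toarray(), index=res.gene_ids, columns=res.barcodes
    )
    pb = sx.standardize(
        sx.aggregate(sx.normalize_counts(counts, "tenx"), res.labels["population"])
    )
    pb_log = pd.DataFrame(
        pb.standardizer.inverse(pb.values.to_numpy()),
        index=pb.values.index, columns=pb.values.columns,
    )
    return pb, pb_log


@pytest.fixture(scope="session")
def small_ensemble(small_sim, small_pseudobulk):
    """A briefly trained 2-replicate ensemble on the small simulation.

    Used where tests need a functioning (not necessarily accurate) model.
    """
    cfg, res = small_sim
    pb, _ = small_pseudobulk
    hln, _ = sx.normalize_halflife(res.truth.halflife_raw)
    gene_ids = res.gene_ids
    ds = sx.make_dataset(res.windows, hln, pb.values, gene_ids)
    tr = ds.subset(np.arange(0, 100))
    va = ds.subset(np.arange(100, 120))
    mc = sx.ModelConfig(
        up_len=300, down_len=100, conv_blocks=((16, 8, 400),),
        dropout=0.0, n_tasks=3, seed=0,
    )
    ens = sx.train_ensemble(
        tr, va, mc, TrainConfig(max_epochs=4, batch_size=16),
        task_names=list(pb.values.columns), standardizer=pb.standardizer,
        n_replicates=2, base_seed=13,
    )
    return ens, hln
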
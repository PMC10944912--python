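"""Parse a toy annotation, extract a TSS window, and compute half-life features.

The five transcript-structure covariates (UTR lengths, ORF length, intron
length, exon junction density) proxy mRNA degradation and enter the model
next to the promoter sequence.
"""

import tempfile
from pathlib import Path

import seqexpress as sx

workdir = Path(tempfile.mkdtemp())
attrs = 'gene_id "demo"; transcript_id "demo.t1";'
(workdir / "toy.gtf").write_text(
    "\n".join(
        [
            f"chr1\tx\ttranscript\t1001\t1300\t.\t+\t.\t{attrs}",
            f"chr1\tx\texon\t1001\t1100\t.\t+\t.\t{attrs}",
            f"chr1\tx\texon\t1201\t1300\t.\t+\t.\t{attrs}",
            f"chr1\tx\tCDS\t1051\t1100\t.\t+\t.\t{attrs}",
            f"chr1\tx\tCDS\t1201\t1250\t.\t+\t.\t{attrs}",
        ]
    )
    + "\n"
)
import numpy as np

rng = np.random.default_rng(0)
contig = "".join(rng.choice(list("ACGT"), size=3000))
(workdir / "toy.fa").write_text(f">chr1\n{contig}\n")

(gene,) = sx.load_genes(workdir / "toy.gtf")
print(f"gene {gene.gene_id}: strand {gene.strand}, TSS at {gene.tss} (0-based)")

window = sx.extract_window(workdir / "toy.fa", gene, up_len=200, down_len=100)
print(f"window length {len(window.seq)} bp; index 200 is the TSS base "
      f"({window.seq[195:206]} around it)")

feats = sx.compute_halflife(gene)
print(
    f"half-life features: 5'UTR {feats.utr5_len:.0f} bp, ORF {feats.orf_len:.0f} bp, "
    f"3'UTR {feats.utr3_len:.0f} bp, introns {feats.intron_len:.0f} bp, "
    f"{feats.exon_junction_density:.1f} exons per kb of ORF"
)
print("(two 100-bp exons, CDS from exonic position 50 to 150: both UTRs 50 bp,")
print(" the 100-bp gap between exons is intronic)")
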
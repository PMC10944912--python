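"""Self-contained synthetic data: toy genome, annotation, and single-cell counts.

The generator plants population-specific transcription-factor-like motifs
inside TSS-anchored promoter windows of a random genome and lets each
gene's latent log10 expression follow

    y[g, p] = beta0 + sum_k c[g, k] * beta[k, p] + gamma . z[g] + eps[g, p]

where ``c[g, k]`` counts planted copies of motif k in gene g's window,
``beta[k, p]`` is the motif's per-population effect (entries of 0 make it
population-specific), ``z[g]`` are the gene's z-scored log half-life
features, and ``eps ~ N(0, sigma^2)``. Per-cell counts are drawn around
``10^y`` scaled by a lognormal library size, under a Poisson or
negative-binomial (gamma-Poisson) count model. Every output is written in
the same formats the real-data path consumes (FASTA, GTF, MTX, TSV), so
the fixtures double as format tests, and everything is fully seeded.

A small fraction of genes is silenced in the first population (zero counts
in every cell) to exercise the pseudobulk sentinel path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .annotation import GeneRecord, SequenceWindow
from .encoding import reverse_complement

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Motif:
    consensus: str  # 8-12 bp, planted verbatim in transcript orientation
    beta: tuple[float, ...]  # per-population effect on log10 expression

    @property
    def target_population(self) -> int:
        return int(np.argmax(np.abs(self.beta)))


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Defaults emulate a small 10X-like experiment: ~1,500 genes with 2-kb
    promoter windows, three populations of 80 cells, two population-specific
    motifs with log10-scale effects of 0.9, residual noise sd 0.25, and
    negative-binomial counts with dispersion 0.1 around lognormal library
    sizes centred on 10k reads per cell.
    """

    n_genes: int = 1500
    n_chromosomes: int = 5
    up_len: int = 1500
    down_len: int = 500
    motifs: tuple[Motif, ...] = (
        Motif("TGACTCAGCG", (0.9, 0.0, 0.0)),
        Motif("CACGTGATCC", (0.0, 0.9, 0.0)),
    )
    placement_rate: float = 0.5  # per-gene probability of carrying each motif
    beta0: float = 1.0  # baseline log10 normalized expression
    # shared (population-independent) half-life contribution: longer ORFs and
    # introns depress expression, junction density raises it — so degradation
    # features carry real signal alongside the planted promoter motifs
    gamma: tuple[float, ...] | None = (0.0, -0.2, -0.3, -0.1, 0.25)
    sigma: float = 0.25  # residual sd, log10 units
    populations: tuple[str, ...] = ("pop1", "pop2", "pop3")
    class_map: dict = field(default_factory=dict)  # population -> parent class
    n_cells: int = 80  # per population
    count_model: str = "negative_binomial"  # or 'poisson'
    dispersion: float = 0.1
    library_size_mean: float = 1e4
    library_size_sigma: float = 0.3  # lognormal sd of log library size
    silent_fraction: float = 0.01  # genes forced to zero counts in populations[0]
    seed: int = 0

    def __post_init__(self) -> None:
        window = self.up_len + self.down_len
        for m in self.motifs:
            if len(m.consensus) >= window:
                raise ValueError(f"motif {m.consensus} longer than the window")
            if len(m.beta) != len(self.populations):
                raise ValueError("motif beta length must match population count")
        if min(self.placement_rate, self.sigma, self.dispersion, 0) < 0:
            raise ValueError("rates must be nonnegative")
        if not self.class_map:
            # default two-class hierarchy: last population its own class
            self.class_map = {
                p: ("classA" if i < len(self.populations) - 1 else "classB")
                for i, p in enumerate(self.populations)
            }


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    y: pd.DataFrame  # genes x populations latent log10 expression
    placements: dict[str, list[tuple[int, int]]]  # gene -> [(motif idx, window offset)]
    copies: pd.DataFrame  # genes x motifs planted copy counts
    halflife_raw: pd.DataFrame
    silent_genes: list[str]  # zero counts forced in populations[0]
    config: SimConfig

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "y": self.y.to_dict(orient="index"),
                    "placements": self.placements,
                    "silent_genes": self.silent_genes,
                },
                sort_keys=True,
            )
        )


@dataclass
class SimResult:
    genes: list[GeneRecord]
    windows: dict[str, SequenceWindow]
    contigs: dict[str, str]
    counts: sp.csr_matrix  # genes x cells
    gene_ids: list[str]
    barcodes: list[str]
    labels: pd.DataFrame  # index barcode; columns population, cls
    truth: SimTruth


def _make_transcript(rng: np.random.Generator) -> tuple[list[tuple[int, int]], int, int]:
    """Random exon chain in span-local coords, plus exonic UTR trims."""
    n_exons = int(rng.integers(1, 4))
    exon_lens = rng.integers(150, 400, size=n_exons)
    intron_lens = rng.integers(200, 800, size=max(0, n_exons - 1))
    exons, pos = [], 0
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + int(el)))
        pos += int(el)
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    exonic = int(exon_lens.sum())
    utr5 = int(rng.integers(20, min(80, exon_lens[0] - 10)))
    utr3 = int(rng.integers(20, min(120, exon_lens[-1] - 10)))
    while exonic - utr5 - utr3 < 30:  # keep a non-trivial ORF
        utr5 = max(5, utr5 // 2)
        utr3 = max(5, utr3 // 2)
    return exons, utr5, utr3


def _trim_exons(exons: list[tuple[int, int]], left: int, right: int) -> list[tuple[int, int]]:
    """CDS intervals: the exon union minus `left`/`right` exonic bases."""
    exonic = sum(e - s for s, e in exons)
    cds = []
    consumed = 0
    for s, e in exons:
        a = max(s, s + (left - consumed))
        consumed += e - s
        b = min(e, e - max(0, right - (exonic - consumed)))
        if b > a:
            cds.append((a, b))
    return cds


def simulate(config: SimConfig | None = None, outdir: str | Path | None = None) -> SimResult:
    """Generate a toy genome + GTF + counts with planted motifs; optionally
    write FASTA/GTF/MTX/TSV files under ``outdir``."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    n_pops = len(config.populations)
    window_len = config.up_len + config.down_len

    genes: list[GeneRecord] = []
    placements: dict[str, list[tuple[int, int]]] = {}
    copies = np.zeros((config.n_genes, len(config.motifs)), dtype=int)
    contig_parts: dict[str, list[str]] = {
        f"chr{i + 1}": [] for i in range(config.n_chromosomes)
    }
    contig_pos = {c: 0 for c in contig_parts}

    max_span = 3 * 400 + 2 * 800  # generous bound from _make_transcript
    slot = config.up_len + config.down_len + max_span + 200

    for g in range(config.n_genes):
        gid = f"g{g:05d}"
        chrom = f"chr{(g % config.n_chromosomes) + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        exons_local, utr5, utr3 = _make_transcript(rng)
        span = exons_local[-1][1]

        base = contig_pos[chrom]
        if strand == "+":
            span_start = base + config.up_len
            exons = [(span_start + s, span_start + e) for s, e in exons_local]
            left, right = utr5, utr3
        else:
            span_end = base + config.down_len + span
            # mirror the local chain so the transcript runs right-to-left
            exons = sorted(
                (span_end - e, span_end - s) for s, e in exons_local
            )
            left, right = utr3, utr5
        cds = _trim_exons(exons, left, right)
        gene = GeneRecord(
            gene_id=gid, gene_name=gid.upper(), chrom=chrom, strand=strand,
            transcript_id=f"{gid}.t1", exons=exons, cds=cds,
        )
        genes.append(gene)

        # background sequence for this gene's slot
        seq = rng.choice(_BASES, size=slot)
        tss_in_slot = gene.tss - base
        win_start = (
            tss_in_slot - config.up_len
            if strand == "+"
            else tss_in_slot - config.down_len + 1
        )

        # plant motifs (transcript orientation), avoiding overlaps
        placements[gid] = []
        occupied: list[tuple[int, int]] = []
        for k, motif in enumerate(config.motifs):
            if rng.random() >= config.placement_rate:
                continue
            mlen = len(motif.consensus)
            for _ in range(20):  # rejection-sample a free offset
                off = int(rng.integers(10, window_len - mlen - 10))
                if all(off + mlen <= a or off >= b for a, b in occupied):
                    break
            else:
                continue
            occupied.append((off, off + mlen))
            if strand == "+":
                gstart = win_start + off
                planted = motif.consensus
            else:
                # window offset i sits at genomic tss + up_len - i
                gend = tss_in_slot + config.up_len - off + 1
                gstart = gend - mlen
                planted = reverse_complement(motif.consensus)
            seq[gstart : gstart + mlen] = list(planted)
            placements[gid].append((k, off))
            copies[g, k] += 1

        contig_parts[chrom].append("".join(seq))
        contig_pos[chrom] += slot

    contigs = {c: "".join(parts) for c, parts in contig_parts.items()}

    # ---- latent expression -------------------------------------------------
    from .halflife import halflife_table

    hl_raw = halflife_table(genes)
    logged = np.log10(hl_raw.to_numpy() + 0.1)
    sds = logged.std(axis=0)
    z = (logged - logged.mean(axis=0)) / np.where(sds == 0, 1.0, sds)
    gamma = np.array(config.gamma) if config.gamma is not None else np.zeros(5)
    betas = np.array([m.beta for m in config.motifs], dtype=float).reshape(
        len(config.motifs), n_pops
    )  # (K, P)
    eps = rng.normal(0.0, config.sigma, size=(config.n_genes, n_pops))
    y = config.beta0 + copies @ betas + (z @ gamma)[:, None] + eps
    gene_ids = [g.gene_id for g in genes]
    y_df = pd.DataFrame(y, index=gene_ids, columns=list(config.populations))

    n_silent = int(round(config.silent_fraction * config.n_genes))
    silent = [gene_ids[i] for i in rng.choice(config.n_genes, n_silent, replace=False)]

    # ---- per-cell counts ---------------------------------------------------
    barcodes, labels_pop = [], []
    blocks = []
    silent_mask = np.isin(gene_ids, silent)
    for p, pop in enumerate(config.populations):
        libs = config.library_size_mean * np.exp(
            rng.normal(0.0, config.library_size_sigma, size=config.n_cells)
        )
        mean_expr = 10.0 ** y[:, p]  # normalized units (per library_size_mean)
        if p == 0:
            mean_expr = np.where(silent_mask, 0.0, mean_expr)
        mu = mean_expr[:, None] * (libs[None, :] / config.library_size_mean)
        if config.count_model == "poisson":
            block = rng.poisson(mu)
        elif config.count_model == "negative_binomial":
            shape = 1.0 / config.dispersion
            lam = rng.gamma(shape, mu * config.dispersion)
            block = rng.poisson(lam)
        else:
            raise ValueError(f"unknown count model {config.count_model!r}")
        blocks.append(sp.csr_matrix(block))
        barcodes += [f"{pop}_cell{j:03d}" for j in range(config.n_cells)]
        labels_pop += [pop] * config.n_cells

    counts = sp.hstack(blocks, format="csr")
    labels = pd.DataFrame(
        {
            "population": labels_pop,
            "cls": [config.class_map[p] for p in labels_pop],
        },
        index=pd.Index(barcodes, name="barcode"),
    )

    windows = {
        g.gene_id: _window_from_contig(contigs[g.chrom], g, config.up_len, config.down_len)
        for g in genes
    }
    truth = SimTruth(
        y=y_df,
        placements=placements,
        copies=pd.DataFrame(copies, index=gene_ids,
                            columns=[m.consensus for m in config.motifs]),
        halflife_raw=hl_raw,
        silent_genes=silent,
        config=config,
    )
    result = SimResult(
        genes=genes, windows=windows, contigs=contigs, counts=counts,
        gene_ids=gene_ids, barcodes=barcodes, labels=labels, truth=truth,
    )
    if outdir is not None:
        write_simulation(result, outdir)
    return result


def _window_from_contig(
    contig: str, gene: GeneRecord, up_len: int, down_len: int
) -> SequenceWindow:
    if gene.strand == "+":
        seq = contig[gene.tss - up_len : gene.tss + down_len]
    else:
        seq = reverse_complement(contig[gene.tss - down_len + 1 : gene.tss + up_len + 1])
    return SequenceWindow(
        gene_id=gene.gene_id, chrom=gene.chrom, strand=gene.strand,
        tss=gene.tss, up_len=up_len, down_len=down_len, seq=seq,
    )


def write_simulation(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write genome.fa, annotation.gtf, counts.mtx (+ manifests), labels.tsv,
    and truth.json; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "gtf": outdir / "annotation.gtf",
        "mtx": outdir / "counts.mtx",
        "genes": outdir / "genes.tsv",
        "barcodes": outdir / "barcodes.tsv",
        "labels": outdir / "labels.tsv",
        "truth": outdir / "truth.json",
    }
    with open(paths["fasta"], "w") as fh:
        for chrom in sorted(result.contigs):
            fh.write(f">{chrom}\n")
            seq = result.contigs[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    with open(paths["gtf"], "w") as fh:
        for g in result.genes:
            attrs = (
                f'gene_id "{g.gene_id}"; transcript_id "{g.transcript_id}"; '
                f'gene_name "{g.gene_name}";'
            )
            span = (g.span_start + 1, g.span_end)
            for ftype, ivals in (
                ("gene", [span]),
                ("transcript", [span]),
                ("exon", [(s + 1, e) for s, e in g.exons]),
                ("CDS", [(s + 1, e) for s, e in g.cds]),
            ):
                for s, e in ivals:
                    fh.write(
                        f"{g.chrom}\tsim\t{ftype}\t{s}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                    )
    sio.mmwrite(str(paths["mtx"]), result.counts.astype(int))
    pd.Series(result.gene_ids).to_csv(paths["genes"], sep="\t", index=False, header=False)
    pd.Series(result.barcodes).to_csv(paths["barcodes"], sep="\t", index=False, header=False)
    result.labels.to_csv(paths["labels"], sep="\t")
    result.truth.to_json(paths["truth"])
    return paths


@dataclass
class BenchmarkReport:
    """Recovery metrics of a trained ensemble against simulation truth."""

    per_population_r: pd.Series  # held-out Pearson per population
    motif_enrichment: float  # mean |effect| in planted sites / background
    motif_population_effects: pd.DataFrame  # motifs x populations, mean |effect|
    n_test_genes: int
    n_ism_genes: int

    def population_specificity_ok(self, config: SimConfig) -> bool:
        """True if each motif's ISM effect is largest in its target population."""
        for k, motif in enumerate(config.motifs):
            row = self.motif_population_effects.iloc[k]
            if int(np.argmax(row.to_numpy())) != motif.target_population:
                return False
        return True


def benchmark_report(
    result: SimResult,
    ensemble,
    pb_log: pd.DataFrame,
    hl_norm: pd.DataFrame,
    test_genes: list[str],
    n_ism_genes: int = 8,
    seed: int = 0,
) -> BenchmarkReport:
    """Held-out prediction accuracy plus ISM motif-recovery metrics.

    ``pb_log`` holds unstandardized log10 pseudobulk targets; predictions are
    compared on the same scale. ISM localization is measured on a seeded
    sample of held-out genes that carry at least one planted motif: the mean
    per-position max-|effect| inside planted sites divided by the background
    mean, pooled over sampled genes; per-motif, per-population mean |effect|
    inside sites checks population specificity.
    """
    from .evaluation import pearson
    from .ism import max_effect_profile, saturation_mutagenesis
    from .model import make_dataset, predict

    truth = result.truth
    missing = set(test_genes) - set(truth.y.index)
    if missing:
        raise ValueError(f"test genes absent from simulation truth: {sorted(missing)[:5]}")
    ds = make_dataset(result.windows, hl_norm, None, gene_ids=test_genes)
    preds = predict(ensemble, ds.x_seq, ds.x_hl, unstandardized=True)
    pops = list(ensemble.task_names)
    r = pd.Series(
        [pearson(pb_log.loc[test_genes, p], preds[:, i]) for i, p in enumerate(pops)],
        index=pops,
        name="pearson_r",
    )

    rng = np.random.default_rng(seed)
    with_motifs = [g for g in test_genes if truth.placements.get(g)]
    sample = list(
        rng.choice(with_motifs, size=min(n_ism_genes, len(with_motifs)), replace=False)
    )
    inside, background = [], []
    motif_effects = np.zeros((len(truth.config.motifs), len(pops)))
    motif_counts = np.zeros(len(truth.config.motifs))
    for g in sample:
        profile = saturation_mutagenesis(ensemble, result.windows[g], hl_norm.loc[g].to_numpy())
        site_mask = np.zeros(profile.length, dtype=bool)
        for k, off in truth.placements[g]:
            mlen = len(truth.config.motifs[k].consensus)
            site_mask[off : off + mlen] = True
            site_abs = np.abs(profile.effects[off : off + mlen])  # (mlen, 3, P)
            motif_effects[k] += np.nanmean(site_abs, axis=(0, 1))
            motif_counts[k] += 1
        pooled = np.nanmean(
            [np.abs(max_effect_profile(profile, p)) for p in pops], axis=0
        )
        inside.append(pooled[site_mask])
        background.append(pooled[~site_mask])
    enrichment = float(
        np.concatenate(inside).mean() / np.concatenate(background).mean()
    )
    motif_effects = motif_effects / np.maximum(motif_counts, 1)[:, None]
    return BenchmarkReport(
        per_population_r=r,
        motif_enrichment=enrichment,
        motif_population_effects=pd.DataFrame(
            motif_effects,
            index=[m.consensus for m in truth.config.motifs],
            columns=pops,
        ),
        n_test_genes=len(test_genes),
        n_ism_genes=len(sample),
    )
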
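"""Gene models from GTF annotation and TSS-anchored sequence windows.

One transcript is resolved per gene (a supplied canonical mapping, falling
back to the transcript with the longest summed coding sequence) and the
transcription start site (TSS) taken from it. Sequence windows are extracted
around the TSS, oriented 5'->3' in the transcript direction: minus-strand
windows are reverse-complemented so that position ``up_len`` is always the
TSS base and lower positions are always transcript-upstream.

Coordinates are 0-based half-open internally; GTF input is read as 1-based
inclusive and converted at the parser boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from pyfaidx import Fasta

from .encoding import reverse_complement

Interval = tuple[int, int]  # [start, end), genomic


class GTFParseError(ValueError):
    """Raised for a structurally malformed GTF line; names the line number."""


class ChromosomeNotFoundError(KeyError):
    """Raised when a gene's chromosome is absent from the FASTA."""


@dataclass
class FilterConfig:
    """Gene-exclusion rules applied by :func:`load_genes`.

    Genes without any coding transcript are always removed. Transgene
    detection is prefix-based because annotations do not flag them uniformly.
    """

    exclude_chroms: tuple[str, ...] = ("chrY", "Y")
    spikein_prefixes: tuple[str, ...] = ("ERCC-",)
    transgene_prefixes: tuple[str, ...] = ()


@dataclass
class GeneRecord:
    """One gene's chosen transcript: TSS, strand, exon/CDS structure."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str  # '+' or '-'
    transcript_id: str
    exons: list[Interval]  # sorted, non-overlapping, genomic coords
    cds: list[Interval]  # sorted, each contained in the exon union

    @property
    def span_start(self) -> int:
        return self.exons[0][0]

    @property
    def span_end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """0-based genomic position of the transcription start site."""
        return self.span_start if self.strand == "+" else self.span_end - 1


@dataclass
class SequenceWindow:
    """TSS-anchored window, oriented 5'->3' in transcript direction.

    Index ``up_len`` within ``seq`` is the TSS base.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    up_len: int
    down_len: int
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) != self.up_len + self.down_len:
            raise ValueError(
                f"window for {self.gene_id} has length {len(self.seq)}, "
                f"expected {self.up_len + self.down_len}"
            )


def _validate_gtf(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GTFParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GTFParseError(f"line {lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise GTFParseError(
                    f"line {lineno}: invalid 1-based interval [{start}, {end}]"
                )


def _read_canonical_map(source) -> dict[str, str]:
    if source is None:
        return {}
    if isinstance(source, dict):
        return dict(source)
    df = pd.read_csv(source, sep="\t", header=None, comment="#", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def load_genes(
    gtf_source: str | Path,
    exclude: FilterConfig | None = None,
    canonical_map: dict[str, str] | str | Path | None = None,
) -> list[GeneRecord]:
    """Parse a GTF and return one :class:`GeneRecord` per retained gene.

    Filters follow the promoter-model convention: genes with no coding
    region on any transcript, genes on the Y chromosome, ERCC spike-ins and
    configured transgene IDs are dropped. The representative transcript is
    the canonical-map entry when present (with a warning + longest-CDS
    fallback if the named transcript is absent), otherwise the transcript
    with the largest summed CDS length (ties broken by transcript_id).
    """
    exclude = exclude or FilterConfig()
    canonical = _read_canonical_map(canonical_map)
    _validate_gtf(gtf_source)
    db = gffutils.create_db(
        str(gtf_source),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    # gene_id -> transcript_id -> {"exons": [...], "cds": [...], meta}
    transcripts: dict[str, dict[str, dict]] = {}
    meta: dict[str, dict] = {}
    for t in db.features_of_type("transcript"):
        gid = t.attributes["gene_id"][0]
        tid = t.attributes["transcript_id"][0]
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(t, featuretype="exon")
        )
        cds = sorted((f.start - 1, f.end) for f in db.children(t, featuretype="CDS"))
        transcripts.setdefault(gid, {})[tid] = {"exons": exons, "cds": cds}
        name = t.attributes.get("gene_name", [gid])[0]
        meta[gid] = {"chrom": t.seqid, "strand": t.strand, "gene_name": name}

    records: list[GeneRecord] = []
    for gid, tdict in transcripts.items():
        m = meta[gid]
        if m["chrom"] in exclude.exclude_chroms:
            continue
        if any(gid.startswith(p) for p in exclude.spikein_prefixes):
            continue
        if any(gid.startswith(p) for p in exclude.transgene_prefixes):
            continue
        coding = {tid: t for tid, t in tdict.items() if t["cds"]}
        if not coding:
            continue

        tid = canonical.get(gid)
        if tid is not None and tid not in coding:
            warnings.warn(
                f"canonical transcript {tid} for gene {gid} not found (or has no "
                f"CDS); falling back to longest-CDS transcript",
                stacklevel=2,
            )
            tid = None
        if tid is None:
            # longest summed CDS; lexicographic transcript_id breaks ties
            tid = min(
                coding,
                key=lambda t: (-sum(e - s for s, e in coding[t]["cds"]), t),
            )
        chosen = coding[tid]
        records.append(
            GeneRecord(
                gene_id=gid,
                gene_name=m["gene_name"],
                chrom=m["chrom"],
                strand=m["strand"],
                transcript_id=tid,
                exons=chosen["exons"],
                cds=chosen["cds"],
            )
        )
    return records


def _fetch_padded(contig_seq: str, start: int, end: int) -> str:
    """Slice [start, end) from a contig, padding out-of-bounds with 'N'."""
    n = len(contig_seq)
    left = "N" * max(0, -start)
    right = "N" * max(0, end - n)
    return left + contig_seq[max(0, start) : min(n, end)] + right


def extract_window(
    genome: Fasta | str | Path,
    gene: GeneRecord,
    up_len: int = 7000,
    down_len: int = 3500,
) -> SequenceWindow:
    """Extract the TSS-anchored window for one gene, transcript-oriented.

    Plus-strand genes read the genomic interval ``[tss - up_len, tss +
    down_len)`` forward; minus-strand genes read ``[tss - down_len + 1,
    tss + up_len + 1)`` and reverse-complement it. Positions beyond the
    contig ends are filled with 'N'.
    """
    if not isinstance(genome, Fasta):
        genome = Fasta(str(genome))
    if gene.chrom not in genome:
        raise ChromosomeNotFoundError(
            f"chromosome {gene.chrom!r} (gene {gene.gene_id}) not in FASTA"
        )
    contig = str(genome[gene.chrom][:])
    if gene.strand == "+":
        seq = _fetch_padded(contig, gene.tss - up_len, gene.tss + down_len)
    else:
        fwd = _fetch_padded(contig, gene.tss - down_len + 1, gene.tss + up_len + 1)
        seq = reverse_complement(fwd)
    return SequenceWindow(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=gene.strand,
        tss=gene.tss,
        up_len=up_len,
        down_len=down_len,
        seq=seq,
    )


def write_windows_fasta(windows: list[SequenceWindow], path: str | Path) -> None:
    """Write windows as FASTA with headers ``gene_id|chrom|strand|tss``."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.gene_id}|{w.chrom}|{w.strand}|{w.tss}\n")
            for i in range(0, len(w.seq), 80):
                fh.write(w.seq[i : i + 80] + "\n")


def read_windows_fasta(
    path: str | Path, up_len: int, down_len: int
) -> list[SequenceWindow]:
    """Read windows written by :func:`write_windows_fasta`."""
    windows = []
    fa = Fasta(str(path))
    for name in fa.keys():
        gene_id, chrom, strand, tss = name.split("|")
        windows.append(
            SequenceWindow(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                tss=int(tss),
                up_len=up_len,
                down_len=down_len,
                seq=str(fa[name][:]),
            )
        )
    return windows
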
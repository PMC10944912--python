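"""mRNA half-life proxy features from transcript structure.

Five covariates that track mRNA stability are computed per gene from its
representative transcript: 5' UTR length, 3' UTR length, ORF length, intron
length, and exon junction density (exons per kb of ORF). UTR lengths are
exonic (spliced) distances, so UTRs spanning several exons sum their exonic
pieces; intron length is the genomic span minus the three exonic pieces.
Features are log10(x + 0.1)-transformed and z-scaled before entering the
model; the per-feature (mean, sd) pairs are retained so the same scaling can
be applied to new genes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneRecord

FEATURE_NAMES = ("utr5_len", "utr3_len", "orf_len", "intron_len", "exon_junction_density")


@dataclass
class HalfLifeFeatures:
    gene_id: str
    utr5_len: float
    utr3_len: float
    orf_len: float
    intron_len: float
    exon_junction_density: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [getattr(self, n) for n in FEATURE_NAMES], dtype=np.float64
        )


def _exonic_length_between(exons, start: int, end: int) -> int:
    """Total exonic bases of [start, end) intersected with the exon union."""
    total = 0
    for s, e in exons:
        total += max(0, min(e, end) - max(s, start))
    return total


def compute_halflife(gene: GeneRecord) -> HalfLifeFeatures:
    """Raw half-life features for one coding gene.

    Strand-aware: the 5' UTR is measured from the transcript 5' end to the
    first coding base in transcript orientation, regardless of genomic
    strand, so mirrored annotations on opposite strands give identical
    features.
    """
    if not gene.cds:
        raise ValueError(f"gene {gene.gene_id} has no CDS; should have been filtered")
    exons = gene.exons
    cds_start = gene.cds[0][0]  # leftmost coding base (genomic)
    cds_end = gene.cds[-1][1]  # one past rightmost coding base
    orf_len = sum(e - s for s, e in gene.cds)
    left_utr = _exonic_length_between(exons, gene.span_start, cds_start)
    right_utr = _exonic_length_between(exons, cds_end, gene.span_end)
    if gene.strand == "+":
        utr5, utr3 = left_utr, right_utr
    else:
        utr5, utr3 = right_utr, left_utr
    span_len = gene.span_end - gene.span_start
    intron_len = span_len - orf_len - utr5 - utr3
    density = len(exons) / orf_len * 1000.0
    return HalfLifeFeatures(
        gene_id=gene.gene_id,
        utr5_len=float(utr5),
        utr3_len=float(utr3),
        orf_len=float(orf_len),
        intron_len=float(intron_len),
        exon_junction_density=density,
    )


def halflife_table(genes: list[GeneRecord]) -> pd.DataFrame:
    """Raw feature table (genes x 5), indexed by gene_id."""
    rows = [compute_halflife(g).as_array() for g in genes]
    return pd.DataFrame(
        rows, index=[g.gene_id for g in genes], columns=list(FEATURE_NAMES)
    )


@dataclass
class HalfLifeScaler:
    """Per-feature (mean, sd) of the log-transformed features."""

    means: np.ndarray
    sds: np.ndarray

    def transform(self, raw: pd.DataFrame) -> pd.DataFrame:
        logged = np.log10(raw.to_numpy(dtype=np.float64) + 0.1)
        z = (logged - self.means) / np.where(self.sds == 0.0, 1.0, self.sds)
        z[:, self.sds == 0.0] = 0.0
        return pd.DataFrame(z, index=raw.index, columns=raw.columns)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"means": self.means.tolist(), "sds": self.sds.tolist()})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "HalfLifeScaler":
        d = json.loads(Path(path).read_text())
        return cls(means=np.array(d["means"]), sds=np.array(d["sds"]))


def normalize_halflife(raw: pd.DataFrame) -> tuple[pd.DataFrame, HalfLifeScaler]:
    """log10(x + 0.1) then per-feature z-score; returns table and scaler.

    A feature whose log-transformed values have zero variance is set to 0
    for every gene, with a warning (degenerate on toy annotations).
    """
    if raw.empty:
        raise ValueError("feature table is empty")
    logged = np.log10(raw.to_numpy(dtype=np.float64) + 0.1)
    means = logged.mean(axis=0)
    sds = logged.std(axis=0)  # population sd, matching the target z-score
    if (sds == 0.0).any():
        flat = [c for c, s in zip(raw.columns, sds) if s == 0.0]
        warnings.warn(
            f"zero-variance half-life feature(s) {flat}; set to 0 for all genes",
            stacklevel=2,
        )
    scaler = HalfLifeScaler(means=means, sds=sds)
    return scaler.transform(raw), scaler
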
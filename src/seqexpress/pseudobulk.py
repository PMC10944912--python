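"""Pseudobulk targets: per-population log-mean expression, standardized invertibly.

Single-cell counts are library-size normalized (counts per million for
Smart-seq2, counts per ten thousand for 10X; TPM for bulk), averaged over
the cells of each population, and log10-transformed without pseudocount.
Genes with zero counts in every cell of a population have no defined
log-mean; they receive a fixed sentinel value (-4 for Tabula-Muris-like
depth, -5 for the deeper motor-cortex-like data) chosen to extrapolate the
low tail of the distribution. Each population column is then z-scored over
all genes (sentinels included); the (mean, sd) pairs are stored so model
outputs can be mapped back to the log scale exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

PROTOCOL_SCALE = {"smartseq2": 1e6, "tenx": 1e4}


@dataclass
class Standardizer:
    """Per-population (mean, sd) used to z-score and invert predictions."""

    means: np.ndarray  # (P,)
    sds: np.ndarray  # (P,)
    populations: list[str]

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.means) / self.sds

    def inverse(self, values: np.ndarray) -> np.ndarray:
        return values * self.sds + self.means

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "means": self.means.tolist(),
                    "sds": self.sds.tolist(),
                    "populations": list(self.populations),
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Standardizer":
        d = json.loads(Path(path).read_text())
        return cls(
            means=np.array(d["means"]),
            sds=np.array(d["sds"]),
            populations=list(d["populations"]),
        )

    @classmethod
    def identity(cls, populations: list[str]) -> "Standardizer":
        p = len(populations)
        return cls(means=np.zeros(p), sds=np.ones(p), populations=list(populations))


@dataclass
class PseudobulkMatrix:
    """Genes x populations log10 expression with sentinel bookkeeping."""

    values: pd.DataFrame  # genes x populations, log10 scale (or z-scored)
    sentinel: float
    zero_mask: pd.DataFrame  # True where the gene had zero counts in the population
    standardizer: Standardizer | None = None  # set once standardized

    @property
    def populations(self) -> list[str]:
        return list(self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


def normalize_counts(
    counts,
    protocol: str,
    gene_lengths: pd.Series | None = None,
    gene_ids: list[str] | None = None,
    cell_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Library-size normalize a genes x cells count matrix.

    ``smartseq2`` scales each cell to 1e6 total (CPM), ``tenx`` to 1e4,
    ``bulk`` computes TPM using exonic gene lengths. Cells (or samples) with
    zero total counts are dropped with a warning.
    """
    if isinstance(counts, pd.DataFrame):
        mat = counts.to_numpy(dtype=np.float64)
        gene_ids = list(counts.index)
        cell_ids = list(counts.columns)
    else:
        mat = (
            counts.toarray().astype(np.float64)
            if sp.issparse(counts)
            else np.asarray(counts, dtype=np.float64)
        )
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(mat.shape[0])]
        if cell_ids is None:
            cell_ids = [f"c{j}" for j in range(mat.shape[1])]
    if (mat < 0).any():
        raise ValueError("counts must be nonnegative")

    if protocol == "bulk":
        if gene_lengths is None:
            raise ValueError("bulk protocol requires exonic gene lengths for TPM")
        lengths = gene_lengths.reindex(gene_ids).to_numpy(dtype=np.float64)
        if np.isnan(lengths).any():
            missing = [g for g, l in zip(gene_ids, lengths) if np.isnan(l)]
            raise ValueError(f"missing gene lengths for {missing[:5]}...")
        mat = mat / lengths[:, None]  # reads per base
        scale = 1e6
    elif protocol in PROTOCOL_SCALE:
        scale = PROTOCOL_SCALE[protocol]
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    totals = mat.sum(axis=0)
    keep = totals > 0
    if not keep.all():
        dropped = [c for c, k in zip(cell_ids, keep) if not k]
        warnings.warn(f"dropping {len(dropped)} zero-total column(s): {dropped[:5]}",
                      stacklevel=2)
        mat = mat[:, keep]
        cell_ids = [c for c, k in zip(cell_ids, keep) if k]
        totals = totals[keep]
    return pd.DataFrame(mat / totals * scale, index=gene_ids, columns=cell_ids)


def aggregate(
    normalized: pd.DataFrame,
    labels: pd.Series | dict,
    sentinel: float = -4.0,
) -> PseudobulkMatrix:
    """Aggregate normalized expression into log10 pseudobulk per population.

    values[g, p] = log10(mean over cells of population p), no pseudocount;
    all-zero genes in a population get ``sentinel`` and are flagged in
    ``zero_mask``. Bulk data aggregates over samples the same way.
    """
    labels = pd.Series(labels)
    unlabeled = [c for c in normalized.columns if c not in labels.index]
    if unlabeled:
        raise ValueError(f"unlabeled cells: {unlabeled[:5]}")
    labels = labels.reindex(normalized.columns)
    pops = sorted(labels.unique())
    values = {}
    mask = {}
    for p in pops:
        cells = labels.index[labels == p]
        if len(cells) == 0:
            raise ValueError(f"population {p!r} has no cells")
        mean = normalized[cells].mean(axis=1)
        zero = mean == 0.0
        with np.errstate(divide="ignore"):
            logged = np.log10(mean.to_numpy())
        logged[zero.to_numpy()] = sentinel
        values[p] = logged
        mask[p] = zero.to_numpy()
    return PseudobulkMatrix(
        values=pd.DataFrame(values, index=normalized.index),
        sentinel=sentinel,
        zero_mask=pd.DataFrame(mask, index=normalized.index),
    )


def standardize(pb: PseudobulkMatrix) -> PseudobulkMatrix:
    """Z-score each population column over all genes; stores the standardizer."""
    vals = pb.values.to_numpy(dtype=np.float64)
    if vals.shape[0] < 2:
        raise ValueError("need >= 2 genes per population to standardize")
    means = vals.mean(axis=0)
    sds = vals.std(axis=0)
    if (sds == 0.0).any():
        flat = [c for c, s in zip(pb.values.columns, sds) if s == 0.0]
        raise ValueError(f"degenerate target: zero sd in population(s) {flat}")
    std = Standardizer(means=means, sds=sds, populations=list(pb.values.columns))
    return PseudobulkMatrix(
        values=pd.DataFrame(
            std.transform(vals), index=pb.values.index, columns=pb.values.columns
        ),
        sentinel=pb.sentinel,
        zero_mask=pb.zero_mask,
        standardizer=std,
    )


def un_standardize(pb: PseudobulkMatrix) -> PseudobulkMatrix:
    """Invert :func:`standardize`, restoring the log10-scale values."""
    if pb.standardizer is None:
        raise ValueError("matrix has no stored standardizer")
    vals = pb.standardizer.inverse(pb.values.to_numpy(dtype=np.float64))
    return PseudobulkMatrix(
        values=pd.DataFrame(vals, index=pb.values.index, columns=pb.values.columns),
        sentinel=pb.sentinel,
        zero_mask=pb.zero_mask,
        standardizer=None,
    )


def read_counts_mtx(mtx: str | Path, genes_tsv: str | Path, barcodes_tsv: str | Path):
    """Read an MTX count matrix plus gene/barcode manifests (genes x cells)."""
    import scipy.io as sio

    mat = sio.mmread(str(mtx)).tocsr()
    genes = pd.read_csv(genes_tsv, sep="\t", header=None).iloc[:, 0].tolist()
    cells = pd.read_csv(barcodes_tsv, sep="\t", header=None).iloc[:, 0].tolist()
    if mat.shape != (len(genes), len(cells)):
        raise ValueError(
            f"MTX shape {mat.shape} does not match {len(genes)} genes x {len(cells)} cells"
        )
    return mat, genes, cells
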
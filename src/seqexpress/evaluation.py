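"""Cross-validation folds, performance metrics, and model comparison.

Genes are split into k folds (default 20); each fold's test set is one
block, its validation set the next block cyclically, and the remaining
genes form the training set, so the three sets are disjoint and every gene
is tested exactly once across folds. A cross-chromosome scheme assigns
whole chromosomes to folds (greedy largest-first balancing by gene count)
to rule out within-chromosome leakage.

Performance is the Pearson correlation between true and predicted
expression, computed on the unstandardized log scale: per population over
the test genes of each fold, and per gene across populations. The gain of
a population-resolution model over a tissue-resolution one is the
difference of fold-median correlations per population; significance across
folds uses the one-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class Fold:
    train: list[str]
    validation: list[str]
    test: list[str]


@dataclass
class FoldPlan:
    k: int
    scheme: str  # 'random_gene' or 'cross_chromosome'
    seed: int
    folds: list[Fold]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "k": self.k,
                    "scheme": self.scheme,
                    "seed": self.seed,
                    "folds": [
                        {"train": f.train, "validation": f.validation, "test": f.test}
                        for f in self.folds
                    ],
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FoldPlan":
        d = json.loads(Path(path).read_text())
        return cls(
            k=d["k"],
            scheme=d["scheme"],
            seed=d["seed"],
            folds=[Fold(f["train"], f["validation"], f["test"]) for f in d["folds"]],
        )


def make_folds(
    genes,
    k: int = 20,
    scheme: str = "random_gene",
    seed: int = 0,
) -> FoldPlan:
    """Build a k-fold plan over genes.

    ``genes`` is a list of gene ids (random_gene scheme) or a mapping /
    DataFrame giving each gene's chromosome (required for cross_chromosome).
    """
    if isinstance(genes, pd.DataFrame):
        gene_ids = list(genes.index)
        chroms = genes.iloc[:, 0].to_dict() if genes.shape[1] else None
    elif isinstance(genes, dict):
        gene_ids = list(genes)
        chroms = dict(genes)
    else:
        gene_ids = list(genes)
        chroms = None

    rng = np.random.default_rng(seed)
    if scheme == "random_gene":
        if len(gene_ids) < k:
            raise ValueError(f"need >= {k} genes for {k} folds, got {len(gene_ids)}")
        order = [gene_ids[i] for i in rng.permutation(len(gene_ids))]
        blocks = [list(b) for b in np.array_split(order, k)]
    elif scheme == "cross_chromosome":
        if chroms is None:
            raise ValueError("cross_chromosome scheme requires gene -> chromosome map")
        by_chrom: dict[str, list[str]] = {}
        for g in gene_ids:
            by_chrom.setdefault(chroms[g], []).append(g)
        if len(by_chrom) < k:
            raise ValueError(
                f"only {len(by_chrom)} chromosomes for {k} bins; use a smaller k"
            )
        # greedy largest-first bin packing, balancing gene counts
        bins: list[list[str]] = [[] for _ in range(k)]
        sizes = np.zeros(k, dtype=int)
        for chrom in sorted(by_chrom, key=lambda c: (-len(by_chrom[c]), c)):
            j = int(np.argmin(sizes))
            bins[j].extend(sorted(by_chrom[chrom]))
            sizes[j] += len(by_chrom[chrom])
        blocks = bins
    else:
        raise ValueError(f"unknown fold scheme {scheme!r}")

    folds = []
    for i in range(k):
        test = blocks[i]
        val = blocks[(i + 1) % k]
        trainset = [g for j, b in enumerate(blocks) if j not in (i, (i + 1) % k) for g in b]
        folds.append(Fold(train=trainset, validation=val, test=test))
    return FoldPlan(k=k, scheme=scheme, seed=seed, folds=folds)


def pearson(true, pred) -> float:
    """Pearson correlation; NaN (with a warning) on constant input."""
    true = np.asarray(true, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    if true.shape != pred.shape or true.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    if true.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(true) == 0.0 or np.ptp(pred) == 0.0:
        warnings.warn("Pearson undefined for constant input", stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(true, pred).statistic)


def per_gene_correlation(true: pd.DataFrame, pred: pd.DataFrame) -> pd.Series:
    """Row-wise Pearson across populations, on the unstandardized log scale."""
    if true.shape[1] < 3:
        raise ValueError("need >= 3 populations for per-gene correlation")
    pred = pred.loc[true.index, true.columns]
    t = true.to_numpy(dtype=np.float64)
    p = pred.to_numpy(dtype=np.float64)
    tc = t - t.mean(axis=1, keepdims=True)
    pc = p - p.mean(axis=1, keepdims=True)
    num = (tc * pc).sum(axis=1)
    den = np.sqrt((tc**2).sum(axis=1) * (pc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, np.nan)
    return pd.Series(r, index=true.index, name="pearson_r")


@dataclass
class PerformanceReport:
    """Fold-wise Pearson per population, long format + fold-median summary."""

    per_fold: pd.DataFrame  # columns: population, fold, r

    def median_by_population(self) -> pd.Series:
        return self.per_fold.groupby("population")["r"].median()

    def to_tsv(self, path: str | Path) -> None:
        self.per_fold.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_records(cls, records: list[dict]) -> "PerformanceReport":
        return cls(per_fold=pd.DataFrame(records, columns=["population", "fold", "r"]))


def delta_cp_t(cp_report: PerformanceReport, t_report: PerformanceReport) -> pd.Series:
    """Per-population gain: fold-median r of the cell-population model minus
    the fold-median r of the tissue model (the tissue model contributes the
    same median to every population)."""
    cp_folds = set(cp_report.per_fold["fold"])
    if cp_folds != set(t_report.per_fold["fold"]):
        raise ValueError("reports cover different folds")
    cp_med = cp_report.median_by_population()
    t_med = t_report.median_by_population()
    if len(t_med) == 1:
        t_med = pd.Series(t_med.iloc[0], index=cp_med.index)
    elif set(t_med.index) != set(cp_med.index):
        raise ValueError("reports cover different populations")
    return (cp_med - t_med).rename("delta")


def compare_models(
    report_a: PerformanceReport,
    report_b: PerformanceReport,
    alternative: str = "greater",
) -> float:
    """One-sided Wilcoxon rank-sum p-value that model A's fold-wise r exceeds
    model B's (pooled over populations)."""
    ra = report_a.per_fold["r"].to_numpy()
    rb = report_b.per_fold["r"].to_numpy()
    return float(stats.ranksums(ra, rb, alternative=alternative).pvalue)


def broadcast_parent_predictions(
    parent_pred: pd.DataFrame, hierarchy: dict[str, str]
) -> pd.DataFrame:
    """Copy each parent-class prediction column to its child populations.

    A tissue-level model is the single-parent special case. Raises KeyError
    for a child whose parent has no prediction column.
    """
    cols = {}
    for child, parent in hierarchy.items():
        if parent not in parent_pred.columns:
            raise KeyError(f"child {child!r} has no parent column {parent!r}")
        cols[child] = parent_pred[parent].to_numpy()
    return pd.DataFrame(cols, index=parent_pred.index)
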
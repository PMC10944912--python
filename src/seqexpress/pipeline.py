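"""End-to-end experiment orchestration from a single configuration.

One :class:`RunConfig` names the inputs (genome, GTF, counts, labels), the
target resolution (tissue / class / population), the model and training
hyperparameters, and a global seed; :func:`run_experiment` executes
prepare -> pseudobulk -> folds -> per-fold ensemble training -> prediction
-> evaluation, writing every intermediate artifact plus a manifest to the
run directory. Stage seeds are derived deterministically from the global
seed, so a rerun with the same config reproduces every output; completed
stages whose outputs are already on disk are reused.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import FilterConfig, extract_window, load_genes
from .evaluation import FoldPlan, PerformanceReport, make_folds, pearson
from .halflife import halflife_table, normalize_halflife
from .model import (
    ModelConfig,
    ModelEnsemble,
    TrainConfig,
    make_dataset,
    predict,
    train_ensemble,
)
from .pseudobulk import (
    PseudobulkMatrix,
    aggregate,
    normalize_counts,
    read_counts_mtx,
    standardize,
)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (zlib.crc32(f"{stage}:{global_seed}".encode()) ^ global_seed) % (2**31)


@dataclass
class RunConfig:
    genome: str
    gtf: str
    labels: str
    counts_mtx: str | None = None
    genes_tsv: str | None = None
    barcodes_tsv: str | None = None
    counts_csv: str | None = None
    canonical_map: str | None = None
    protocol: str = "tenx"
    sentinel: float = -4.0
    up_len: int = 7000
    down_len: int = 3500
    resolution: str = "population"  # 'tissue' | 'class' | 'population'
    label_columns: dict = field(
        default_factory=lambda: {"population": "population", "class": "cls"}
    )
    model: dict = field(default_factory=dict)  # ModelConfig overrides
    train: dict = field(default_factory=dict)  # TrainConfig overrides
    k_folds: int = 20
    fold_scheme: str = "random_gene"
    folds_to_run: list[int] | None = None  # None = all
    n_replicates: int = 5
    save_ensembles: bool = False
    outdir: str = "run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return f"{zlib.crc32(json.dumps(self.to_dict(), sort_keys=True).encode()):08x}"


def _load_counts(config: RunConfig):
    if config.counts_csv:
        df = pd.read_csv(config.counts_csv, sep=None, engine="python", index_col=0)
        return df
    if not (config.counts_mtx and config.genes_tsv and config.barcodes_tsv):
        raise ValueError("provide counts_csv or counts_mtx + genes_tsv + barcodes_tsv")
    mat, genes, cells = read_counts_mtx(
        config.counts_mtx, config.genes_tsv, config.barcodes_tsv
    )
    return pd.DataFrame(mat.toarray(), index=genes, columns=cells)


def _resolve_labels(config: RunConfig, cells) -> pd.Series:
    labels = pd.read_csv(config.labels, sep="\t", index_col=0)
    if config.resolution == "tissue":
        return pd.Series("tissue", index=cells)
    col = config.label_columns.get(
        "class" if config.resolution == "class" else "population"
    )
    if col not in labels.columns:
        raise ValueError(f"label column {col!r} not in {list(labels.columns)}")
    return labels[col].reindex(cells)


def run_experiment(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    # ---- stage: prepare (annotation, windows, half-life) -------------------
    genes = load_genes(config.gtf, FilterConfig(), config.canonical_map)
    windows = {
        g.gene_id: extract_window(config.genome, g, config.up_len, config.down_len)
        for g in genes
    }
    hl_raw = halflife_table(genes)
    hl_norm, hl_scaler = normalize_halflife(hl_raw)
    hl_raw.join(hl_norm, rsuffix="_z").to_csv(out / "halflife.tsv", sep="\t")
    hl_scaler.to_json(out / "halflife_scaler.json")

    # ---- stage: pseudobulk -------------------------------------------------
    counts = _load_counts(config)
    labels = _resolve_labels(config, counts.columns)
    if labels.isna().any():
        raise ValueError("some cells are missing labels")
    gene_lengths = pd.Series(
        {g.gene_id: float(sum(e - s for s, e in g.exons)) for g in genes}
    )
    normalized = normalize_counts(
        counts, config.protocol,
        gene_lengths=gene_lengths if config.protocol == "bulk" else None,
    )
    pb = standardize(aggregate(normalized, labels, sentinel=config.sentinel))
    pb_log = pb.standardizer.inverse(pb.values.to_numpy())
    pb_log = pd.DataFrame(pb_log, index=pb.values.index, columns=pb.values.columns)
    pb_log.to_csv(out / "pseudobulk.tsv", sep="\t")
    pb.standardizer.to_json(out / "standardizer.json")

    gene_ids = [g.gene_id for g in genes if g.gene_id in pb.values.index]

    # ---- stage: folds ------------------------------------------------------
    fold_file = out / "folds.json"
    if fold_file.exists():
        plan = FoldPlan.from_json(fold_file)
    else:
        gene_arg = (
            {g.gene_id: g.chrom for g in genes if g.gene_id in set(gene_ids)}
            if config.fold_scheme == "cross_chromosome"
            else gene_ids
        )
        plan = make_folds(
            gene_arg, k=config.k_folds, scheme=config.fold_scheme,
            seed=stage_seed(config.seed, "folds"),
        )
        plan.to_json(fold_file)

    # ---- stage: train + predict per fold -----------------------------------
    model_cfg = ModelConfig(
        up_len=config.up_len, down_len=config.down_len,
        n_tasks=pb.values.shape[1], **config.model,
    )
    train_cfg = TrainConfig(**config.train)
    pops = list(pb.values.columns)
    fold_ids = config.folds_to_run or list(range(plan.k))
    pred_rows = []
    records = []
    for fold_id in fold_ids:
        fold = plan.folds[fold_id]
        ens_dir = out / f"ensemble_fold{fold_id}"
        if config.save_ensembles and (ens_dir / "ensemble.json").exists():
            ensemble = ModelEnsemble.load(ens_dir)
        else:
            train_ds = make_dataset(windows, hl_norm, pb.values, fold.train)
            val_ds = make_dataset(windows, hl_norm, pb.values, fold.validation)
            ensemble = train_ensemble(
                train_ds, val_ds, model_cfg, train_cfg,
                task_names=pops, standardizer=pb.standardizer,
                n_replicates=config.n_replicates,
                base_seed=stage_seed(config.seed, f"train_fold{fold_id}"),
            )
            if config.save_ensembles:
                ensemble.save(ens_dir)
        test_ds = make_dataset(windows, hl_norm, None, fold.test)
        preds = predict(ensemble, test_ds.x_seq, test_ds.x_hl, unstandardized=True)
        for i, g in enumerate(fold.test):
            pred_rows.append({"gene_id": g, "fold": fold_id,
                              **{p: preds[i, j] for j, p in enumerate(pops)}})
        for j, p in enumerate(pops):
            records.append(
                {"population": p, "fold": fold_id,
                 "r": pearson(pb_log.loc[fold.test, p].to_numpy(), preds[:, j])}
            )

    pd.DataFrame(pred_rows).to_csv(out / "predictions.tsv", sep="\t", index=False)
    report = PerformanceReport.from_records(records)
    report.to_tsv(out / "report.tsv")
    report.median_by_population().to_csv(out / "summary.tsv", sep="\t")

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": chash,
        "stage_seeds": {
            s: stage_seed(config.seed, s)
            for s in ["folds"] + [f"train_fold{i}" for i in fold_ids]
        },
        "n_genes": len(gene_ids),
        "populations": pops,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
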
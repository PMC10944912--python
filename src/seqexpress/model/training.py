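"""Training loop, replicate ensembles, and prediction.

Networks are trained with Adam on mean-squared error against standardized
log-expression targets. The learning rate starts at 5e-4 and is divided by
10 whenever the validation loss has not improved for 5 consecutive epochs;
training runs at most 40 epochs and the parameters with the lowest
validation loss are kept (earliest epoch wins ties). Because CNN training
is stochastic, an ensemble of replicates (default 5) is trained from
consecutive seeds and predictions are averaged across them.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..pseudobulk import Standardizer
from .layers import DTYPE, Adam
from .network import ExpressionCNN, ModelConfig, build_model


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite; message carries the epoch and learning rate."""


class EnsembleError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    initial_lr: float = 5e-4
    lr_patience: int = 5
    lr_factor: float = 10.0
    max_epochs: int = 40
    batch_size: int = 128

    def __post_init__(self) -> None:
        if self.lr_factor <= 1.0:
            raise ValueError("lr_factor must exceed 1")
        if min(self.initial_lr, self.lr_patience, self.max_epochs, self.batch_size) <= 0:
            raise ValueError("training hyperparameters must be positive")


@dataclass
class Dataset:
    """Encoded inputs and standardized targets for a set of genes."""

    x_seq: np.ndarray  # (N, 4, L)
    x_hl: np.ndarray  # (N, 5)
    y: np.ndarray  # (N, n_tasks)
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.x_seq = np.asarray(self.x_seq, dtype=DTYPE)
        self.x_hl = np.asarray(self.x_hl, dtype=DTYPE)
        self.y = np.asarray(self.y, dtype=DTYPE)
        if self.y.ndim == 1:
            self.y = self.y[:, None]

    def __len__(self) -> int:
        return self.x_seq.shape[0]

    def subset(self, idx) -> "Dataset":
        return Dataset(
            self.x_seq[idx], self.x_hl[idx], self.y[idx],
            [self.gene_ids[i] for i in np.atleast_1d(idx)],
        )


def _mse(pred: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((pred - y) ** 2))


def train(
    network: ExpressionCNN,
    train_data: Dataset,
    val_data: Dataset,
    config: TrainConfig | None = None,
    seed: int = 0,
) -> tuple[ExpressionCNN, list[dict]]:
    """Train one network; returns it (best-validation weights) and its history.

    Fully deterministic given ``seed``, which drives minibatch shuffling and
    dropout. Train and validation gene sets must be disjoint.
    """
    config = config or TrainConfig()
    overlap = set(train_data.gene_ids) & set(val_data.gene_ids)
    if overlap:
        raise ValueError(f"train/validation gene sets overlap: {sorted(overlap)[:5]}")
    rng = np.random.default_rng(seed)
    opt = Adam(network.params, lr=config.initial_lr)
    n = len(train_data)
    best_val = np.inf
    best_weights = network.get_weights()
    since_improve = 0
    history: list[dict] = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, hb, yb = train_data.x_seq[idx], train_data.x_hl[idx], train_data.y[idx]
            pred = network.forward(xb, hb, train=True, rng=rng)
            loss = _mse(pred, yb)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite training loss at epoch {epoch}, lr {opt.lr:g}"
                )
            epoch_loss += loss * len(idx)
            dpred = (2.0 / pred.size) * (pred - yb)
            network.backward(dpred)
            opt.step(network.grads)
        val_loss = _mse(network.predict(val_data.x_seq, val_data.x_hl), val_data.y)
        if not np.isfinite(val_loss):
            raise TrainingDivergedError(
                f"non-finite validation loss at epoch {epoch}, lr {opt.lr:g}"
            )
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss / n,
             "val_loss": val_loss, "lr": opt.lr}
        )
        if val_loss < best_val:  # strict: earliest epoch wins ties
            best_val = val_loss
            best_weights = network.get_weights()
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.lr_patience:
                opt.lr /= config.lr_factor
                since_improve = 0
    network.set_weights(best_weights)
    return network, history


@dataclass
class ModelEnsemble:
    """Trained replicates of one configuration, averaged at prediction time."""

    networks: list[ExpressionCNN]
    config: ModelConfig
    task_names: list[str]
    standardizer: Standardizer
    histories: list[list[dict]] = field(default_factory=list)

    @property
    def n_replicates(self) -> int:
        return len(self.networks)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": self.config.to_dict(),
            "task_names": self.task_names,
            "channel_order": ["A", "C", "G", "T"],
            "n_replicates": self.n_replicates,
        }
        (outdir / "ensemble.json").write_text(json.dumps(meta, indent=1))
        self.standardizer.to_json(outdir / "standardizer.json")
        (outdir / "histories.json").write_text(json.dumps(self.histories))
        for i, net in enumerate(self.networks):
            np.savez(
                outdir / f"replicate_{i}.npz",
                **{f"p{j}": p for j, p in enumerate(net.params)},
            )

    @classmethod
    def load(cls, outdir: str | Path) -> "ModelEnsemble":
        outdir = Path(outdir)
        meta = json.loads((outdir / "ensemble.json").read_text())
        config = ModelConfig.from_dict(meta["config"])
        networks = []
        for i in range(meta["n_replicates"]):
            net = build_model(config)
            with np.load(outdir / f"replicate_{i}.npz") as z:
                net.set_weights([z[f"p{j}"] for j in range(len(net.params))])
            networks.append(net)
        histories = json.loads((outdir / "histories.json").read_text())
        return cls(
            networks=networks,
            config=config,
            task_names=meta["task_names"],
            standardizer=Standardizer.from_json(outdir / "standardizer.json"),
            histories=histories,
        )


def train_ensemble(
    train_data: Dataset,
    val_data: Dataset,
    model_config: ModelConfig,
    train_config: TrainConfig | None = None,
    task_names: list[str] | None = None,
    standardizer: Standardizer | None = None,
    n_replicates: int = 5,
    base_seed: int = 0,
) -> ModelEnsemble:
    """Train ``n_replicates`` networks from seeds base_seed .. base_seed+n-1."""
    task_names = task_names or [f"task{t}" for t in range(model_config.n_tasks)]
    standardizer = standardizer or Standardizer.identity(task_names)
    networks, histories, failures = [], [], []
    for i in range(n_replicates):
        seed = base_seed + i
        cfg = copy.deepcopy(model_config)
        cfg.seed = seed
        try:
            net, hist = train(build_model(cfg), train_data, val_data, train_config, seed)
        except TrainingDivergedError as exc:
            failures.append((seed, str(exc)))
            continue
        networks.append(net)
        histories.append(hist)
    if failures:
        raise EnsembleError(f"replicate(s) failed: {failures}")
    return ModelEnsemble(
        networks=networks,
        config=model_config,
        task_names=task_names,
        standardizer=standardizer,
        histories=histories,
    )


def make_dataset(windows, halflife_norm, targets, gene_ids=None) -> Dataset:
    """Assemble a :class:`Dataset` from sequence windows, a normalized
    half-life table and (optionally) a target matrix, all indexed by gene.

    ``windows`` is a list of SequenceWindow or a gene_id -> window mapping;
    ``targets`` may be None for prediction-only datasets (targets become 0).
    """
    import pandas as pd

    from ..encoding import encode_batch

    if not isinstance(windows, dict):
        windows = {w.gene_id: w for w in windows}
    if gene_ids is None:
        gene_ids = list(windows)
    x_seq = encode_batch([windows[g].seq for g in gene_ids], list(gene_ids))
    x_hl = halflife_norm.loc[gene_ids].to_numpy()
    if targets is None:
        y = np.zeros((len(gene_ids), 1))
    elif isinstance(targets, (pd.DataFrame, pd.Series)):
        y = targets.loc[gene_ids].to_numpy()
    else:
        y = np.asarray(targets)
    return Dataset(x_seq=x_seq, x_hl=x_hl, y=y, gene_ids=list(gene_ids))


def predict(
    ensemble: ModelEnsemble,
    x_seq: np.ndarray,
    x_hl: np.ndarray,
    unstandardized: bool = False,
    batch: int = 256,
) -> np.ndarray:
    """Mean of replicate predictions, optionally mapped back to log10 scale."""
    if ensemble.config.n_tasks != len(ensemble.standardizer.populations):
        raise ValueError(
            f"model has {ensemble.config.n_tasks} tasks but standardizer covers "
            f"{len(ensemble.standardizer.populations)} populations"
        )
    preds = [net.predict(x_seq, x_hl, batch=batch) for net in ensemble.networks]
    mean = np.mean(preds, axis=0)
    if unstandardized:
        mean = ensemble.standardizer.inverse(mean.astype(np.float64))
    return mean
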
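"""Model training, stratified 5-fold cross-validation, grid search, selection.

The training loop follows the published recipe: Adam with learning rate
1e-4, 2-class cross-entropy on softmax outputs, 30% dropout active only
during training, mini-batches of 32.  Cross-validation uses stratified
k-fold splitting (k = 5), so each fold preserves the global true:false
ratio; model selection averages mean CV validation accuracy across
organisms and ranks architectures by that cross-organism average.

All randomness (fold shuffling, weight init, batch order, dropout masks)
derives from one master seed, so a run is reproducible end to end.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import nn
from .errors import ConfigError, TrainingError
from .models import (
    ArchitectureSpec,
    ModelWeights,
    build_architecture,
    build_network,
    catalog_spec,
)
from .seqdata import SpliceDataset


@dataclass
class TrainingConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    epochs: int = 30
    batch_size: int = 32
    early_stop_patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")


@dataclass
class FoldSplit:
    """k disjoint validation-index subsets that partition the dataset."""

    folds: list[np.ndarray]
    class_counts: list[tuple[int, int]]  # (n_true, n_false) per fold
    seed: int = 0

    @property
    def k(self) -> int:
        return len(self.folds)

    def train_val_indices(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        val = self.folds[i]
        train = np.concatenate([f for j, f in enumerate(self.folds) if j != i])
        return train, val


def stratified_kfold(dataset: SpliceDataset, k: int = 5, seed: int = 0) -> FoldSplit:
    """Split into k folds preserving the true:false ratio in every fold."""
    y = dataset.labels()
    for cls in (0, 1):
        n_cls = int((y == cls).sum())
        if n_cls < k:
            raise TrainingError(
                f"class {cls} has only {n_cls} records; need at least k={k}"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [val.astype(np.int64) for _, val in skf.split(np.zeros(len(y)), y)]
    counts = [(int(y[f].sum()), int(len(f) - y[f].sum())) for f in folds]
    return FoldSplit(folds=folds, class_counts=counts, seed=seed)


@dataclass
class TrainResult:
    weights: ModelWeights
    history: list[dict]  # per-epoch train/val loss and accuracy
    best_epoch: int  # epoch whose weights were restored (1-based)


def _accuracy(net: nn.Network, x: np.ndarray, y: np.ndarray, batch: int = 256) -> tuple[float, float]:
    """(mean loss, accuracy) of a network on encoded data, inference mode."""
    n = x.shape[0]
    losses = []
    correct = 0
    for s in range(0, n, batch):
        logits = net.forward(x[s : s + batch], train=False)
        loss, _ = nn.softmax_cross_entropy(logits, y[s : s + batch])
        losses.append(loss * logits.shape[0])
        correct += int((logits.argmax(axis=1) == y[s : s + batch]).sum())
    return float(np.sum(losses) / n), correct / n


def train(
    spec: ArchitectureSpec,
    weights: ModelWeights,
    train_xy: tuple[np.ndarray, np.ndarray],
    val_xy: tuple[np.ndarray, np.ndarray],
    cfg: TrainingConfig,
) -> TrainResult:
    """Mini-batch training with early stopping on validation loss.

    Restores the weights of the best-validation-loss epoch on exit; dropout
    is active only during the training forward passes.
    """
    x_train, y_train = train_xy
    x_val, y_val = val_xy
    if x_train.shape[0] == 0:
        raise TrainingError("empty training set")
    if x_train.shape[1] != spec.input_len:
        raise TrainingError(
            f"encoded inputs of length {x_train.shape[1]} do not match "
            f"input_len {spec.input_len}"
        )
    x_train = np.asarray(x_train, dtype=np.float32)
    x_val = np.asarray(x_val, dtype=np.float32)
    net = build_network(spec)
    net.set_parameters(weights.tensors)
    params = net.parameters()
    opt = nn.make_optimizer(cfg.optimizer, params, cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    history: list[dict] = []
    best_val = np.inf
    best_epoch = 0
    best_params = {k: v.copy() for k, v in params.items()}
    patience_left = cfg.early_stop_patience
    n = x_train.shape[0]
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_correct = 0
        for s in range(0, n, cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            logits = net.forward(xb, train=True, rng=rng)
            loss, dlogits = nn.softmax_cross_entropy(logits, yb)
            net.backward(dlogits)
            opt.step(net.gradients())
            epoch_loss += loss * len(idx)
            epoch_correct += int((logits.argmax(axis=1) == yb).sum())
        val_loss, val_acc = _accuracy(net, x_val, y_val)
        history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / n,
                "train_accuracy": epoch_correct / n,
                "val_loss": val_loss,
                "val_accuracy": val_acc,
            }
        )
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_params = {k: v.copy() for k, v in params.items()}
            patience_left = cfg.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    trained = ModelWeights(
        best_params,
        provenance=(
            f"trained {spec.name} (optimizer={cfg.optimizer}, lr={cfg.learning_rate}, "
            f"seed={cfg.seed}, best_epoch={best_epoch})"
        ),
    )
    return TrainResult(weights=trained, history=history, best_epoch=best_epoch)


@dataclass
class CVResult:
    architecture: str
    organism: str
    fold_accuracies: list[float]  # at the restored (best-val-loss) epoch
    fold_losses: list[float]
    fold_final_accuracies: list[float]  # at the last trained epoch

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def mean_loss(self) -> float:
        return float(np.mean(self.fold_losses))

    @property
    def mean_final_accuracy(self) -> float:
        return float(np.mean(self.fold_final_accuracies))


def cross_validate(
    arch_name: str,
    dataset: SpliceDataset,
    cfg: TrainingConfig,
    k: int = 5,
    organism: str = "",
    encoded: tuple[np.ndarray, np.ndarray] | None = None,
) -> CVResult:
    """k-fold CV of one architecture; reports per-fold and mean accuracy/loss.

    Validation accuracy is reported both at the restored best-validation-loss
    epoch and at the final trained epoch.  ``encoded`` lets callers reuse a
    precomputed (x, y) encoding of the dataset.
    """
    spec = catalog_spec(arch_name, input_len=len(dataset.windows[0].bases) if len(dataset) else 400)
    if encoded is None:
        x, y = dataset.encode(), dataset.labels()
    else:
        x, y = encoded
    split = stratified_kfold(dataset, k=k, seed=cfg.seed)
    fold_acc: list[float] = []
    fold_loss: list[float] = []
    fold_final: list[float] = []
    for i in range(split.k):
        tr_idx, va_idx = split.train_val_indices(i)
        fold_seed = (cfg.seed * 1000 + i) % (2**31)
        _, init_w = build_architecture(spec.name, input_len=spec.input_len, seed=fold_seed)
        result = train(
            spec,
            init_w,
            (x[tr_idx], y[tr_idx]),
            (x[va_idx], y[va_idx]),
            replace(cfg, seed=fold_seed),
        )
        best = result.history[result.best_epoch - 1]
        fold_acc.append(best["val_accuracy"])
        fold_loss.append(best["val_loss"])
        fold_final.append(result.history[-1]["val_accuracy"])
    return CVResult(
        architecture=spec.name,
        organism=organism or (dataset.windows[0].organism if len(dataset) else ""),
        fold_accuracies=fold_acc,
        fold_losses=fold_loss,
        fold_final_accuracies=fold_final,
    )


# ---------------------------------------------------------------------------
# hyperparameter grid search


@dataclass
class HyperparameterGrid:
    """The tuning search space (defaults mirror the published grid)."""

    layers: Sequence[int] = (1, 2, 3, 4, 5)
    filter_number: Sequence[int] = (50, 64, 100, 128, 150)
    filter_size: Sequence[int] = (3, 5, 7, 9, 11)
    stride: Sequence[int] = (1, 3, 5)
    activation: Sequence[str] = ("sigmoid", "relu", "softmax", "tanh")
    learning_rate: Sequence[float] = (1e-3, 5e-4, 1e-4, 5e-5, 1e-5)
    optimizer: Sequence[str] = ("sgd", "adam", "adagrad", "rmsprop", "nadam")

    def points(self) -> Iterable[dict]:
        keys = (
            "layers",
            "filter_number",
            "filter_size",
            "stride",
            "activation",
            "learning_rate",
            "optimizer",
        )
        for combo in itertools.product(*(getattr(self, k) for k in keys)):
            yield dict(zip(keys, combo))

    def size(self) -> int:
        return int(
            np.prod(
                [
                    len(s)
                    for s in (
                        self.layers,
                        self.filter_number,
                        self.filter_size,
                        self.stride,
                        self.activation,
                        self.learning_rate,
                        self.optimizer,
                    )
                ]
            )
        )


@dataclass
class GridSearchResult:
    best: dict
    leaderboard: list[dict]  # ascending validation loss


def grid_search(
    grid: HyperparameterGrid,
    tuning_dataset: SpliceDataset,
    budget: int,
    seed: int = 0,
    epochs: int = 2,
    val_fraction: float = 0.2,
    cv_dataset_ids: set[str] | None = None,
) -> GridSearchResult:
    """Evaluate up to ``budget`` grid points; best = minimum validation loss.

    Points are subsampled deterministically under ``seed`` when the budget is
    smaller than the grid (exhaustive otherwise).  ``cv_dataset_ids`` guards
    against tuning on records that also feed cross-validation: any overlap of
    record ids is an error.
    """
    if budget < 1:
        raise ConfigError("budget must be >= 1")
    all_points = list(grid.points())
    if not all_points:
        raise ConfigError("empty hyperparameter grid")
    if cv_dataset_ids is not None:
        tune_ids = {w.sequence.id for w in tuning_dataset}
        overlap = tune_ids & cv_dataset_ids
        if overlap:
            raise ConfigError(
                f"tuning dataset shares {len(overlap)} record ids with the CV "
                f"dataset (e.g., {sorted(overlap)[:3]}); they must be disjoint"
            )
    rng = np.random.default_rng(seed)
    if budget < len(all_points):
        chosen = [all_points[i] for i in rng.choice(len(all_points), size=budget, replace=False)]
    else:
        chosen = all_points
    x, y = tuning_dataset.encode(), tuning_dataset.labels()
    n_val = max(1, int(round(val_fraction * len(y))))
    order = rng.permutation(len(y))
    va_idx, tr_idx = order[:n_val], order[n_val:]
    if tr_idx.size == 0:
        raise TrainingError("tuning dataset too small to split")
    input_len = x.shape[1]
    leaderboard: list[dict] = []
    for point in chosen:
        spec = ArchitectureSpec(
            name="GRIDPOINT",
            n_conv_blocks=point["layers"],
            pooling="max",
            filters=point["filter_number"],
            kernel_size=point["filter_size"],
            conv_stride=point["stride"],
            conv_activation=point["activation"],
            input_len=input_len,
        )
        net = build_network(spec)
        net.init(seed)
        init_w = ModelWeights({k: v.copy() for k, v in net.parameters().items()})
        cfg = TrainingConfig(
            optimizer=point["optimizer"],
            learning_rate=point["learning_rate"],
            epochs=epochs,
            early_stop_patience=epochs,
            seed=seed,
        )
        result = train(spec, init_w, (x[tr_idx], y[tr_idx]), (x[va_idx], y[va_idx]), cfg)
        best_hist = result.history[result.best_epoch - 1]
        leaderboard.append(
            {**point, "val_loss": best_hist["val_loss"], "val_accuracy": best_hist["val_accuracy"]}
        )
    leaderboard.sort(key=lambda e: (e["val_loss"], tuple(sorted(e.items()))))
    return GridSearchResult(best=leaderboard[0], leaderboard=leaderboard)


# ---------------------------------------------------------------------------
# model selection


@dataclass
class SelectionResult:
    table: list[dict]  # one row per architecture, descending cross-organism average
    top: list[str]

    def row(self, architecture: str) -> dict:
        for r in self.table:
            if r["architecture"] == architecture:
                return r
        raise KeyError(architecture)


def select_models(
    cv_results: Iterable[CVResult] | Mapping[tuple[str, str], CVResult],
    top_k: int = 5,
) -> SelectionResult:
    """Rank architectures by mean CV accuracy averaged across organisms.

    Every architecture must have a result for every organism.  Ties are
    broken lexicographically by architecture name, so the ranking is
    deterministic and permutation-invariant.
    """
    if isinstance(cv_results, Mapping):
        results = list(cv_results.values())
    else:
        results = list(cv_results)
    if not results:
        raise ConfigError("no CV results supplied")
    architectures = sorted({r.architecture for r in results})
    organisms = sorted({r.organism for r in results})
    by_cell = {(r.architecture, r.organism): r for r in results}
    table = []
    for arch in architectures:
        per_org = {}
        for org in organisms:
            if (arch, org) not in by_cell:
                raise ConfigError(f"missing CV result for architecture {arch!r} on organism {org!r}")
            per_org[org] = by_cell[(arch, org)].mean_accuracy
        table.append(
            {
                "architecture": arch,
                "per_organism": per_org,
                "cross_organism_mean": float(np.mean(list(per_org.values()))),
            }
        )
    table.sort(key=lambda r: (-r["cross_organism_mean"], r["architecture"]))
    for i, row in enumerate(table, start=1):
        row["rank"] = i
    return SelectionResult(table=table, top=[r["architecture"] for r in table[:top_k]])
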
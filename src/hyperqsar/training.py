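"""Episodic end-to-end training.

Each optimization step consumes a *meta-batch* of protein targets, each
paired with a *mini-batch* of drug interactions sampled from the training
fold (with replacement only when a target has fewer interactions than the
mini-batch size).  Underrepresented targets are oversampled by duplicating
their roster entries until their drawn-drug total reaches the configured
floor.  Sampling applies to training only; validation and test folds are
evaluated exhaustively.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._tensor import Tensor, bce_with_logits, concat
from .data_model_io import EmbeddingStore, InteractionTable, validate_coverage
from .hyper_qsar import HyperQSAR, distribute, hyper_forward, qsar_forward
from .metrics import (
    UndefinedMetricError,
    auc,
    concordance_index,
    mcc,
    mse_mae,
)
from .splitting import SplitSpec

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "NumericalError",
    "make_meta_batches",
    "train",
    "evaluate",
    "ConcatFCN",
    "baseline_concat_fcn",
]


class NumericalError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass
class TrainConfig:
    loss: str = "l1"  # {"l1", "mse", "bce"}
    meta_batch_size: int = 8
    mini_batch_size: int = 16
    min_drugs_per_target: int = 1
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    decay_factor: float = 0.5
    decay_patience: int = 5
    lr_floor: float = 1e-6
    max_epochs: int = 100
    early_stop_patience: int = 10
    classification_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.loss not in ("l1", "mse", "bce"):
            raise ValueError("loss must be one of {'l1', 'mse', 'bce'}")
        if min(self.meta_batch_size, self.mini_batch_size, self.min_drugs_per_target) < 1:
            raise ValueError("batch sizes and the oversampling floor must be >= 1")
        if not 0 < self.decay_factor <= 1:
            raise ValueError("decay_factor must lie in (0, 1]")

    @classmethod
    def from_file(cls, path: str) -> "TrainConfig":
        if path.endswith((".yaml", ".yml")):
            import yaml

            with open(path, "r", encoding="utf-8") as fh:
                d = yaml.safe_load(fh)
        else:
            with open(path, "r", encoding="utf-8") as fh:
                d = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class MetricsReport:
    values: dict[str, float]
    split: str
    n: int


def _check_loss_labels(loss: str, label_kind: str) -> None:
    if (loss == "bce") != (label_kind == "binary"):
        raise ValueError(
            f"loss {loss!r} is incompatible with label_kind {label_kind!r}"
        )


def make_meta_batches(
    table: InteractionTable, split: SplitSpec, config: TrainConfig, epoch_seed: int
):
    """One epoch's batches: a list of lists of (target_id, record indices).

    Record indices point into ``table``.  A target's entry appears multiple
    times in the epoch roster when its interaction count is below
    ``min_drugs_per_target``; each entry draws ``mini_batch_size`` records.
    """
    if not split.train_idx:
        raise ValueError("train fold is empty")
    rng = np.random.default_rng(epoch_seed)
    by_target: dict[str, list[int]] = {}
    for i in split.train_idx:
        by_target.setdefault(table[i].target_id, []).append(i)
    roster: list[str] = []
    for tid in sorted(by_target):
        n_avail = len(by_target[tid])
        if n_avail == 0:  # pragma: no cover - defensive
            warnings.warn(f"target {tid} has no training interactions; skipped")
            continue
        copies = 1
        if n_avail < config.min_drugs_per_target:
            copies = int(np.ceil(config.min_drugs_per_target / config.mini_batch_size))
            copies = max(copies, 1)
        roster.extend([tid] * copies)
    rng.shuffle(roster)
    batches = []
    for lo in range(0, len(roster), config.meta_batch_size):
        chunk = roster[lo : lo + config.meta_batch_size]
        batch = []
        for tid in chunk:
            pool = by_target[tid]
            if len(pool) < config.mini_batch_size:
                draw = rng.choice(pool, size=config.mini_batch_size, replace=True)
            else:
                draw = rng.choice(pool, size=config.mini_batch_size, replace=False)
            batch.append((tid, [int(d) for d in draw]))
        batches.append(batch)
    return batches


class Adam:
    """Adam with decoupled (AdamW-style) weight decay."""

    def __init__(self, params: list[Tensor], lr: float, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            # decay matrices only: biases and norm affines stay unpenalized
            wd = self.weight_decay if p.data.ndim > 1 else 0.0
            p.data = p.data - self.lr * (
                mhat / (np.sqrt(vhat) + self.eps) + wd * p.data
            )

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def _pair_loss(pred: Tensor, y: np.ndarray, loss: str) -> Tensor:
    if loss == "l1":
        return (pred - Tensor(y)).abs().sum()
    if loss == "mse":
        return ((pred - Tensor(y)) ** 2).sum()
    return bce_with_logits(pred, y) * y.size  # summed, normalized later


def _np_loss(pred: np.ndarray, y: np.ndarray, loss: str) -> float:
    if loss == "l1":
        return float(np.mean(np.abs(pred - y)))
    if loss == "mse":
        return float(np.mean((pred - y) ** 2))
    p = np.clip(pred, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _validation_scores(model, table, idx, drug_store, target_store, config):
    drug_ids = [table[i].drug_id for i in idx]
    target_ids = [table[i].target_id for i in idx]
    y = np.array([table[i].label for i in idx])
    model.clear_cache()
    pred = model.predict_table(drug_ids, target_ids, drug_store, target_store)
    val_loss = _np_loss(pred, y, config.loss)
    if table.label_kind == "binary":
        hard = (pred >= config.classification_threshold).astype(float)
        try:
            metric = mcc(y, hard)
        except ValueError:
            metric = 0.0
    else:
        try:
            metric = concordance_index(y, pred)
        except UndefinedMetricError:
            metric = 0.5
    return val_loss, metric


def train(
    model: HyperQSAR,
    table: InteractionTable,
    split: SplitSpec,
    config: TrainConfig,
    drug_store: EmbeddingStore,
    target_store: EmbeddingStore,
):
    """Train end-to-end; returns (model at best validation, history rows).

    The model's context memory is built from the training fold only.  The
    returned history is a list of dicts (epoch, train_loss, val_loss,
    val_metric, lr).
    """
    _check_loss_labels(config.loss, table.label_kind)
    cov = validate_coverage(table, drug_store, target_store)
    if not cov.ok:
        raise ValueError(
            f"missing embeddings: drugs={cov.missing_drugs[:5]} targets={cov.missing_targets[:5]}"
        )
    train_targets = sorted({table[i].target_id for i in split.train_idx})
    if model.state is None:
        model.fit_context(target_store, train_targets)

    # for BCE the network is evaluated on logits during training
    logits_spec = replace(model.main_spec, output_activation="identity")
    train_spec = logits_spec if config.loss == "bce" else model.main_spec

    opt = Adam(model.parameters(), config.learning_rate, config.weight_decay)
    rng = np.random.default_rng(config.seed)
    history = []
    best_metric = -np.inf
    best_weights = model.get_weights()
    best_epoch = 0
    epochs_no_metric_improve = 0
    epochs_no_loss_improve = 0
    best_val_loss = np.inf

    for epoch in range(1, config.max_epochs + 1):
        batches = make_meta_batches(table, split, config, epoch_seed=config.seed + epoch)
        total_loss, total_pairs = 0.0, 0
        for batch in batches:
            T_batch = np.stack([target_store[tid] for tid, _ in batch])
            flat = model.predict_flat(T_batch, training=True, rng=rng)
            losses = []
            n_pairs = 0
            for row, (tid, rec_idx) in enumerate(batch):
                params = distribute(flat[row], model.schema)
                X = np.stack([drug_store[table[i].drug_id] for i in rec_idx])
                y = np.array([table[i].label for i in rec_idx])
                pred = qsar_forward(X, params, train_spec)
                losses.append(_pair_loss(pred, y, config.loss))
                n_pairs += len(rec_idx)
            loss = sum(losses[1:], start=losses[0]) * (1.0 / n_pairs)
            if not np.isfinite(loss.numpy()):
                raise NumericalError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            total_loss += float(loss.numpy()) * n_pairs
            total_pairs += n_pairs
        train_loss = total_loss / max(total_pairs, 1)

        if split.val_idx:
            val_loss, val_metric = _validation_scores(
                model, table, split.val_idx, drug_store, target_store, config
            )
        else:
            val_loss, val_metric = train_loss, -train_loss
        history.append(
            {
                "epoch": epoch,
                "train_loss": train_loss,
                "val_loss": val_loss,
                "val_metric": val_metric,
                "lr": opt.lr,
            }
        )

        if val_metric > best_metric:
            best_metric = val_metric
            best_weights = model.get_weights()
            best_epoch = epoch
            epochs_no_metric_improve = 0
        else:
            epochs_no_metric_improve += 1
        if val_loss < best_val_loss - 1e-12:
            best_val_loss = val_loss
            epochs_no_loss_improve = 0
        else:
            epochs_no_loss_improve += 1
            if epochs_no_loss_improve > config.decay_patience and opt.lr > config.lr_floor:
                opt.lr = max(opt.lr * config.decay_factor, config.lr_floor)
                epochs_no_loss_improve = 0
        if epochs_no_metric_improve > config.early_stop_patience:
            break

    model.set_weights(best_weights)
    model.clear_cache()
    return model, history


def evaluate(
    model,
    table: InteractionTable,
    fold_idx,
    metrics,
    threshold: float | None = None,
    drug_store: EmbeddingStore | None = None,
    target_store: EmbeddingStore | None = None,
    split_tag: str = "test",
    classification_threshold: float = 0.5,
) -> MetricsReport:
    """Exhaustive (no sampling) evaluation of a model on one fold.

    Continuous tables feed mse/mae/ci directly; for mcc/auc the true labels
    are binarized at ``threshold`` (score side: predictions thresholded for
    mcc, ranked as-is for auc).
    """
    fold_idx = list(fold_idx)
    if not fold_idx:
        raise ValueError("fold is empty")
    drug_ids = [table[i].drug_id for i in fold_idx]
    target_ids = [table[i].target_id for i in fold_idx]
    y = np.array([table[i].label for i in fold_idx])
    pred = model.predict_table(drug_ids, target_ids, drug_store, target_store)

    values: dict[str, float] = {}
    for m in metrics:
        if m in ("mse", "mae"):
            mse_v, mae_v = mse_mae(y, pred)
            values[m] = mse_v if m == "mse" else mae_v
        elif m == "ci":
            if table.label_kind == "binary":
                raise ValueError("ci requires continuous labels")
            values[m] = concordance_index(y, pred)
        elif m in ("mcc", "auc"):
            if table.label_kind == "binary":
                y_bin, scores = y, pred
                score_thr = classification_threshold
            else:
                if threshold is None:
                    raise ValueError(f"{m} on continuous labels needs a threshold")
                y_bin = (y >= threshold).astype(float)
                scores = pred
                score_thr = threshold
            if m == "auc":
                values[m] = auc(y_bin, scores)
            else:
                values[m] = mcc(y_bin, (scores >= score_thr).astype(float))
        else:
            raise ValueError(f"unknown metric {m!r}")
    return MetricsReport(values, split_tag, len(fold_idx))


# ---------------------------------------------------------------------------
# concatenation-FCN reference baseline
# ---------------------------------------------------------------------------


class ConcatFCN:
    """Feed-forward net on the concatenated [drug; target] embedding."""

    def __init__(self, d_drug: int, d_target: int, hidden=(64,), seed: int = 0):
        rng = np.random.default_rng(seed)
        dims = [d_drug + d_target, *hidden, 1]
        self.layers = []
        for i in range(len(dims) - 1):
            gain = 2.0 if i < len(dims) - 2 else 1.0
            W = rng.standard_normal((dims[i], dims[i + 1])) * np.sqrt(gain / dims[i])
            self.layers.append(
                (Tensor(W, requires_grad=True), Tensor(np.zeros(dims[i + 1]), requires_grad=True))
            )

    def parameters(self):
        return [p for layer in self.layers for p in layer]

    def forward(self, Z) -> Tensor:
        a = Z if isinstance(Z, Tensor) else Tensor(Z)
        for i, (W, b) in enumerate(self.layers):
            a = a @ W + b
            if i < len(self.layers) - 1:
                a = a.relu()
        return a.reshape(-1)

    def predict_table(self, drug_ids, target_ids, drug_store, target_store) -> np.ndarray:
        Z = np.hstack(
            [
                np.stack([drug_store[d] for d in drug_ids]),
                np.stack([target_store[t] for t in target_ids]),
            ]
        )
        return self.forward(Z).numpy()


def baseline_concat_fcn(
    table: InteractionTable,
    split: SplitSpec,
    config: TrainConfig,
    drug_store: EmbeddingStore,
    target_store: EmbeddingStore,
    hidden=(64,),
):
    """Train the concatenation-FCN comparator with plain mini-batch Adam."""
    _check_loss_labels(config.loss, table.label_kind)
    cov = validate_coverage(table, drug_store, target_store)
    if not cov.ok:
        raise ValueError("missing embeddings for baseline")
    model = ConcatFCN(drug_store.dim, target_store.dim, hidden=hidden, seed=config.seed)
    opt = Adam(model.parameters(), config.learning_rate, config.weight_decay)
    rng = np.random.default_rng(config.seed)
    idx = np.array(split.train_idx)
    Z = np.hstack(
        [
            np.stack([drug_store[table[i].drug_id] for i in idx]),
            np.stack([target_store[table[i].target_id] for i in idx]),
        ]
    )
    y = np.array([table[i].label for i in idx])
    bs = config.meta_batch_size * config.mini_batch_size
    history = []
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(idx))
        epoch_loss = 0.0
        for lo in range(0, len(order), bs):
            sel = order[lo : lo + bs]
            pred = model.forward(Z[sel])
            loss = _pair_loss(pred, y[sel], config.loss) * (1.0 / len(sel))
            if not np.isfinite(loss.numpy()):
                raise NumericalError(f"baseline loss diverged at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.numpy()) * len(sel)
        history.append({"epoch": epoch, "train_loss": epoch_loss / len(idx)})
    return model, history
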
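"""Task-conditioned synthetic benchmark generator.

Drug and target embeddings are i.i.d. standard normal.  Each target ``i``
carries a hidden weight vector ``w_i = A t_i`` (``A`` a fixed random matrix
of configurable rank), and the label of pair (i, j) is
``<w_i, x_j> / sqrt(d_drug) + noise``.  Because ``w_i`` is an exact function
of the target embedding, held-out targets remain predictable from their
embeddings alone — the structure a task-conditioned model must exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_model_io import EmbeddingStore, InteractionRecord, InteractionTable
from .metrics import PredictionSet

__all__ = ["SynthConfig", "GroundTruth", "generate", "binarize_synthetic", "metric_fixture"]


@dataclass
class SynthConfig:
    n_targets: int = 20
    n_drugs: int = 30
    d_target: int = 8
    d_drug: int = 8
    noise_sd: float = 0.0
    sparsity: float = 1.0
    active_fraction: float = 0.5
    ground_truth_rank: int | None = None  # defaults to d_target
    nonlinear: bool = False  # tanh applied elementwise after A
    seed: int = 0

    def __post_init__(self):
        if min(self.n_targets, self.n_drugs, self.d_target, self.d_drug) <= 0:
            raise ValueError("counts and dimensions must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.sparsity <= 1:
            raise ValueError("sparsity must lie in (0, 1]")
        if not 0 < self.active_fraction < 1:
            raise ValueError("active_fraction must lie in (0, 1)")
        if self.sparsity * self.n_targets * self.n_drugs < 1:
            raise ValueError("sparsity leaves no labeled pairs")
        if self.ground_truth_rank is None:
            self.ground_truth_rank = self.d_target
        if not 1 <= self.ground_truth_rank <= self.d_target:
            raise ValueError("ground_truth_rank must lie in [1, d_target]")


@dataclass
class GroundTruth:
    """Everything needed for recovery oracles: the map, per-task weights and
    the noise-free label grid."""

    A: np.ndarray  # (d_drug, d_target), rank-limited
    weights: dict[str, np.ndarray]  # target_id -> w_i
    clean_labels: dict[tuple[str, str], float]


def _task_weights(A: np.ndarray, t: np.ndarray, nonlinear: bool) -> np.ndarray:
    w = A @ t
    return np.tanh(w) if nonlinear else w


def generate(config: SynthConfig):
    """Return (drug store, target store, interaction table, ground truth)."""
    rng = np.random.default_rng(config.seed)
    width = max(len(str(config.n_targets)), len(str(config.n_drugs)))
    target_ids = [f"T{i:0{width}d}" for i in range(config.n_targets)]
    drug_ids = [f"D{j:0{width}d}" for j in range(config.n_drugs)]

    T = rng.standard_normal((config.n_targets, config.d_target))
    X = rng.standard_normal((config.n_drugs, config.d_drug))

    # rank-limited linear map from target embedding to task weights
    r = config.ground_truth_rank
    U = rng.standard_normal((config.d_drug, r)) / np.sqrt(r)
    V = rng.standard_normal((r, config.d_target))
    A = U @ V

    weights = {tid: _task_weights(A, T[i], config.nonlinear) for i, tid in enumerate(target_ids)}
    scale = np.sqrt(config.d_drug)

    clean = {}
    records = []
    n_pairs = config.n_targets * config.n_drugs
    keep = rng.random(n_pairs) < config.sparsity if config.sparsity < 1 else np.ones(n_pairs, bool)
    if not keep.any():
        keep[rng.integers(n_pairs)] = True
    noise = rng.normal(0.0, config.noise_sd, size=n_pairs) if config.noise_sd > 0 else np.zeros(n_pairs)
    k = 0
    for i, tid in enumerate(target_ids):
        w = weights[tid]
        for j, did in enumerate(drug_ids):
            y_clean = float(w @ X[j] / scale)
            clean[(did, tid)] = y_clean
            if keep[k]:
                records.append(InteractionRecord(did, tid, y_clean + float(noise[k])))
            k += 1

    drug_store = EmbeddingStore(config.d_drug, {d: X[j] for j, d in enumerate(drug_ids)})
    target_store = EmbeddingStore(config.d_target, {t: T[i] for i, t in enumerate(target_ids)})
    table = InteractionTable(records, label_kind="continuous")
    return drug_store, target_store, table, GroundTruth(A, weights, clean)


def binarize_synthetic(table: InteractionTable, active_fraction: float) -> InteractionTable:
    """Binarize at the empirical (1 - active_fraction) label quantile."""
    if table.label_kind != "continuous":
        raise ValueError("binarize_synthetic requires a continuous table")
    if not 0 < active_fraction < 1:
        raise ValueError("active_fraction must lie in (0, 1)")
    labels = table.labels
    if np.ptp(labels) == 0:
        raise ValueError("labels are constant; quantile threshold undefined")
    thr = float(np.quantile(labels, 1.0 - active_fraction))
    records = [replace(r, label=1.0 if r.label >= thr else 0.0) for r in table.records]
    return InteractionTable(records, label_kind="binary", allow_duplicates=True)


def metric_fixture(kind: str, n: int = 20, seed: int = 0) -> PredictionSet:
    """Small canonical prediction sets exercising every metric branch."""
    half = n // 2
    labels = np.r_[np.ones(half), np.zeros(n - half)]
    if kind == "perfect":
        return PredictionSet(labels, labels.copy())
    if kind == "inverted":
        return PredictionSet(labels, 1.0 - labels)
    if kind == "tied":
        return PredictionSet(labels, np.full(n, 0.5))
    if kind == "random":
        rng = np.random.default_rng(seed)
        return PredictionSet(labels, rng.random(n))
    raise ValueError(f"unknown fixture kind {kind!r}")
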
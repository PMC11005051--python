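"""Chemogenomic hold-out strategies with machine-checkable leakage guarantees.

Strategies:

- ``random``          uniform over interactions
- ``temporal``        drugs bucketed by earliest dated record vs. cut dates
- ``lcco``            leave-cluster-compound-out: k-means on Morgan bits,
                      whole clusters packed into folds
- ``lpo``             leave-protein-out (target holdout); alias ``cold_target``
- ``cold_drug``       drug holdout
- ``cold``            both held out; test keeps only doubly-unseen pairs
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data_model_io import InteractionTable, ValidationError

__all__ = [
    "SplitSpec",
    "FingerprintSet",
    "SplitViolation",
    "split_random",
    "split_temporal",
    "compute_morgan_fingerprints",
    "split_lcco",
    "split_entity_holdout",
    "validate_split",
]

STRATEGIES = ("random", "temporal", "lcco", "lpo", "cold_drug", "cold_target", "cold")

# which entity must be disjoint between train and test, per strategy
_ENTITY_GUARDS = {
    "lpo": ("target",),
    "cold_target": ("target",),
    "cold_drug": ("drug",),
    "lcco": ("drug",),
    "temporal": ("drug",),
    "cold": ("drug", "target"),
    "random": (),
}


@dataclass
class SplitSpec:
    strategy: str
    seed: int
    train_idx: list[int]
    val_idx: list[int]
    test_idx: list[int]
    fold_id: int | None = None
    degenerate: bool = False  # set by lcco on pathological fingerprints

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        sets = [set(self.train_idx), set(self.val_idx), set(self.test_idx)]
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise ValueError("fold index sets overlap")

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "strategy": self.strategy,
                    "seed": self.seed,
                    "fold_id": self.fold_id,
                    "degenerate": self.degenerate,
                    "train_idx": list(map(int, self.train_idx)),
                    "val_idx": list(map(int, self.val_idx)),
                    "test_idx": list(map(int, self.test_idx)),
                },
                fh,
            )

    @classmethod
    def from_json(cls, path: str) -> "SplitSpec":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            strategy=d["strategy"],
            seed=d["seed"],
            train_idx=d["train_idx"],
            val_idx=d["val_idx"],
            test_idx=d["test_idx"],
            fold_id=d.get("fold_id"),
            degenerate=d.get("degenerate", False),
        )


@dataclass
class FingerprintSet:
    n_bits: int
    bits: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for k, v in self.bits.items():
            v = np.asarray(v, dtype=np.uint8)
            if v.shape != (self.n_bits,):
                raise ValueError(f"fingerprint for {k!r} has wrong length")
            self.bits[k] = v

    def matrix(self, ids) -> np.ndarray:
        return np.stack([self.bits[i] for i in ids]).astype(float)


@dataclass(frozen=True)
class SplitViolation:
    kind: str  # {"index_overlap", "entity_leak"}
    detail: str


def _check_fractions(fractions) -> tuple[float, float, float]:
    fr = tuple(float(f) for f in fractions)
    if len(fr) != 3:
        raise ValueError("fractions must be (train, val, test)")
    if any(f < 0 for f in fr) or fr[0] <= 0:
        raise ValueError("fractions must be positive")
    if sum(fr) > 1.0 + 1e-9:
        raise ValueError(f"fractions sum to {sum(fr)} > 1")
    return fr


def _partition_counts(n: int, fractions) -> tuple[int, int, int]:
    f_tr, f_va, f_te = fractions
    n_tr = int(round(f_tr * n))
    n_va = int(round(f_va * n))
    n_te = int(round(f_te * n))
    # if the fractions exhaust the pool, hand rounding slack to train
    if abs(sum(fractions) - 1.0) < 1e-9:
        n_tr = n - n_va - n_te
    return n_tr, n_va, n_te


def split_random(table: InteractionTable, fractions, seed: int) -> SplitSpec:
    fr = _check_fractions(fractions)
    n = len(table)
    n_tr, n_va, n_te = _partition_counts(n, fr)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return SplitSpec(
        "random",
        seed,
        train_idx=sorted(map(int, perm[:n_tr])),
        val_idx=sorted(map(int, perm[n_tr : n_tr + n_va])),
        test_idx=sorted(map(int, perm[n_tr + n_va : n_tr + n_va + n_te])),
    )


def split_temporal(table: InteractionTable, cut_dates) -> SplitSpec:
    """Assign each drug by its earliest dated record: before the first cut ->
    train, before the second -> validation, otherwise test."""
    if len(cut_dates) != 2:
        raise ValueError("cut_dates must be (train/val cut, val/test cut)")
    undated = sorted({r.drug_id for r in table if r.date is None})
    if undated:
        raise ValidationError(f"undated drugs: {undated}")
    earliest: dict[str, object] = {}
    for r in table:
        if r.drug_id not in earliest or r.date < earliest[r.drug_id]:
            earliest[r.drug_id] = r.date
    c1, c2 = cut_dates
    folds = ([], [], [])
    for i, r in enumerate(table):
        d = earliest[r.drug_id]
        folds[0 if d < c1 else 1 if d < c2 else 2].append(i)
    return SplitSpec("temporal", seed=0, train_idx=folds[0], val_idx=folds[1], test_idx=folds[2])


def compute_morgan_fingerprints(smiles_map: dict[str, str], radius: int = 2, n_bits: int = 256) -> FingerprintSet:
    """Hashed circular-substructure bit vectors (requires rdkit)."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bits = {}
    for did in sorted(smiles_map):
        mol = Chem.MolFromSmiles(smiles_map[did])
        if mol is None:
            raise ValidationError(f"unparseable SMILES for {did!r}: {smiles_map[did]!r}")
        fp = gen.GetFingerprint(mol)
        arr = np.zeros(n_bits, dtype=np.uint8)
        for b in fp.GetOnBits():
            arr[b] = 1
        bits[did] = arr
    return FingerprintSet(n_bits, bits)


def split_lcco(
    table: InteractionTable,
    fingerprints: FingerprintSet,
    k: int = 10,
    seed: int = 0,
    held_out_clusters: list[int] | None = None,
    fractions=(0.8, 0.1, 0.1),
) -> SplitSpec:
    """Cluster drugs by k-means on fingerprint bits; pack whole clusters into
    folds, greedily balancing interaction counts toward ``fractions``."""
    if k < 3 and held_out_clusters is None:
        raise ValueError("k must be >= 3 to fill three folds")
    drugs = table.unique_drugs()
    if k > len(drugs):
        raise ValueError(f"k={k} exceeds {len(drugs)} unique drugs")
    missing = [d for d in drugs if d not in fingerprints.bits]
    if missing:
        raise ValidationError(f"drugs without fingerprints: {missing}")
    X = fingerprints.matrix(drugs)

    degenerate = len(np.unique(X, axis=0)) < k
    if degenerate:
        cluster_of = {d: i % k for i, d in enumerate(drugs)}
    else:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        assignment = km.fit_predict(X)
        cluster_of = {d: int(c) for d, c in zip(drugs, assignment)}

    counts = np.zeros(k, dtype=int)
    for r in table:
        counts[cluster_of[r.drug_id]] += 1

    fr = _check_fractions(fractions)
    if held_out_clusters is not None:
        fold_of_cluster = {c: 2 for c in held_out_clusters}
        rest = [c for c in range(k) if c not in fold_of_cluster]
        # pack the remainder into train/val by the train:val ratio
        targets = np.array([fr[0], fr[1]], dtype=float)
        targets /= targets.sum()
        totals = np.zeros(2)
        for c in sorted(rest, key=lambda c: -counts[c]):
            load = totals / max(counts[rest].sum(), 1)
            fold_of_cluster[c] = int(np.argmin(load - targets))
            totals[fold_of_cluster[c]] += counts[c]
    else:
        targets = np.asarray(fr, dtype=float)
        targets = targets / targets.sum()
        totals = np.zeros(3)
        fold_of_cluster = {}
        for c in sorted(range(k), key=lambda c: -counts[c]):
            deficit = targets - totals / max(counts.sum(), 1)
            fold_of_cluster[c] = int(np.argmax(deficit))
            totals[fold_of_cluster[c]] += counts[c]

    folds = ([], [], [])
    for i, r in enumerate(table):
        folds[fold_of_cluster[cluster_of[r.drug_id]]].append(i)
    return SplitSpec(
        "lcco", seed, train_idx=folds[0], val_idx=folds[1], test_idx=folds[2],
        degenerate=degenerate,
    )


def split_entity_holdout(table: InteractionTable, entity: str, fractions, seed: int) -> SplitSpec:
    """Hold out whole drugs (``cold_drug``), targets (``lpo``) or both
    (``cold``).  For ``both``, a fold keeps only pairs whose two entities were
    assigned to that same fold; mixed pairs are discarded."""
    fr = _check_fractions(fractions)
    rng = np.random.default_rng(seed)

    def assign(ids: list[str]) -> dict[str, int]:
        ids = sorted(ids)
        n_tr, n_va, n_te = _partition_counts(len(ids), fr)
        perm = rng.permutation(len(ids))
        fold = {}
        for rank, pos in enumerate(perm):
            fold[ids[pos]] = 0 if rank < n_tr else 1 if rank < n_tr + n_va else 2 if rank < n_tr + n_va + n_te else -1
        return fold

    if entity == "target":
        fold_t = assign(table.unique_targets())
        folds = ([], [], [])
        for i, r in enumerate(table):
            f = fold_t[r.target_id]
            if f >= 0:
                folds[f].append(i)
        strategy = "lpo"
    elif entity == "drug":
        fold_d = assign(table.unique_drugs())
        folds = ([], [], [])
        for i, r in enumerate(table):
            f = fold_d[r.drug_id]
            if f >= 0:
                folds[f].append(i)
        strategy = "cold_drug"
    elif entity == "both":
        fold_d = assign(table.unique_drugs())
        fold_t = assign(table.unique_targets())
        folds = ([], [], [])
        for i, r in enumerate(table):
            fd, ft = fold_d[r.drug_id], fold_t[r.target_id]
            if fd == ft and fd >= 0:
                folds[fd].append(i)
        strategy = "cold"
    else:
        raise ValueError("entity must be one of {'drug', 'target', 'both'}")

    import warnings

    if any(len(f) == 0 for f in folds):
        warnings.warn(f"{strategy} split produced an empty fold", stacklevel=2)
    return SplitSpec(strategy, seed, train_idx=folds[0], val_idx=folds[1], test_idx=folds[2])


def validate_split(spec: SplitSpec, table: InteractionTable) -> list[SplitViolation]:
    """Report index overlaps, out-of-range indices and entity leakage between
    the train and test folds under the split's strategy."""
    violations: list[SplitViolation] = []
    sets = {
        "train": set(spec.train_idx),
        "val": set(spec.val_idx),
        "test": set(spec.test_idx),
    }
    for a, b in (("train", "val"), ("train", "test"), ("val", "test")):
        for i in sorted(sets[a] & sets[b]):
            violations.append(SplitViolation("index_overlap", f"index {i} in both {a} and {b}"))
    n = len(table)
    for name, s in sets.items():
        for i in sorted(s):
            if not 0 <= i < n:
                violations.append(SplitViolation("index_overlap", f"index {i} in {name} out of range"))
    entity_of = {"drug": lambda r: r.drug_id, "target": lambda r: r.target_id}
    for guard in _ENTITY_GUARDS[spec.strategy]:
        get = entity_of[guard]
        train_ents = {get(table[i]) for i in sets["train"] if 0 <= i < n}
        test_ents = {get(table[i]) for i in sets["test"] if 0 <= i < n}
        for e in sorted(train_ents & test_ents):
            violations.append(SplitViolation("entity_leak", f"{guard} {e!r} in both train and test"))
    return violations
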
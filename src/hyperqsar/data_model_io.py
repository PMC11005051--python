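"""Core record types and readers/writers.

Interaction tables are UTF-8 delimited text (tab or comma, auto-detected).
Embedding stores are either a TSV file (``id`` column followed by one column
per dimension) or an ``.npz`` archive with an ``ids`` string array and a
``vectors`` matrix.  Compounds come as one-SMILES-per-line files and protein
sequences as FASTA.
"""

from __future__ import annotations

import csv
import datetime as _dt
import os
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "InteractionRecord",
    "InteractionTable",
    "EmbeddingStore",
    "CoverageReport",
    "SchemaError",
    "ValidationError",
    "load_interaction_table",
    "write_interaction_table",
    "load_embeddings",
    "write_embeddings",
    "binarize_labels",
    "validate_coverage",
    "load_smiles",
    "load_fasta",
]


class SchemaError(ValueError):
    """A file does not match the expected column schema."""


class ValidationError(ValueError):
    """Data content violates an invariant (bad label, ragged vector, ...)."""


@dataclass(frozen=True)
class InteractionRecord:
    drug_id: str
    target_id: str
    label: float
    date: _dt.date | None = None

    def __post_init__(self):
        if not self.drug_id or not self.target_id:
            raise ValidationError("drug_id and target_id must be non-empty")
        if not np.isfinite(self.label):
            raise ValidationError(
                f"non-finite label for pair ({self.drug_id}, {self.target_id})"
            )


@dataclass
class InteractionTable:
    """Ordered list of labeled (drug, target) interactions."""

    records: list[InteractionRecord]
    label_kind: str = "continuous"  # {"continuous", "binary"}
    allow_duplicates: bool = False

    def __post_init__(self):
        if self.label_kind not in ("continuous", "binary"):
            raise ValidationError(f"unknown label_kind {self.label_kind!r}")
        if self.label_kind == "binary":
            bad = [r for r in self.records if r.label not in (0.0, 1.0)]
            if bad:
                raise ValidationError(
                    f"binary table contains non-binary labels, e.g. {bad[0]}"
                )
        if not self.allow_duplicates:
            seen = set()
            for r in self.records:
                key = (r.drug_id, r.target_id)
                if key in seen:
                    raise ValidationError(f"duplicate pair {key}")
                seen.add(key)

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def drug_ids(self) -> list[str]:
        return [r.drug_id for r in self.records]

    @property
    def target_ids(self) -> list[str]:
        return [r.target_id for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=float)

    def unique_drugs(self) -> list[str]:
        return sorted(set(self.drug_ids))

    def unique_targets(self) -> list[str]:
        return sorted(set(self.target_ids))

    def subset(self, indices) -> "InteractionTable":
        return InteractionTable(
            [self.records[i] for i in indices],
            label_kind=self.label_kind,
            allow_duplicates=True,
        )


@dataclass
class EmbeddingStore:
    """Map from entity id to a fixed-dimension real vector."""

    dim: int
    table: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.dim <= 0:
            raise ValidationError("embedding dimension must be positive")
        for k, v in self.table.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (self.dim,):
                raise ValidationError(
                    f"vector for {k!r} has shape {v.shape}, expected ({self.dim},)"
                )
            if not np.all(np.isfinite(v)):
                raise ValidationError(f"non-finite entries in vector for {k!r}")
            self.table[k] = v

    @classmethod
    def from_dict(cls, table: dict[str, np.ndarray]) -> "EmbeddingStore":
        if not table:
            raise ValidationError("empty embedding container")
        lengths = {len(np.atleast_1d(v)) for v in table.values()}
        if len(lengths) != 1:
            raise ValidationError(f"ragged vector lengths: {sorted(lengths)}")
        return cls(dim=lengths.pop(), table={k: np.asarray(v, float) for k, v in table.items()})

    def __contains__(self, key):
        return key in self.table

    def __getitem__(self, key) -> np.ndarray:
        return self.table[key]

    def __len__(self):
        return len(self.table)

    def ids(self) -> list[str]:
        return list(self.table)

    def matrix(self, ids) -> np.ndarray:
        """Stack vectors for ``ids`` into a (len(ids), dim) matrix."""
        return np.stack([self.table[i] for i in ids])


@dataclass
class CoverageReport:
    missing_drugs: list[str]
    missing_targets: list[str]

    @property
    def ok(self) -> bool:
        return not self.missing_drugs and not self.missing_targets


# ---------------------------------------------------------------------------
# interaction table IO
# ---------------------------------------------------------------------------

_DEFAULT_COLUMNS = {"drug_id": "drug_id", "target_id": "target_id", "label": "label", "date": "date"}


def _sniff_delimiter(path: str) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def _parse_date(text: str) -> _dt.date:
    text = text.strip()
    if len(text) == 4 and text.isdigit():  # bare year
        return _dt.date(int(text), 1, 1)
    return _dt.date.fromisoformat(text)


def load_interaction_table(
    path: str,
    column_map: dict | None = None,
    label_kind: str = "continuous",
    delimiter: str | None = None,
    allow_duplicates: bool = False,
) -> InteractionTable:
    """Parse a delimited interaction file into an :class:`InteractionTable`.

    ``column_map`` maps the logical names ``drug_id``/``target_id``/``label``
    (and optionally ``date``) to the file's column headers.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    cols = dict(_DEFAULT_COLUMNS)
    cols.update(column_map or {})
    delimiter = delimiter or _sniff_delimiter(path)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise ValidationError(f"empty interaction file: {path}")
        for logical in ("drug_id", "target_id", "label"):
            if cols[logical] not in reader.fieldnames:
                raise SchemaError(
                    f"missing column {cols[logical]!r} (for {logical}); "
                    f"found {reader.fieldnames}"
                )
        has_date = cols.get("date") in reader.fieldnames
        records = []
        for rownum, row in enumerate(reader, start=2):  # 1-based incl. header
            raw = row[cols["label"]]
            try:
                label = float(raw)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: unparseable label {raw!r} at row {rownum}"
                ) from None
            date = None
            if has_date and row[cols["date"]] not in (None, "", "NA"):
                date = _parse_date(row[cols["date"]])
            records.append(
                InteractionRecord(row[cols["drug_id"]], row[cols["target_id"]], label, date)
            )
    if not records:
        raise ValidationError(f"interaction file has no data rows: {path}")
    return InteractionTable(records, label_kind=label_kind, allow_duplicates=allow_duplicates)


def write_interaction_table(table: InteractionTable, path: str, delimiter: str = "\t") -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        has_date = any(r.date is not None for r in table.records)
        header = ["drug_id", "target_id", "label"] + (["date"] if has_date else [])
        writer.writerow(header)
        for r in table.records:
            row = [r.drug_id, r.target_id, repr(float(r.label))]
            if has_date:
                row.append(r.date.isoformat() if r.date else "")
            writer.writerow(row)


# ---------------------------------------------------------------------------
# embedding store IO
# ---------------------------------------------------------------------------


def load_embeddings(path: str) -> EmbeddingStore:
    """Load an embedding store from TSV text or an ``.npz`` archive."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.endswith(".npz"):
        with np.load(path, allow_pickle=False) as z:
            if "ids" not in z or "vectors" not in z:
                raise SchemaError("npz embedding archive needs 'ids' and 'vectors'")
            ids = [str(i) for i in z["ids"]]
            vectors = np.asarray(z["vectors"], dtype=float)
        if vectors.ndim != 2 or len(ids) != vectors.shape[0]:
            raise ValidationError("ids/vectors shape mismatch in embedding archive")
        table = {i: v for i, v in zip(ids, vectors)}
    else:
        table = {}
        lengths = set()
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                vec = np.array([float(p) for p in parts[1:]], dtype=float)
                table[parts[0]] = vec
                lengths.add(len(vec))
        if len(lengths) > 1:
            raise ValidationError(f"ragged vector lengths: {sorted(lengths)}")
    if not table:
        raise ValidationError(f"empty embedding container: {path}")
    store = EmbeddingStore.from_dict(table)
    return store


def write_embeddings(store: EmbeddingStore, path: str) -> None:
    if path.endswith(".npz"):
        ids = store.ids()
        np.savez(path, ids=np.array(ids), vectors=store.matrix(ids))
        return
    with open(path, "w", encoding="utf-8") as fh:
        for i in store.ids():
            fh.write(i + "\t" + "\t".join(repr(float(x)) for x in store[i]) + "\n")


# ---------------------------------------------------------------------------
# label transforms & checks
# ---------------------------------------------------------------------------


def binarize_labels(table: InteractionTable, threshold: float) -> InteractionTable:
    """Threshold continuous labels into {0, 1}; ties (== threshold) become 1."""
    if table.label_kind != "continuous":
        raise ValidationError("binarize_labels requires a continuous table")
    records = [replace(r, label=1.0 if r.label >= threshold else 0.0) for r in table.records]
    return InteractionTable(records, label_kind="binary", allow_duplicates=True)


def validate_coverage(
    table: InteractionTable, drug_store: EmbeddingStore, target_store: EmbeddingStore
) -> CoverageReport:
    missing_drugs = sorted({d for d in table.drug_ids if d not in drug_store})
    missing_targets = sorted({t for t in table.target_ids if t not in target_store})
    return CoverageReport(missing_drugs, missing_targets)


# ---------------------------------------------------------------------------
# sequence / compound bookkeeping
# ---------------------------------------------------------------------------


def load_smiles(path: str) -> dict[str, str]:
    """Read a .smi-style file: SMILES, whitespace, id — one compound per line."""
    out: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise SchemaError(f"{path}:{lineno}: expected 'SMILES id'")
            out[parts[1]] = parts[0]
    return out


def load_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
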
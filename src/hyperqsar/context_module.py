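"""Associative-memory enrichment of target embeddings.

A continuous modern Hopfield layer retrieves, for a query target embedding,
a softmax-weighted combination of the (normalized) training-target
embeddings.  Query, memory and output all pass through layer normalization;
the query/key (and optionally value) projections and the LayerNorm affine
parameters are trainable end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tensor import Tensor, softmax
from .data_model_io import EmbeddingStore

__all__ = ["ContextMemory", "HopfieldParams", "build_context", "enrich", "attention_weights"]

_EPS = 1e-5


def _layer_norm_np(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + _EPS)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor) -> Tensor:
    """Per-vector mean-0/var-1 normalization with learnable affine."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / (var + _EPS).sqrt() * gamma + beta


@dataclass
class ContextMemory:
    """T x d matrix of normalized unique training-target embeddings."""

    C: np.ndarray
    ids: list[str]

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        if self.C.ndim != 2 or self.C.shape[0] < 1:
            raise ValueError("memory must be a non-empty T x d matrix")
        if len(self.ids) != self.C.shape[0]:
            raise ValueError("ids length must match memory rows")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in context memory")

    @property
    def T_size(self) -> int:
        return self.C.shape[0]

    @property
    def dim(self) -> int:
        return self.C.shape[1]


@dataclass
class HopfieldParams:
    """Trainable maps and scale of the retrieval.

    ``value_map`` of None means the (normalized) memory rows are used as
    values directly.  ``beta`` defaults to 1/sqrt(d_assoc) when left None at
    construction via :func:`default_params`.
    """

    query_map: Tensor
    key_map: Tensor
    value_map: Tensor | None
    beta: float
    ln_query: tuple[Tensor, Tensor]
    ln_memory: tuple[Tensor, Tensor]
    ln_out: tuple[Tensor, Tensor]
    residual: bool = False

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.query_map.shape != self.key_map.shape:
            raise ValueError("query and key maps must share shape")

    def trainable(self) -> list[Tensor]:
        out = [self.query_map, self.key_map, *self.ln_query, *self.ln_memory, *self.ln_out]
        if self.value_map is not None:
            out.append(self.value_map)
        return [t for t in out if t.requires_grad]


def default_params(
    d: int,
    d_assoc: int | None = None,
    beta: float | None = None,
    identity_value: bool = True,
    residual: bool = False,
    rng: np.random.Generator | None = None,
    trainable: bool = True,
) -> HopfieldParams:
    rng = rng or np.random.default_rng(0)
    d_assoc = d_assoc or d
    beta = beta if beta is not None else 1.0 / np.sqrt(d_assoc)

    def lin(n_in, n_out):
        return Tensor(rng.standard_normal((n_in, n_out)) / np.sqrt(n_in), requires_grad=trainable)

    def ln(dim):
        return (Tensor(np.ones(dim), requires_grad=trainable), Tensor(np.zeros(dim), requires_grad=trainable))

    return HopfieldParams(
        query_map=lin(d, d_assoc),
        key_map=lin(d, d_assoc),
        value_map=None if identity_value else lin(d, d),
        beta=beta,
        ln_query=ln(d),
        ln_memory=ln(d),
        ln_out=ln(d),
        residual=residual,
    )


def identity_params(d: int, beta: float = 1.0) -> HopfieldParams:
    """Identity query/key maps and identity value — for analysis and tests."""
    eye = lambda: Tensor(np.eye(d))
    ones = lambda: Tensor(np.ones(d))
    zeros = lambda: Tensor(np.zeros(d))
    return HopfieldParams(
        query_map=eye(),
        key_map=eye(),
        value_map=None,
        beta=beta,
        ln_query=(ones(), zeros()),
        ln_memory=(ones(), zeros()),
        ln_out=(ones(), zeros()),
    )


def build_context(target_store: EmbeddingStore, train_target_ids) -> ContextMemory:
    """Memory of the unique training-target embeddings, rows mean-0/var-1
    normalized, ordered by sorted id."""
    ids = sorted(set(train_target_ids))
    if not ids:
        raise ValueError("train_target_ids is empty")
    missing = [i for i in ids if i not in target_store]
    if missing:
        raise KeyError(f"ids missing from target store: {missing}")
    C = _layer_norm_np(target_store.matrix(ids))
    return ContextMemory(C, ids)


def _retrieve(t, memory: ContextMemory, params: HopfieldParams):
    """Shared core: returns (attention Tensor (B,T), value rows Tensor (T,d),
    normalized query Tensor)."""
    t = t if isinstance(t, Tensor) else Tensor(t)
    squeeze = t.ndim == 1
    if squeeze:
        t = t.reshape(1, -1)
    if t.shape[1] != memory.dim:
        raise ValueError(f"query dim {t.shape[1]} != memory dim {memory.dim}")
    tq = layer_norm(t, *params.ln_query)
    M = layer_norm(Tensor(memory.C), *params.ln_memory)
    q = tq @ params.query_map
    K = M @ params.key_map
    logits = (q @ K.T) * params.beta
    attn = softmax(logits, axis=-1)
    V = M if params.value_map is None else M @ params.value_map
    return attn, V, tq, squeeze


def enrich(t, memory: ContextMemory, params: HopfieldParams):
    """Retrieve a context-enriched embedding; same dimension as the input.

    Returns a Tensor if ``t`` (or the params) participate in a gradient
    computation; call ``.numpy()`` for the plain array.
    """
    attn, V, tq, squeeze = _retrieve(t, memory, params)
    out = attn @ V
    if params.residual:
        out = out + tq
    out = layer_norm(out, *params.ln_out)
    return out.reshape(-1) if squeeze else out


def attention_weights(t, memory: ContextMemory, params: HopfieldParams) -> np.ndarray:
    """Length-T simplex vector (or B x T matrix) of retrieval weights."""
    attn, _, _, squeeze = _retrieve(t, memory, params)
    w = attn.numpy()
    return w[0] if squeeze else w
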
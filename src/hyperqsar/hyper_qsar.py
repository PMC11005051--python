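"""Hypernetwork and the functional per-target prediction network.

The hypernetwork is a fully connected trunk followed by one linear *head*
per parameter block (weight matrix or bias vector) of the main network.
Head weights are initialized so that parameters emitted at initialization
give the main network a distribution-preserving forward pass:

- weight head for a main layer of fan-in ``d_in``:
  ``Var(H) = g / (2 * d_in * c_in * var_t)`` where ``c_in`` is the trunk
  output width, ``var_t`` the per-entry variance of the head input, and
  ``g = 2`` when the layer's output feeds a relu (no gain on the last layer);
- bias head: ``Var(G) = 1 / (2 * c_in * var_t)``;

so the weight and bias contributions each carry half of the target variance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._tensor import Tensor, concat
from .context_module import (
    ContextMemory,
    HopfieldParams,
    build_context,
    default_params,
    enrich,
)
from .data_model_io import EmbeddingStore

__all__ = [
    "MainNetSpec",
    "ParamSchema",
    "ParamEntry",
    "HyperNetSpec",
    "HyperNetState",
    "build_param_schema",
    "pwi_initialize",
    "naive_initialize",
    "hyper_forward",
    "distribute",
    "flatten_params",
    "qsar_forward",
    "HyperQSAR",
]


@dataclass(frozen=True)
class MainNetSpec:
    """Feed-forward main network: ``layer_dims = [d_in, h_1, ..., 1]``."""

    layer_dims: tuple
    activation: str = "relu"  # hidden activation: {"relu", "linear"}
    output_activation: str = "identity"  # {"identity", "sigmoid"}

    def __post_init__(self):
        object.__setattr__(self, "layer_dims", tuple(int(d) for d in self.layer_dims))
        if len(self.layer_dims) < 3:
            raise ValueError("main network needs at least one hidden layer")
        if any(d <= 0 for d in self.layer_dims):
            raise ValueError("layer dims must be positive")
        if self.layer_dims[-1] != 1:
            raise ValueError("main network output must be scalar")
        if self.activation not in ("relu", "linear"):
            raise ValueError("activation must be 'relu' or 'linear'")
        if self.output_activation not in ("identity", "sigmoid"):
            raise ValueError("output_activation must be 'identity' or 'sigmoid'")

    @property
    def n_layers(self) -> int:
        return len(self.layer_dims) - 1


@dataclass(frozen=True)
class ParamEntry:
    name: str
    shape: tuple
    fan_in: int

    @property
    def size(self) -> int:
        return int(np.prod(self.shape))


@dataclass(frozen=True)
class ParamSchema:
    entries: tuple

    @property
    def total_count(self) -> int:
        return sum(e.size for e in self.entries)

    def offsets(self):
        off = 0
        for e in self.entries:
            yield e, off, off + e.size
            off += e.size


def build_param_schema(main_spec: MainNetSpec) -> ParamSchema:
    """Enumerate W then b per layer, first layer to last."""
    entries = []
    dims = main_spec.layer_dims
    for layer in range(main_spec.n_layers):
        d_in, d_out = dims[layer], dims[layer + 1]
        entries.append(ParamEntry(f"W{layer + 1}", (d_out, d_in), d_in))
        entries.append(ParamEntry(f"b{layer + 1}", (d_out,), d_in))
    return ParamSchema(tuple(entries))


@dataclass(frozen=True)
class HyperNetSpec:
    """Trunk of the hypernetwork; ``trunk_dims[0]`` is the (enriched) target
    embedding dimension and ``trunk_dims[-1]`` the head input width c_in.
    A single-element ``trunk_dims`` means the heads read the embedding
    directly."""

    trunk_dims: tuple
    dropout: float = 0.0
    activation: str = "relu"

    def __post_init__(self):
        object.__setattr__(self, "trunk_dims", tuple(int(d) for d in self.trunk_dims))
        if len(self.trunk_dims) < 1 or any(d <= 0 for d in self.trunk_dims):
            raise ValueError("trunk_dims must be a non-empty list of positive ints")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def c_in(self) -> int:
        return self.trunk_dims[-1]


@dataclass
class HyperNetState:
    spec: HyperNetSpec
    schema: ParamSchema
    main_spec: MainNetSpec
    trunk: list  # list of (W Tensor, b Tensor)
    heads: dict  # entry name -> (H Tensor (c_in, size), bias Tensor (size,))
    var_t: float

    def trainable(self) -> list[Tensor]:
        out = []
        for W, b in self.trunk:
            out += [W, b]
        for H, hb in self.heads.values():
            out += [H, hb]
        return out


def _head_variances(entry: ParamEntry, main_spec: MainNetSpec, c_in: int, var_t: float):
    """PWI variance for one head; relu gain on hidden-layer weight heads."""
    layer = int(entry.name[1:]) - 1
    feeds_relu = main_spec.activation == "relu" and layer < main_spec.n_layers - 1
    if entry.name.startswith("W"):
        gain = 2.0 if feeds_relu else 1.0
        return gain / (2.0 * entry.fan_in * c_in * var_t)
    return 1.0 / (2.0 * c_in * var_t)


def pwi_initialize(
    hyper_spec: HyperNetSpec,
    schema: ParamSchema,
    var_t: float,
    main_spec: MainNetSpec | None = None,
    rng: np.random.Generator | None = None,
    calibration: np.ndarray | None = None,
) -> HyperNetState:
    """Initialize trunk (fan-in preserving, zero biases) and heads (PWI).

    When ``calibration`` (a sample of hypernetwork inputs, one per row) is
    given, the head variance uses the empirical per-entry variance of the
    trunk *output* on that sample instead of ``var_t`` — this keeps the head
    scaling exact when relu trunks shift the variance seen by the heads.
    """
    if var_t <= 0:
        raise ValueError("var_t must be positive")
    rng = rng or np.random.default_rng(0)
    if main_spec is None:
        # infer from schema: dims are fan_ins of the W entries plus final 1
        dims = [e.fan_in for e in schema.entries if e.name.startswith("W")] + [1]
        main_spec = MainNetSpec(tuple(dims))
    trunk = []
    dims = hyper_spec.trunk_dims
    for i in range(len(dims) - 1):
        gain = 2.0 if hyper_spec.activation == "relu" else 1.0
        W = rng.standard_normal((dims[i], dims[i + 1])) * np.sqrt(gain / dims[i])
        trunk.append((Tensor(W, requires_grad=True), Tensor(np.zeros(dims[i + 1]), requires_grad=True)))
    if calibration is not None:
        a = np.atleast_2d(np.asarray(calibration, dtype=float))
        for W, b in trunk:
            a = a @ W.numpy() + b.numpy()
            if hyper_spec.activation == "relu":
                a = np.maximum(a, 0.0)
        var_t = max(float(np.mean(np.var(a, axis=0))), 1e-8)
    heads = {}
    for entry in schema.entries:
        var = _head_variances(entry, main_spec, hyper_spec.c_in, var_t)
        H = rng.standard_normal((hyper_spec.c_in, entry.size)) * np.sqrt(var)
        heads[entry.name] = (
            Tensor(H, requires_grad=True),
            Tensor(np.zeros(entry.size), requires_grad=True),
        )
    return HyperNetState(hyper_spec, schema, main_spec, trunk, heads, var_t)


def naive_initialize(
    hyper_spec: HyperNetSpec,
    schema: ParamSchema,
    main_spec: MainNetSpec | None = None,
    rng: np.random.Generator | None = None,
) -> HyperNetState:
    """Control init: plain fan-in scaling on the heads (no PWI correction)."""
    rng = rng or np.random.default_rng(0)
    state = pwi_initialize(hyper_spec, schema, 1.0, main_spec, rng)
    for entry in schema.entries:
        H = rng.standard_normal((hyper_spec.c_in, entry.size)) / np.sqrt(hyper_spec.c_in)
        state.heads[entry.name] = (
            Tensor(H, requires_grad=True),
            Tensor(np.zeros(entry.size), requires_grad=True),
        )
    return state


def hyper_forward(
    t_enriched,
    state: HyperNetState,
    training: bool = False,
    rng: np.random.Generator | None = None,
):
    """Map (batch of) enriched target embeddings to flat parameter vectors.

    Returns a Tensor of shape (B, total_count); 1-D input gives (total_count,).
    """
    t = t_enriched if isinstance(t_enriched, Tensor) else Tensor(t_enriched)
    squeeze = t.ndim == 1
    if squeeze:
        t = t.reshape(1, -1)
    if t.shape[1] != state.spec.trunk_dims[0]:
        raise ValueError(
            f"input dim {t.shape[1]} != trunk input {state.spec.trunk_dims[0]}"
        )
    a = t
    relu = state.spec.activation == "relu"
    for W, b in state.trunk:
        a = a @ W + b
        if relu:
            a = a.relu()
        if training and state.spec.dropout > 0:
            rng = rng or np.random.default_rng(0)
            mask = (rng.random(a.shape) >= state.spec.dropout) / (1 - state.spec.dropout)
            a = a * Tensor(mask)
    pieces = [a @ H + hb for H, hb in (state.heads[e.name] for e in state.schema.entries)]
    flat = concat(pieces, axis=1)
    return flat.reshape(-1) if squeeze else flat


def distribute(flat, schema: ParamSchema):
    """Reshape a flat parameter vector into per-entry arrays (row-major, in
    schema order).  Works on numpy arrays and Tensors alike."""
    if flat.ndim != 1:
        raise ValueError("distribute expects a 1-D flat vector")
    n = flat.shape[0]
    if n != schema.total_count:
        raise ValueError(f"flat length {n} != schema total {schema.total_count}")
    out = {}
    for entry, lo, hi in schema.offsets():
        block = flat[lo:hi]
        out[entry.name] = block.reshape(*entry.shape)
    return out


def flatten_params(params: dict, schema: ParamSchema) -> np.ndarray:
    parts = []
    for entry in schema.entries:
        arr = params[entry.name]
        arr = arr.numpy() if isinstance(arr, Tensor) else np.asarray(arr)
        parts.append(arr.reshape(-1))
    return np.concatenate(parts)


def qsar_forward(x, params: dict, main_spec: MainNetSpec):
    """Forward pass of the main network with externally supplied parameters.

    ``x`` is (B, d_in) or (d_in,); returns predictions of shape (B,) / scalar.
    """
    xt = x if isinstance(x, Tensor) else Tensor(x)
    squeeze = xt.ndim == 1
    if squeeze:
        xt = xt.reshape(1, -1)
    if xt.shape[1] != main_spec.layer_dims[0]:
        raise ValueError(f"input dim {xt.shape[1]} != {main_spec.layer_dims[0]}")
    a = xt
    for layer in range(main_spec.n_layers):
        W = params[f"W{layer + 1}"]
        b = params[f"b{layer + 1}"]
        W = W if isinstance(W, Tensor) else Tensor(W)
        b = b if isinstance(b, Tensor) else Tensor(b)
        a = a @ W.T + b.reshape(1, -1)
        if layer < main_spec.n_layers - 1 and main_spec.activation == "relu":
            a = a.relu()
    if main_spec.output_activation == "sigmoid":
        a = a.sigmoid()
    return a.reshape(-1)


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------


class HyperQSAR:
    """Context enrichment -> hypernetwork -> per-target prediction network.

    Parameters are predicted once per unique target and cached at inference;
    the cache is cleared whenever trainable parameters change.
    """

    def __init__(
        self,
        main_spec: MainNetSpec,
        hyper_spec: HyperNetSpec,
        use_context: bool = True,
        d_assoc: int | None = None,
        beta: float | None = None,
        identity_value: bool = True,
        residual: bool = False,
        seed: int = 0,
    ):
        self.main_spec = main_spec
        self.hyper_spec = hyper_spec
        self.schema = build_param_schema(main_spec)
        self.use_context = use_context
        self.seed = seed
        self._rng = np.random.default_rng(seed)
        self.memory: ContextMemory | None = None
        self.hopfield: HopfieldParams | None = None
        if use_context:
            self.hopfield = default_params(
                hyper_spec.trunk_dims[0],
                d_assoc=d_assoc,
                beta=beta,
                identity_value=identity_value,
                residual=residual,
                rng=self._rng,
            )
        self.state: HyperNetState | None = None
        self._param_cache: dict[str, np.ndarray] = {}

    # -- setup ---------------------------------------------------------------
    def fit_context(self, target_store: EmbeddingStore, train_target_ids) -> None:
        """Build the context memory from *training* targets only, then apply
        PWI using the empirical variance of the enriched train embeddings."""
        if self.use_context:
            self.memory = build_context(target_store, train_target_ids)
            enriched = self.enrich_targets(target_store.matrix(self.memory.ids)).numpy()
        else:
            ids = sorted(set(train_target_ids))
            enriched = target_store.matrix(ids)
        var_t = float(np.mean(np.var(enriched, axis=0)))
        var_t = max(var_t, 1e-8)
        self.state = pwi_initialize(
            self.hyper_spec, self.schema, var_t, self.main_spec, self._rng,
            calibration=enriched,
        )
        self._param_cache.clear()

    # -- forward pieces ------------------------------------------------------
    def enrich_targets(self, T_batch):
        if not self.use_context:
            return T_batch if isinstance(T_batch, Tensor) else Tensor(T_batch)
        if self.memory is None:
            raise RuntimeError("context memory not built; call fit_context first")
        return enrich(T_batch, self.memory, self.hopfield)

    def predict_flat(self, t_vectors, training: bool = False, rng=None) -> Tensor:
        if self.state is None:
            raise RuntimeError("model not initialized; call fit_context first")
        t_enr = self.enrich_targets(t_vectors)
        return hyper_forward(t_enr, self.state, training=training, rng=rng)

    def predict(self, x_batch, t_vector) -> np.ndarray:
        """Predictions for a batch of drug embeddings against one target."""
        flat = self.predict_flat(np.asarray(t_vector))
        params = distribute(flat, self.schema)
        return qsar_forward(np.asarray(x_batch), params, self.main_spec).numpy()

    def predict_pair(
        self, drug_id: str, target_id: str, drug_store: EmbeddingStore, target_store: EmbeddingStore
    ) -> float:
        if drug_id not in drug_store:
            raise KeyError(f"unknown drug id {drug_id!r}")
        if target_id not in target_store:
            raise KeyError(f"unknown target id {target_id!r}")
        flat = self._cached_flat(target_id, target_store)
        params = distribute(flat, self.schema)
        out = qsar_forward(drug_store[drug_id], params, self.main_spec).numpy()
        return float(out[0])

    def predict_table(self, drug_ids, target_ids, drug_store, target_store) -> np.ndarray:
        """Vectorized prediction for parallel id lists; one hypernetwork call
        per unique target."""
        out = np.empty(len(drug_ids))
        by_target: dict[str, list[int]] = {}
        for i, t in enumerate(target_ids):
            by_target.setdefault(t, []).append(i)
        for t, idxs in by_target.items():
            flat = self._cached_flat(t, target_store)
            params = distribute(flat, self.schema)
            X = np.stack([drug_store[drug_ids[i]] for i in idxs])
            out[idxs] = qsar_forward(X, params, self.main_spec).numpy()
        return out

    def _cached_flat(self, target_id: str, target_store: EmbeddingStore) -> np.ndarray:
        if target_id not in self._param_cache:
            flat = self.predict_flat(target_store[target_id])
            self._param_cache[target_id] = flat.numpy()
        return self._param_cache[target_id]

    def clear_cache(self) -> None:
        self._param_cache.clear()

    # -- parameter plumbing --------------------------------------------------
    def parameters(self) -> list[Tensor]:
        if self.state is None:
            raise RuntimeError("model not initialized")
        params = list(self.state.trainable())
        if self.use_context and self.hopfield is not None:
            params += self.hopfield.trainable()
        return params

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            p.data = w.copy()
        self._param_cache.clear()

    # -- persistence ---------------------------------------------------------
    def save(self, path: str, extra: dict | None = None) -> None:
        blob = {
            "config": {
                "main_layer_dims": list(self.main_spec.layer_dims),
                "main_activation": self.main_spec.activation,
                "output_activation": self.main_spec.output_activation,
                "trunk_dims": list(self.hyper_spec.trunk_dims),
                "dropout": self.hyper_spec.dropout,
                "use_context": self.use_context,
                "seed": self.seed,
                "var_t": self.state.var_t if self.state else None,
                "beta": self.hopfield.beta if self.hopfield else None,
                "residual": self.hopfield.residual if self.hopfield else False,
                "identity_value": self.hopfield.value_map is None if self.hopfield else True,
            },
            "memory": {
                "ids": self.memory.ids if self.memory else None,
                "C": self.memory.C.tolist() if self.memory else None,
            },
            "weights": [w.tolist() for w in self.get_weights()],
            "manifest": extra or {},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(blob, fh)

    @classmethod
    def load(cls, path: str) -> "HyperQSAR":
        with open(path, "r", encoding="utf-8") as fh:
            blob = json.load(fh)
        cfg = blob["config"]
        model = cls(
            MainNetSpec(
                tuple(cfg["main_layer_dims"]),
                cfg["main_activation"],
                cfg["output_activation"],
            ),
            HyperNetSpec(tuple(cfg["trunk_dims"]), cfg["dropout"]),
            use_context=cfg["use_context"],
            beta=cfg["beta"],
            identity_value=cfg["identity_value"],
            residual=cfg["residual"],
            seed=cfg["seed"],
        )
        if blob["memory"]["ids"] is not None:
            model.memory = ContextMemory(np.array(blob["memory"]["C"]), blob["memory"]["ids"])
        model.state = pwi_initialize(
            model.hyper_spec, model.schema, cfg["var_t"] or 1.0, model.main_spec, model._rng
        )
        model.set_weights([np.array(w) for w in blob["weights"]])
        return model
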
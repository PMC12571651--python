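"""Trainable adapter components.

Two families are implemented as pure array operations:

* a *reversible* adapter — an additive coupling layer whose inverse is
  available in closed form, so embeddings can be mapped into and out of
  the adapted space without information loss;
* *bottleneck* adapters (language / task roles) — down-projection, ReLU,
  up-projection with a residual connection, stacked and followed by layer
  normalization inside a transformer block ("transformer-adapt" layer).

All maps are stored as ``(in_dim, out_dim)`` weight matrices applied as
``x @ W + b`` so the same arrays can back both the functional API here and
the autograd graph in :mod:`clinvla.models`.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import AdapterConfig

__all__ = [
    "AffineMap",
    "ReversibleAdapterParams",
    "BottleneckAdapterParams",
    "LayerState",
    "he_init",
    "reversible_forward",
    "reversible_inverse",
    "language_adapter_apply",
    "task_adapter_apply",
    "layer_norm",
    "transformer_adapt_layer",
    "save_adapter_archive",
    "load_adapter_archive",
]


@dataclass
class AffineMap:
    """x -> x @ weight + bias, with weight of shape (in_dim, out_dim)."""

    weight: np.ndarray
    bias: np.ndarray | None = None

    @classmethod
    def zeros(cls, in_dim: int, out_dim: int, use_bias: bool = True,
              dtype=np.float64) -> "AffineMap":
        return cls(
            weight=np.zeros((in_dim, out_dim), dtype=dtype),
            bias=np.zeros(out_dim, dtype=dtype) if use_bias else None,
        )

    @property
    def in_dim(self) -> int:
        return self.weight.shape[0]

    @property
    def out_dim(self) -> int:
        return self.weight.shape[1]

    def __call__(self, x: np.ndarray) -> np.ndarray:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


@dataclass
class ReversibleAdapterParams:
    """Coupling-layer weights: F(x) = U_F @ ReLU(D_F @ x), likewise G."""

    D_F: AffineMap
    U_F: AffineMap
    D_G: AffineMap
    U_G: AffineMap

    @classmethod
    def zeros(cls, h: int, use_bias: bool = True, dtype=np.float64):
        if h % 4 != 0:
            raise ValueError(f"h must be divisible by 4, got {h}")
        half, quarter = h // 2, h // 4
        return cls(
            D_F=AffineMap.zeros(half, quarter, use_bias, dtype),
            U_F=AffineMap.zeros(quarter, half, use_bias, dtype),
            D_G=AffineMap.zeros(half, quarter, use_bias, dtype),
            U_G=AffineMap.zeros(quarter, half, use_bias, dtype),
        )

    @property
    def h(self) -> int:
        return 2 * self.D_F.in_dim

    def named_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for name in ("D_F", "U_F", "D_G", "U_G"):
            m: AffineMap = getattr(self, name)
            out[f"{prefix}{name}.weight"] = m.weight
            if m.bias is not None:
                out[f"{prefix}{name}.bias"] = m.bias
        return out


@dataclass
class BottleneckAdapterParams:
    """Down/up projection pair with a role tag ('language' or 'task')."""

    D: AffineMap
    U: AffineMap
    role: str = "language"

    def __post_init__(self):
        if self.role not in ("language", "task"):
            raise ValueError(f"role must be 'language' or 'task', got {self.role!r}")

    @classmethod
    def zeros(cls, h: int, d: int, role: str = "language", use_bias: bool = True,
              dtype=np.float64):
        return cls(D=AffineMap.zeros(h, d, use_bias, dtype),
                   U=AffineMap.zeros(d, h, use_bias, dtype), role=role)

    @property
    def h(self) -> int:
        return self.D.in_dim

    @property
    def d(self) -> int:
        return self.D.out_dim

    def named_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {f"{prefix}D.weight": self.D.weight, f"{prefix}U.weight": self.U.weight}
        if self.D.bias is not None:
            out[f"{prefix}D.bias"] = self.D.bias
        if self.U.bias is not None:
            out[f"{prefix}U.bias"] = self.U.bias
        return out


@dataclass
class LayerState:
    """Hidden state and feed-forward residual at one transformer layer."""

    hidden: np.ndarray
    residual: np.ndarray

    def __post_init__(self):
        if np.shape(self.hidden)[-1] != np.shape(self.residual)[-1]:
            raise ValueError(
                "hidden and residual must share the last dimension: "
                f"{np.shape(self.hidden)} vs {np.shape(self.residual)}"
            )


# --------------------------------------------------------------------------
# initialization
# --------------------------------------------------------------------------

def he_init(params, seed: int):
    """Initialize all affine maps in `params` in place with the He scheme.

    Weights are drawn i.i.d. Normal(0, 2/fan_in) — the variance-preserving
    choice for ReLU-followed affine maps — and biases are set to zero.
    Deterministic for a fixed seed.  Returns `params` for chaining.
    """
    rng = np.random.default_rng(seed)
    if isinstance(params, ReversibleAdapterParams):
        maps = [params.D_F, params.U_F, params.D_G, params.U_G]
    elif isinstance(params, BottleneckAdapterParams):
        maps = [params.D, params.U]
    else:
        raise TypeError(f"cannot He-initialize {type(params).__name__}")
    for m in maps:
        std = np.sqrt(2.0 / m.in_dim)
        m.weight[...] = rng.normal(0.0, std, size=m.weight.shape)
        if m.bias is not None:
            m.bias[...] = 0.0
    return params


# --------------------------------------------------------------------------
# reversible adapter
# --------------------------------------------------------------------------

def _coupling_fn(down: AffineMap, up: AffineMap, x: np.ndarray) -> np.ndarray:
    return up(np.maximum(down(x), 0.0))


def _check_last_dim(v: np.ndarray, expected: int, what: str):
    if v.shape[-1] != expected:
        raise ValueError(
            f"{what}: last dimension is {v.shape[-1]}, adapter expects {expected}"
        )


def reversible_forward(e: np.ndarray, params: ReversibleAdapterParams) -> np.ndarray:
    """o1 = F(e2) + e1; o2 = G(o1) + e2; return [o1, o2].

    `e` is split into first-half / second-half along its last axis; works on
    single vectors or stacks of vectors.
    """
    e = np.asarray(e, dtype=np.result_type(e, np.float32))
    _check_last_dim(e, params.h, "reversible_forward input")
    half = params.h // 2
    e1, e2 = e[..., :half], e[..., half:]
    o1 = _coupling_fn(params.D_F, params.U_F, e2) + e1
    o2 = _coupling_fn(params.D_G, params.U_G, o1) + e2
    return np.concatenate([o1, o2], axis=-1)


def reversible_inverse(o: np.ndarray, params: ReversibleAdapterParams) -> np.ndarray:
    """Exact inverse of :func:`reversible_forward` with the same params:
    e2 = o2 - G(o1); e1 = o1 - F(e2); return [e1, e2]."""
    o = np.asarray(o, dtype=np.result_type(o, np.float32))
    _check_last_dim(o, params.h, "reversible_inverse input")
    half = params.h // 2
    o1, o2 = o[..., :half], o[..., half:]
    e2 = o2 - _coupling_fn(params.D_G, params.U_G, o1)
    e1 = o1 - _coupling_fn(params.D_F, params.U_F, e2)
    return np.concatenate([e1, e2], axis=-1)


# --------------------------------------------------------------------------
# bottleneck adapters and the transformer-adapt layer
# --------------------------------------------------------------------------

def language_adapter_apply(state: LayerState,
                           params: BottleneckAdapterParams) -> np.ndarray:
    """U(ReLU(D(hidden))) + residual."""
    if params.role != "language":
        raise ValueError(f"expected a language adapter, got role={params.role!r}")
    _check_last_dim(np.asarray(state.hidden), params.h, "language adapter input")
    return _coupling_fn(params.D, params.U, np.asarray(state.hidden)) + state.residual


def task_adapter_apply(la_out: np.ndarray, residual: np.ndarray,
                       params: BottleneckAdapterParams) -> np.ndarray:
    """U(ReLU(D(la_out))) + residual — the residual is added outside the
    nonlinearity."""
    if params.role != "task":
        raise ValueError(f"expected a task adapter, got role={params.role!r}")
    la_out = np.asarray(la_out)
    _check_last_dim(la_out, params.h, "task adapter input")
    return _coupling_fn(params.D, params.U, la_out) + np.asarray(residual)


def layer_norm(x: np.ndarray, gain: np.ndarray | None = None,
               shift: np.ndarray | None = None, eps: float = 1e-6) -> np.ndarray:
    """Normalize over the last axis to zero mean / unit variance, then apply
    the optional affine gain and shift."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    y = (x - mu) / np.sqrt(var + eps)
    if gain is not None:
        y = y * gain
    if shift is not None:
        y = y + shift
    return y


def transformer_adapt_layer(state: LayerState,
                            lang: BottleneckAdapterParams,
                            task: BottleneckAdapterParams,
                            ln_gain: np.ndarray | None = None,
                            ln_shift: np.ndarray | None = None) -> np.ndarray:
    """Language adapter, then task adapter (both residual), then layer norm."""
    h = np.shape(state.hidden)[-1]
    if h < 2:
        raise ValueError(f"layer norm is degenerate for h={h} < 2")
    la = language_adapter_apply(state, lang)
    ta = task_adapter_apply(la, state.residual, task)
    return layer_norm(ta, gain=ln_gain, shift=ln_shift)


# --------------------------------------------------------------------------
# checkpoint archive: flat named arrays + JSON manifest
# --------------------------------------------------------------------------

def save_adapter_archive(path, arrays: dict[str, np.ndarray],
                         config: AdapterConfig, roles: dict[str, str] | None = None):
    """Write named arrays and a JSON manifest into one zip archive."""
    path = Path(path)
    manifest = {
        "h": config.h,
        "d": config.d,
        "use_bias": config.use_bias,
        "roles": roles or {},
        "arrays": {k: list(v.shape) for k, v in arrays.items()},
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=1))
        for k, v in arrays.items():
            zf.writestr(k + ".npy", _npy_bytes(v))


def _npy_bytes(arr: np.ndarray) -> bytes:
    import io

    buf = io.BytesIO()
    np.save(buf, arr, allow_pickle=False)
    return buf.getvalue()


def load_adapter_archive(path, config: AdapterConfig | None = None):
    """Load an adapter archive; validates shapes against `config` if given.

    Returns (arrays, manifest).
    """
    import io

    path = Path(path)
    with zipfile.ZipFile(path, "r") as zf:
        manifest = json.loads(zf.read("manifest.json"))
        arrays = {}
        for k, shape in manifest["arrays"].items():
            arr = np.load(io.BytesIO(zf.read(k + ".npy")), allow_pickle=False)
            if list(arr.shape) != list(shape):
                raise ValueError(f"array {k!r}: stored shape {arr.shape} "
                                 f"does not match manifest {shape}")
            arrays[k] = arr
    if config is not None:
        if manifest["h"] != config.h or manifest["d"] != config.d:
            raise ValueError(
                f"archive was built for h={manifest['h']}, d={manifest['d']}; "
                f"requested h={config.h}, d={config.d}"
            )
    return arrays, manifest
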
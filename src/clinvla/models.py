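"""Dual-encoder model: small frozen transformer backbones with trainable
adapters (reversible adapter at the embeddings, language/task bottleneck
adapters plus a layer norm inside every block).

Backbone weights are plain frozen arrays; adapter weights live in
:class:`~clinvla.adapters` parameter containers and are wrapped as autograd
tensors *sharing the same memory*, so the functional adapter API and the
differentiable graph always agree.
"""

from __future__ import annotations

import numpy as np

from .adapters import (
    BottleneckAdapterParams,
    ReversibleAdapterParams,
    he_init,
)
from .autograd import Tensor, cat
from .config import ModelConfig

__all__ = ["ClinVLAModel", "build_model"]

_EPS = 1e-6


def _ln(x: Tensor, gain: Tensor | None = None, shift: Tensor | None = None) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) * (x - mu)).mean(axis=-1, keepdims=True)
    y = (x - mu) / (var + _EPS).sqrt()
    if gain is not None:
        y = y * gain
    if shift is not None:
        y = y + shift
    return y


def _affine(x: Tensor, weight: Tensor, bias: Tensor | None) -> Tensor:
    y = x @ weight
    if bias is not None:
        y = y + bias
    return y


class _FrozenBlock:
    """One frozen transformer block: self-attention + FFN (weights constant),
    hosting trainable language/task adapters and their layer norm."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, tag: str):
        h, hd = cfg.h, cfg.h // cfg.n_heads
        if cfg.h % cfg.n_heads:
            raise ValueError("h must be divisible by n_heads")
        s = 1.0 / np.sqrt(h)
        self.cfg = cfg
        self.tag = tag
        # frozen backbone weights (plain constants)
        self.Wq = Tensor(rng.normal(0, s, (h, h)))
        self.Wk = Tensor(rng.normal(0, s, (h, h)))
        self.Wv = Tensor(rng.normal(0, s, (h, h)))
        self.Wo = Tensor(rng.normal(0, s, (h, h)))
        f = cfg.ffn_mult * h
        self.W1 = Tensor(rng.normal(0, s, (h, f)))
        self.b1 = Tensor(np.zeros(f))
        self.W2 = Tensor(rng.normal(0, np.sqrt(1.0 / f), (f, h)))
        self.b2 = Tensor(np.zeros(h))
        self.ln1_g = Tensor(np.ones(h))
        self.ln1_b = Tensor(np.zeros(h))
        # trainable adapters (shared-memory numpy containers + tensors)
        self.lang = he_init(BottleneckAdapterParams.zeros(h, cfg.d, "language",
                                                          cfg.use_bias),
                            seed=int(rng.integers(2**31)))
        self.task = he_init(BottleneckAdapterParams.zeros(h, cfg.d, "task",
                                                          cfg.use_bias),
                            seed=int(rng.integers(2**31)))
        # zero the up-projections so the adapter stack starts as a no-op
        self.lang.U.weight[...] = 0.0
        self.task.U.weight[...] = 0.0
        self.t_lang = _wrap_bottleneck(self.lang)
        self.t_task = _wrap_bottleneck(self.task)
        self.ln2_g = Tensor(np.ones(h), requires_grad=True)
        self.ln2_b = Tensor(np.zeros(h), requires_grad=True)

    def backbone_arrays(self) -> dict[str, np.ndarray]:
        return {f"{self.tag}.{n}": getattr(self, n).data
                for n in ("Wq", "Wk", "Wv", "Wo", "W1", "b1", "W2", "b2",
                          "ln1_g", "ln1_b")}

    def trainable(self) -> dict[str, Tensor]:
        out = {}
        for fam, d in (("language_adapter", self.t_lang),
                       ("task_adapter", self.t_task)):
            for k, t in d.items():
                out[f"{self.tag}.{fam}.{k}"] = t
        out[f"{self.tag}.adapter_ln.gain"] = self.ln2_g
        out[f"{self.tag}.adapter_ln.shift"] = self.ln2_b
        return out

    def __call__(self, x: Tensor) -> Tensor:
        # x: (B, K, h)
        cfg = self.cfg
        nh, hd = cfg.n_heads, cfg.h // cfg.n_heads
        B, K, h = x.shape

        def heads(t: Tensor) -> Tensor:
            return t.reshape(B, K, nh, hd).swapaxes(1, 2)  # (B, nh, K, hd)

        q, k, v = heads(x @ self.Wq), heads(x @ self.Wk), heads(x @ self.Wv)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(hd))
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).swapaxes(1, 2).reshape(B, K, h)
        a = _ln(x + ctx @ self.Wo, self.ln1_g, self.ln1_b)  # residual stream r_l
        hidden = _affine(_affine(a, self.W1, self.b1).relu(), self.W2, self.b2)
        # transformer-adapt: language adapter, task adapter, layer norm
        la = _bottleneck(hidden, self.t_lang) + a
        ta = _bottleneck(la, self.t_task) + a
        return _ln(ta, self.ln2_g, self.ln2_b)


def _wrap_bottleneck(p: BottleneckAdapterParams) -> dict[str, Tensor]:
    out = {
        "D.weight": Tensor(p.D.weight, requires_grad=True),
        "U.weight": Tensor(p.U.weight, requires_grad=True),
    }
    # keep the exact arrays so the functional API sees optimizer updates
    out["D.weight"].data = p.D.weight
    out["U.weight"].data = p.U.weight
    if p.D.bias is not None:
        out["D.bias"] = Tensor(p.D.bias, requires_grad=True)
        out["D.bias"].data = p.D.bias
    if p.U.bias is not None:
        out["U.bias"] = Tensor(p.U.bias, requires_grad=True)
        out["U.bias"].data = p.U.bias
    return out


def _bottleneck(x: Tensor, t: dict[str, Tensor]) -> Tensor:
    y = _affine(x, t["D.weight"], t.get("D.bias")).relu()
    return _affine(y, t["U.weight"], t.get("U.bias"))


def _wrap_reversible(p: ReversibleAdapterParams) -> dict[str, Tensor]:
    out = {}
    for name in ("D_F", "U_F", "D_G", "U_G"):
        m = getattr(p, name)
        tw = Tensor(m.weight, requires_grad=True)
        tw.data = m.weight
        out[f"{name}.weight"] = tw
        if m.bias is not None:
            tb = Tensor(m.bias, requires_grad=True)
            tb.data = m.bias
            out[f"{name}.bias"] = tb
    return out


def _reversible_apply(x: Tensor, t: dict[str, Tensor], h: int) -> Tensor:
    half = h // 2
    e1, e2 = x[..., :half], x[..., half:]

    def fn(z: Tensor, d: str, u: str) -> Tensor:
        y = _affine(z, t[f"{d}.weight"], t.get(f"{d}.bias")).relu()
        return _affine(y, t[f"{u}.weight"], t.get(f"{u}.bias"))

    o1 = fn(e2, "D_F", "U_F") + e1
    o2 = fn(o1, "D_G", "U_G") + e2
    return cat([o1, o2], axis=-1)


class _Encoder:
    """Frozen token embedding + positions, a reversible adapter at the
    embeddings, then `depth` frozen blocks with trainable adapters."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, tag: str,
                 input_dim: int, n_positions: int, is_text: bool):
        self.cfg = cfg
        self.tag = tag
        self.is_text = is_text
        s = 1.0 / np.sqrt(input_dim if not is_text else cfg.h)
        if is_text:
            self.embed = rng.normal(0, 1.0, (input_dim, cfg.h))  # vocab table
        else:
            self.embed = rng.normal(0, s, (input_dim, cfg.h))  # patch projection
        self.pos = rng.normal(0, 0.1, (n_positions, cfg.h))
        self.rev = he_init(ReversibleAdapterParams.zeros(cfg.h, cfg.use_bias),
                           seed=int(rng.integers(2**31)))
        # zero up-projections: the coupling starts at identity
        self.rev.U_F.weight[...] = 0.0
        self.rev.U_G.weight[...] = 0.0
        self.t_rev = _wrap_reversible(self.rev)
        self.blocks = [
            _FrozenBlock(cfg, rng, f"{tag}.block{i}") for i in range(cfg.depth)
        ]

    def backbone_arrays(self) -> dict[str, np.ndarray]:
        out = {f"{self.tag}.embed": self.embed, f"{self.tag}.pos": self.pos}
        for b in self.blocks:
            out.update(b.backbone_arrays())
        return out

    def trainable(self) -> dict[str, Tensor]:
        out = {f"{self.tag}.reversible.{k}": t for k, t in self.t_rev.items()}
        for b in self.blocks:
            out.update(b.trainable())
        return out

    def encode_tokens(self, x0: np.ndarray) -> Tensor:
        """x0: (B, K, h) raw embeddings (constant); runs adapter + blocks."""
        x = _reversible_apply(Tensor(x0), self.t_rev, self.cfg.h)
        for b in self.blocks:
            x = b(x)
        return x


class ClinVLAModel:
    """Image and text encoders sharing one adapter configuration."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.image_encoder = _Encoder(cfg, rng, "image", cfg.patch_dim,
                                      cfg.n_patches, is_text=False)
        self.text_encoder = _Encoder(cfg, rng, "text", cfg.vocab_size,
                                     cfg.max_text_len, is_text=True)

    # ---- parameter access ---------------------------------------------
    def backbone_arrays(self) -> dict[str, np.ndarray]:
        out = self.image_encoder.backbone_arrays()
        out.update(self.text_encoder.backbone_arrays())
        return out

    def trainable_tensors(self) -> dict[str, Tensor]:
        out = self.image_encoder.trainable()
        out.update(self.text_encoder.trainable())
        return out

    # ---- embedding raw inputs (constant part of the graph) ------------
    def embed_patches(self, visible_patches: np.ndarray,
                      visible_indices: np.ndarray) -> np.ndarray:
        """(K, s*s) visible patch pixels -> (K, h) raw token embeddings."""
        x = visible_patches.astype(float) / 255.0  # gray8 -> [0, 1]
        return x @ self.image_encoder.embed + self.image_encoder.pos[visible_indices]

    def embed_token_ids(self, ids: np.ndarray) -> np.ndarray:
        ids = np.asarray(ids)
        L = len(ids)
        return self.text_encoder.embed[ids] + self.text_encoder.pos[:L]

    # ---- forward -------------------------------------------------------
    def encode_image_batch(self, raw: np.ndarray) -> Tensor:
        """raw: (B, K, h) stacked per-record patch embeddings -> tokens."""
        return self.image_encoder.encode_tokens(raw)

    def encode_text_batch(self, raw: np.ndarray) -> Tensor:
        return self.text_encoder.encode_tokens(raw)

    @staticmethod
    def masked_mean(tokens: Tensor, keep: np.ndarray) -> Tensor:
        """Mean over tokens with keep-mask (B, K); returns (B, h)."""
        w = keep[:, :, None].astype(float)
        return (tokens * Tensor(w)).sum(axis=1) / Tensor(w.sum(axis=1))


def build_model(cfg: ModelConfig) -> ClinVLAModel:
    return ClinVLAModel(cfg)
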
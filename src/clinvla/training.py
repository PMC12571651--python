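"""Parameter partitioning, AdamW with per-group learning rates, and a
desk-scale training loop over preprocessed record batches.

Backbone encoder weights are always frozen; in ``pretrain`` mode every
adapter family trains, in ``downstream`` mode only the task adapters and
their layer norms do.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .adapters import save_adapter_archive
from .autograd import Tensor
from .config import AdapterConfig, ModelConfig, TrainConfig
from .image_pipeline import (
    ViewPair,
    apply_mask,
    derive_mask_seed,
    patchify,
    resize_bilinear,
    sample_mask,
    window_normalize,
)
from .models import ClinVLAModel
from .text_pipeline import HashTokenizer, encode_report

__all__ = [
    "ParameterPartition",
    "partition_parameters",
    "AdamW",
    "preprocess_record",
    "train_loop",
    "embed_dataset",
]

FAMILIES = ("reversible", "language_adapter", "task_adapter", "adapter_ln")


@dataclass
class ParameterPartition:
    trainable: dict[str, Tensor]
    frozen: dict[str, np.ndarray]
    counts: dict

    def family(self, name: str) -> str:
        for fam in FAMILIES:
            if f".{fam}." in name:
                return fam
        return "backbone"


def partition_parameters(model: ClinVLAModel, mode: str) -> ParameterPartition:
    """Split model parameters into trainable and frozen sets.

    pretrain  -> all adapter families trainable, backbones frozen.
    downstream -> task adapters and their layer norms only.
    """
    if mode not in ("pretrain", "downstream"):
        raise ValueError(f"unknown mode {mode!r}")
    all_adapters = model.trainable_tensors()
    frozen: dict[str, np.ndarray] = dict(model.backbone_arrays())
    trainable: dict[str, Tensor] = {}
    active = (FAMILIES if mode == "pretrain"
              else ("task_adapter", "adapter_ln"))
    for name, t in all_adapters.items():
        fam = next((f for f in FAMILIES if f".{f}." in name), None)
        if fam in active:
            t.requires_grad = True
            trainable[name] = t
        else:
            t.requires_grad = False
            frozen[name] = t.data
    if not trainable:
        raise ValueError("partition left no trainable parameters")
    n_train = sum(t.data.size for t in trainable.values())
    n_total = n_train + sum(a.size for a in frozen.values())
    counts = {"trainable": n_train, "total": n_total,
              "fraction": n_train / n_total}
    return ParameterPartition(trainable=trainable, frozen=frozen, counts=counts)


class AdamW:
    """Adam with decoupled weight decay; independent learning rate per
    parameter group."""

    def __init__(self, groups: list[dict], weight_decay: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        # groups: [{"params": {name: Tensor}, "lr": float}, ...]
        self.groups = groups
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = {}
        self._v = {}
        for g in groups:
            for name, p in g["params"].items():
                self._m[name] = np.zeros_like(p.data)
                self._v[name] = np.zeros_like(p.data)

    def zero_grad(self):
        for g in self.groups:
            for p in g["params"].values():
                p.zero_grad()

    def step(self):
        self.t += 1
        for g in self.groups:
            lr = g["lr"]
            for name, p in g["params"].items():
                grad = p.grad if p.grad is not None else np.zeros_like(p.data)
                m = self._m[name] = self.b1 * self._m[name] + (1 - self.b1) * grad
                v = self._v[name] = self.b2 * self._v[name] + (1 - self.b2) * grad**2
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                # in-place so functional views of the same arrays stay live
                p.data -= lr * (mhat / (np.sqrt(vhat) + self.eps)
                                + self.weight_decay * p.data)


def make_optimizer(partition: ParameterPartition,
                   config: TrainConfig) -> AdamW:
    lr_by_family = {
        "reversible": config.lr_reversible_adapter,
        "language_adapter": config.lr_language_adapter,
        "task_adapter": config.lr_task_adapter,
        "adapter_ln": config.lr_task_adapter,  # LN trains with the task adapter
    }
    groups: dict[str, dict] = {}
    for name, t in partition.trainable.items():
        fam = partition.family(name)
        g = groups.setdefault(fam, {"params": {}, "lr": lr_by_family[fam]})
        g["params"][name] = t
    return AdamW(list(groups.values()), weight_decay=config.weight_decay)


# --------------------------------------------------------------------------
# data preparation
# --------------------------------------------------------------------------

def preprocess_record(pair: ViewPair, cfg: ModelConfig,
                      tokenizer: HashTokenizer, base_seed: int,
                      mask_rate: float = 0.75, epoch: int = 0) -> dict:
    """Window, resize, patchify and mask both views; tokenize the report.
    Masks are resampled per epoch with per-(record, view, epoch) seeds."""
    views = {}
    for view_name in ("frontal", "lateral"):
        rad = getattr(pair, view_name)
        if rad is None:
            continue
        if rad.units == "HU":
            rad = window_normalize(rad)
        rad = resize_bilinear(rad, side=cfg.image_side)
        grid = patchify(rad, patch_side=cfg.patch_side)
        seed = derive_mask_seed(base_seed, pair.record_id, view_name, epoch)
        mask = sample_mask(grid.n_patches, mask_rate, seed)
        patches, indices = apply_mask(grid, mask)
        views[view_name] = (patches, indices)
    _, seq = encode_report(pair.report, tokenizer=tokenizer,
                           max_len=cfg.max_text_len, record_id=pair.record_id)
    return {"record_id": pair.record_id, "views": views,
            "token_ids": np.array(seq.ids), "pad_id": seq.pad_id}


def _batch_arrays(model: ClinVLAModel, items: list[dict]):
    img_raw = np.stack([
        np.concatenate([
            model.embed_patches(*it["views"][v])
            for v in ("frontal", "lateral") if v in it["views"]
        ], axis=0)
        for it in items
    ])
    txt_raw = np.stack([model.embed_token_ids(it["token_ids"]) for it in items])
    txt_keep = np.stack([it["token_ids"] != it["pad_id"] for it in items])
    return img_raw, txt_raw, txt_keep


def _cosine_rows(a: Tensor, b: Tensor) -> Tensor:
    num = (a * b).sum(axis=1)
    return num / (a.norm(axis=1) * b.norm(axis=1))


def _group_means(tokens: Tensor, n: int) -> list[Tensor]:
    K = tokens.shape[1]
    bounds = np.linspace(0, K, n + 1).astype(int)
    return [tokens[:, lo:hi, :].mean(axis=1) for lo, hi in
            zip(bounds[:-1], bounds[1:])]


def paper_objective(img_tokens: Tensor, txt_tokens: Tensor,
                    txt_keep: np.ndarray, lambda1: float, n_locals: int):
    """Positives-only objective: mean over the batch of
    (1 - cos(global)) + lambda1 * mean_i (1 - cos(local_i))."""
    img_g = img_tokens.mean(axis=1)
    txt_g = ClinVLAModel.masked_mean(txt_tokens, txt_keep)
    global_term = (1.0 - _cosine_rows(img_g, txt_g)).mean()
    img_locals = _group_means(img_tokens, n_locals)
    txt_locals = _group_means(txt_tokens, n_locals)
    local = None
    for a, b in zip(img_locals, txt_locals):
        term = (1.0 - _cosine_rows(a, b)).mean()
        local = term if local is None else local + term
    local_term = local * (1.0 / n_locals)
    return global_term + lambda1 * local_term, global_term, local_term


def contrastive_objective(img_tokens: Tensor, txt_tokens: Tensor,
                          txt_keep: np.ndarray, temperature: float):
    """Symmetric in-batch cross-entropy over cosine similarities."""
    img_g = img_tokens.mean(axis=1)
    txt_g = ClinVLAModel.masked_mean(txt_tokens, txt_keep)
    B = img_g.shape[0]
    a = img_g / img_g.norm(axis=1, keepdims=True)
    b = txt_g / txt_g.norm(axis=1, keepdims=True)
    sim = (a @ b.swapaxes(0, 1)) * (1.0 / temperature)

    def xent(logits: Tensor) -> Tensor:
        shifted = logits - Tensor(logits.data.max(axis=1, keepdims=True))
        logz = shifted.exp().sum(axis=1, keepdims=True).log()
        logp = shifted - logz
        diag = logp[np.arange(B), np.arange(B)]
        return -diag.mean()

    return 0.5 * (xent(sim) + xent(sim.swapaxes(0, 1)))


# --------------------------------------------------------------------------
# the loop
# --------------------------------------------------------------------------

@dataclass
class TrainResult:
    metrics: list[dict]
    partition: ParameterPartition
    steps: int


def train_loop(records: list[ViewPair], model: ClinVLAModel,
               config: TrainConfig, mask_rate: float = 0.75,
               checkpoint_path=None, metrics_path=None) -> TrainResult:
    """Train the adapter parameters of `model` on `records`.

    Deterministic for a fixed config.seed; raises on NaN loss.  The
    checkpoint archive contains only the trainable arrays plus a manifest.
    """
    if not records:
        raise ValueError("dataset is empty")
    partition = partition_parameters(model, config.mode)
    opt = make_optimizer(partition, config)
    tokenizer = HashTokenizer(vocab_size=model.cfg.vocab_size)
    rng = np.random.default_rng(config.seed)
    metrics: list[dict] = []
    step = 0
    stop = False
    for epoch in range(config.epochs):
        cache = [preprocess_record(r, model.cfg, tokenizer, config.seed,
                                   mask_rate=mask_rate, epoch=epoch)
                 for r in records]
        order = rng.permutation(len(cache))
        for start in range(0, len(cache), config.batch_size):
            batch = [cache[i] for i in order[start:start + config.batch_size]]
            if len(batch) < 2 and config.objective == "contrastive":
                continue
            img_raw, txt_raw, txt_keep = _batch_arrays(model, batch)
            img_tokens = model.encode_image_batch(img_raw)
            txt_tokens = model.encode_text_batch(txt_raw)
            if config.objective == "paper":
                loss, g_term, l_term = paper_objective(
                    img_tokens, txt_tokens, txt_keep,
                    config.lambda1, model.cfg.n_locals)
                row = {"step": step, "loss": float(loss.data),
                       "global": float(g_term.data),
                       "local": float(l_term.data)}
            else:
                loss = contrastive_objective(img_tokens, txt_tokens, txt_keep,
                                             config.temperature)
                row = {"step": step, "loss": float(loss.data)}
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at step {step}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            metrics.append(row)
            step += 1
            if config.max_steps is not None and step >= config.max_steps:
                stop = True
                break
        if stop:
            break
    if metrics_path is not None:
        with open(metrics_path, "w") as fh:
            for row in metrics:
                fh.write(json.dumps(row) + "\n")
    if checkpoint_path is not None:
        arrays = {k: t.data for k, t in partition.trainable.items()}
        acfg = AdapterConfig(h=model.cfg.h, d=model.cfg.d,
                             use_bias=model.cfg.use_bias)
        roles = {k: partition.family(k) for k in arrays}
        save_adapter_archive(checkpoint_path, arrays, acfg, roles)
    return TrainResult(metrics=metrics, partition=partition, steps=step)


# --------------------------------------------------------------------------
# inference helpers
# --------------------------------------------------------------------------

def embed_dataset(records: list[ViewPair], model: ClinVLAModel,
                  base_seed: int = 0, mask_rate: float = 0.75,
                  batch_size: int = 32):
    """Forward every record (fixed epoch-0 masks); returns
    (img_globals, txt_globals) as plain (N, h) arrays."""
    tokenizer = HashTokenizer(vocab_size=model.cfg.vocab_size)
    items = [preprocess_record(r, model.cfg, tokenizer, base_seed,
                               mask_rate=mask_rate, epoch=0) for r in records]
    img_out, txt_out = [], []
    for start in range(0, len(items), batch_size):
        chunk = items[start:start + batch_size]
        img_raw, txt_raw, txt_keep = _batch_arrays(model, chunk)
        img_tokens = model.encode_image_batch(img_raw)
        txt_tokens = model.encode_text_batch(txt_raw)
        img_out.append(img_tokens.mean(axis=1).data)
        txt_out.append(ClinVLAModel.masked_mean(txt_tokens, txt_keep).data)
    return np.concatenate(img_out), np.concatenate(txt_out)
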
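"""Multi-view embedding aggregation and the alignment objective.

The training objective is a positives-only sum of a global and a local
cosine-distance term, ``total = global + lambda1 * local``.  An opt-in
in-batch contrastive objective is also provided for toy retrieval training
(it is *not* part of the reference objective).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModalEmbedding",
    "LossBreakdown",
    "aggregate_multiview",
    "pool_locals",
    "cosine_similarity",
    "global_alignment_loss",
    "local_alignment_loss",
    "total_loss",
    "batch_contrastive_loss",
]


@dataclass
class ModalEmbedding:
    """One modality's global vector plus n local region vectors."""

    global_vec: np.ndarray  # (h,)
    locals: np.ndarray  # (n, h)
    modality: str = "image"

    def __post_init__(self):
        self.global_vec = np.asarray(self.global_vec, dtype=float)
        self.locals = np.atleast_2d(np.asarray(self.locals, dtype=float))
        if self.modality not in ("image", "text"):
            raise ValueError(f"modality must be image/text, got {self.modality!r}")
        if np.isnan(self.global_vec).any() or np.isnan(self.locals).any():
            raise ValueError("embedding contains NaN")
        if self.locals.shape[0] < 1:
            raise ValueError("need at least one local region")
        if self.locals.shape[1] != self.global_vec.shape[0]:
            raise ValueError("local and global dimensions disagree")


@dataclass
class LossBreakdown:
    global_term: float
    local_term: float
    lambda1: float

    @property
    def total(self) -> float:
        return self.global_term + self.lambda1 * self.local_term


def pool_locals(tokens: np.ndarray, n: int) -> np.ndarray:
    """Mean-pool a (K, h) token sequence into n contiguous groups."""
    tokens = np.atleast_2d(tokens)
    if not (1 <= n <= tokens.shape[0]):
        raise ValueError(f"cannot pool {tokens.shape[0]} tokens into {n} groups")
    groups = np.array_split(tokens, n, axis=0)
    return np.stack([g.mean(axis=0) for g in groups])


def aggregate_multiview(frontal_tokens: np.ndarray,
                        lateral_tokens: np.ndarray | None = None,
                        n_locals: int | None = None,
                        modality: str = "image") -> ModalEmbedding:
    """Aggregate per-view token embeddings into one modality embedding.

    global = mean over all tokens of both views; locals = mean-pooled
    contiguous groups of the concatenated token sequence (frontal first).
    """
    frontal_tokens = np.atleast_2d(np.asarray(frontal_tokens, dtype=float))
    if frontal_tokens.shape[0] == 0:
        raise ValueError("frontal token set is empty")
    if lateral_tokens is not None and np.size(lateral_tokens):
        lateral_tokens = np.atleast_2d(np.asarray(lateral_tokens, dtype=float))
        tokens = np.concatenate([frontal_tokens, lateral_tokens], axis=0)
    else:
        tokens = frontal_tokens
    if n_locals is None:
        n_locals = min(tokens.shape[0], 49)
    return ModalEmbedding(
        global_vec=tokens.mean(axis=0),
        locals=pool_locals(tokens, n_locals),
        modality=modality,
    )


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero-norm vector")
    return float(np.dot(a, b) / (na * nb))


def global_alignment_loss(v_img: np.ndarray, v_txt: np.ndarray) -> float:
    """1 − cos(v_img, v_txt); in [0, 2], scale-invariant in each argument."""
    v_img, v_txt = np.asarray(v_img, float), np.asarray(v_txt, float)
    if np.linalg.norm(v_img) == 0:
        raise ValueError("image global embedding has zero norm")
    if np.linalg.norm(v_txt) == 0:
        raise ValueError("text global embedding has zero norm")
    return 1.0 - cosine_similarity(v_img, v_txt)


def local_alignment_loss(img_locals: np.ndarray, txt_locals: np.ndarray) -> float:
    """Mean over regions i of 1 − cos(img_i, txt_i)."""
    img_locals = np.atleast_2d(np.asarray(img_locals, float))
    txt_locals = np.atleast_2d(np.asarray(txt_locals, float))
    if img_locals.shape[0] != txt_locals.shape[0]:
        raise ValueError(
            f"region count mismatch: {img_locals.shape[0]} image vs "
            f"{txt_locals.shape[0]} text regions"
        )
    terms = []
    for i, (a, b) in enumerate(zip(img_locals, txt_locals)):
        if np.linalg.norm(a) == 0 or np.linalg.norm(b) == 0:
            raise ValueError(f"region {i} has a zero-norm vector")
        terms.append(1.0 - cosine_similarity(a, b))
    return float(np.mean(terms))


def total_loss(img: ModalEmbedding, txt: ModalEmbedding,
               lambda1: float = 0.8) -> LossBreakdown:
    """global + lambda1 * local, with components reported separately.

    Both modalities are pooled to the smaller region count before the local
    term so index-wise pairing is defined.
    """
    n = min(img.locals.shape[0], txt.locals.shape[0])
    img_loc = pool_locals(img.locals, n)
    txt_loc = pool_locals(txt.locals, n)
    return LossBreakdown(
        global_term=global_alignment_loss(img.global_vec, txt.global_vec),
        local_term=local_alignment_loss(img_loc, txt_loc),
        lambda1=lambda1,
    )


def batch_contrastive_loss(img_globals: np.ndarray, txt_globals: np.ndarray,
                           temperature: float = 0.1) -> float:
    """Symmetric cross-entropy over the B×B cosine-similarity matrix with
    matched pairs on the diagonal.  Not part of the reference objective;
    provided so toy retrieval training cannot collapse."""
    img_globals = np.atleast_2d(np.asarray(img_globals, float))
    txt_globals = np.atleast_2d(np.asarray(txt_globals, float))
    B = img_globals.shape[0]
    if B < 2:
        raise ValueError("contrastive loss needs a batch of at least 2")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    a = img_globals / np.linalg.norm(img_globals, axis=1, keepdims=True)
    b = txt_globals / np.linalg.norm(txt_globals, axis=1, keepdims=True)
    sim = (a @ b.T) / temperature

    def xent(logits):
        logits = logits - logits.max(axis=1, keepdims=True)
        logp = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
        return float(-np.mean(np.diag(logp)))

    return 0.5 * (xent(sim) + xent(sim.T))
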
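"""Cross-modal retrieval ranking and evaluation metrics.

Ranking is by cosine similarity with a deterministic index tie-break;
metrics are P@k, accuracy, F1 and AUC (Mann–Whitney rank statistic with
midranks), plus zero-shot classification by class-prompt similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "RetrievalResult",
    "rank_by_cosine",
    "precision_at_k",
    "classification_metrics",
    "zero_shot_classify",
    "random_ranker_precision",
]


@dataclass
class RetrievalResult:
    query_id: str
    ranked_ids: np.ndarray  # candidate indices, best first
    scores: np.ndarray  # cosine scores aligned to ranked_ids, non-increasing
    relevant: np.ndarray | None = None  # booleans aligned to ranked_ids

    def __post_init__(self):
        self.ranked_ids = np.asarray(self.ranked_ids)
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing")
        if self.relevant is not None:
            self.relevant = np.asarray(self.relevant, dtype=bool)
            if len(self.relevant) != len(self.ranked_ids):
                raise ValueError("relevance labels misaligned with ranking")


def rank_by_cosine(query: np.ndarray, candidates: np.ndarray,
                   relevant: np.ndarray | None = None,
                   query_id: str = "") -> RetrievalResult:
    """Order candidates by descending cosine similarity to the query; ties
    break by candidate index ascending (stable sort)."""
    query = np.asarray(query, dtype=float)
    candidates = np.atleast_2d(np.asarray(candidates, dtype=float))
    qn = np.linalg.norm(query)
    cn = np.linalg.norm(candidates, axis=1)
    if qn == 0:
        raise ValueError("query vector has zero norm")
    if np.any(cn == 0):
        bad = int(np.flatnonzero(cn == 0)[0])
        raise ValueError(f"candidate {bad} has zero norm")
    scores = (candidates @ query) / (cn * qn)
    order = np.argsort(-scores, kind="stable")
    rel = None if relevant is None else np.asarray(relevant, dtype=bool)[order]
    return RetrievalResult(query_id=query_id, ranked_ids=order,
                           scores=scores[order], relevant=rel)


def precision_at_k(result: RetrievalResult, k: int) -> float:
    """(# relevant among the top k) / k."""
    if result.relevant is None:
        raise ValueError("result carries no relevance labels")
    if not (1 <= k <= len(result.ranked_ids)):
        raise ValueError(
            f"k={k} outside [1, {len(result.ranked_ids)}] candidates"
        )
    return float(result.relevant[:k].sum()) / k


def classification_metrics(labels, scores, threshold: float = 0.5) -> dict:
    """Accuracy and F1 at `threshold`; AUC via the Mann–Whitney rank
    statistic with midranks for ties.

    AUC is returned as None (flagged) when only one class is present.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.size < 2:
        raise ValueError("labels and scores must be equal-length, size >= 2")
    pred = scores >= threshold
    acc = float(np.mean(pred == labels))
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        auc = None
    else:
        ranks = rankdata(scores)  # midranks
        auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        auc = float(auc)
    return {"acc": acc, "f1": float(f1), "auc": auc}


def zero_shot_classify(image_global: np.ndarray,
                       prompt_globals: np.ndarray) -> tuple[int, np.ndarray]:
    """Predict the class whose prompt embedding is most cosine-similar to
    the image embedding; ties go to the lowest class index."""
    prompt_globals = np.atleast_2d(np.asarray(prompt_globals, dtype=float))
    if prompt_globals.shape[0] < 2:
        raise ValueError("need at least 2 class prompts")
    result = rank_by_cosine(image_global, prompt_globals)
    scores = np.empty(prompt_globals.shape[0])
    scores[result.ranked_ids] = result.scores
    return int(result.ranked_ids[0]), scores


def random_ranker_precision(n_classes: int, n_per_class: int, k: int,
                            n_queries: int, seed: int = 0) -> float:
    """Mean P@k of a uniformly random ranking over a balanced class pool,
    relevance = same class as the query; queries are drawn uniformly over
    classes and ranked against the full pool."""
    rng = np.random.default_rng(seed)
    M = n_classes * n_per_class
    labels = np.repeat(np.arange(n_classes), n_per_class)
    total = 0.0
    for _ in range(n_queries):
        qclass = rng.integers(n_classes)
        order = rng.permutation(M)
        rel = labels[order] == qclass
        total += rel[:k].sum() / k
    return total / n_queries
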
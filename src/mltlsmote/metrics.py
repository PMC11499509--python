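"""Multi-label evaluation measures over true label sets and predicted scores.

Conventions used throughout:

* Label ranks come from descending score order with ties broken by ascending
  label index (rank 1 = most confident), so every ranking-based measure is
  deterministic.
* Average precision and ranking loss skip instances whose true label set is
  degenerate for the measure (empty for AP; empty or full for RL).  Hamming
  loss and micro-F1 count every instance.
* Macro AUROC counts tied positive/negative score pairs as 1/2 and skips
  labels lacking both classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "PredictionResult",
    "rank_labels",
    "hamming_loss",
    "ranking_loss",
    "average_precision",
    "micro_f1",
    "macro_auroc",
    "evaluate_predictions",
    "METRIC_NAMES",
]

#: Report column order: scores first (1 best), then losses (0 best).
METRIC_NAMES = ("auroc", "ap", "f1", "hl", "rl")


@dataclass(frozen=True)
class PredictionResult:
    """Per-instance label scores and thresholded label sets.

    ``scores`` is an ``(m, q)`` confidence matrix (higher = more relevant);
    ``predicted`` the binary decisions.  ``threshold`` records the scalar
    cut-off when the decisions came from simple thresholding (strategies
    with structured decision rules leave it ``None``).
    """

    scores: np.ndarray
    predicted: np.ndarray
    threshold: float | None = 0.5

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        predicted = np.asarray(self.predicted)
        if scores.shape != predicted.shape:
            raise ValueError("scores and predicted must share a shape")
        if not np.isfinite(scores).all():
            raise ValueError("scores must be finite")
        if not np.isin(predicted, (0, 1)).all():
            raise ValueError("predicted entries must be 0 or 1")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "predicted", predicted.astype(np.int8))

    @classmethod
    def from_scores(cls, scores: np.ndarray, threshold: float = 0.5
                    ) -> "PredictionResult":
        scores = np.asarray(scores, dtype=float)
        return cls(scores, (scores >= threshold).astype(np.int8), threshold)


def rank_labels(score_row: np.ndarray) -> np.ndarray:
    """Rank one instance's label scores: 1 = highest score.

    Ties are broken by ascending label index, so the result is always a
    permutation of ``1..q``.
    """
    score_row = np.asarray(score_row, dtype=float)
    if score_row.ndim != 1:
        raise ValueError("rank_labels expects a single score row")
    if np.isnan(score_row).any():
        raise ValueError("NaN scores cannot be ranked")
    order = np.argsort(-score_row, kind="stable")
    ranks = np.empty(score_row.size, dtype=int)
    ranks[order] = np.arange(1, score_row.size + 1)
    return ranks


def _rank_matrix(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if np.isnan(scores).any():
        raise ValueError("NaN scores cannot be ranked")
    order = np.argsort(-scores, axis=1, kind="stable")
    ranks = np.empty_like(order)
    m, q = scores.shape
    rows = np.arange(m)[:, None]
    ranks[rows, order] = np.arange(1, q + 1)[None, :]
    return ranks


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def hamming_loss(true: np.ndarray, predicted: np.ndarray) -> float:
    """Fraction of label cells on which truth and prediction disagree."""
    true, predicted = _check_pair(true, predicted)
    m, q = true.shape
    if m == 0 or q == 0:
        raise ValueError("hamming_loss undefined on empty matrices")
    return float((true != predicted).sum() / (m * q))


def ranking_loss(true: np.ndarray, scores: np.ndarray) -> float:
    """Mean fraction of (relevant, irrelevant) label pairs ranked wrongly.

    Instances whose label set is empty or complete carry no such pairs and
    are skipped; if no instance is scoreable a ``ValueError`` is raised.
    """
    true, scores = _check_pair(true, scores)
    ranks = _rank_matrix(scores)
    per_instance = []
    for y, r in zip(true.astype(bool), ranks):
        n_pos = int(y.sum())
        if n_pos == 0 or n_pos == y.size:
            continue
        pos_ranks = r[y]
        neg_ranks = r[~y]
        bad = (pos_ranks[:, None] > neg_ranks[None, :]).sum()
        per_instance.append(bad / (n_pos * (y.size - n_pos)))
    if not per_instance:
        raise ValueError("no instance with both relevant and irrelevant labels")
    return float(np.mean(per_instance))


def average_precision(true: np.ndarray, scores: np.ndarray) -> float:
    """Mean precision of each relevant label at its predicted rank.

    For each instance and each relevant label ``lam``, the proportion of
    labels ranked at or above ``lam`` that are themselves relevant, averaged
    over relevant labels and then instances.  Instances with an empty label
    set are skipped.
    """
    true, scores = _check_pair(true, scores)
    ranks = _rank_matrix(scores)
    per_instance = []
    for y, r in zip(true.astype(bool), ranks):
        if not y.any():
            continue
        pos_ranks = np.sort(r[y])
        # among labels ranked <= pos_ranks[t], exactly t+1 are relevant
        precisions = (np.arange(1, pos_ranks.size + 1)) / pos_ranks
        per_instance.append(precisions.mean())
    if not per_instance:
        raise ValueError("no instance with a relevant label")
    return float(np.mean(per_instance))


def micro_f1(true: np.ndarray, predicted: np.ndarray) -> float:
    """Micro-averaged F1 pooled over all label cells; 0 when degenerate."""
    true, predicted = _check_pair(true, predicted)
    tp = int(((true == 1) & (predicted == 1)).sum())
    fp = int(((true == 0) & (predicted == 1)).sum())
    fn = int(((true == 1) & (predicted == 0)).sum())
    denom = 2 * tp + fp + fn
    return 0.0 if denom == 0 else 2 * tp / denom


def macro_auroc(true: np.ndarray, scores: np.ndarray) -> float:
    """Mean per-label AUROC (probability a positive outscores a negative).

    Computed by the rank-sum (Mann-Whitney) identity with tied scores
    credited 1/2.  Labels without both a positive and a negative instance
    are skipped with a warning; with no evaluable label a ``ValueError``
    is raised.
    """
    true, scores = _check_pair(true, scores)
    aucs = []
    skipped = []
    for j in range(true.shape[1]):
        y = true[:, j].astype(bool)
        n_pos = int(y.sum())
        n_neg = y.size - n_pos
        if n_pos == 0 or n_neg == 0:
            skipped.append(j)
            continue
        r = rankdata(scores[:, j])  # average ranks -> ties count 1/2
        auc = (r[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        aucs.append(auc)
    if skipped:
        warnings.warn(
            f"macro_auroc: skipped label column(s) {skipped} without both "
            "classes", stacklevel=2)
    if not aucs:
        raise ValueError("no label with both a positive and a negative instance")
    return float(np.mean(aucs))


def evaluate_predictions(true: np.ndarray, result: PredictionResult
                         ) -> dict[str, float]:
    """All five measures as a dict keyed by ``METRIC_NAMES``."""
    return {
        "auroc": macro_auroc(true, result.scores),
        "ap": average_precision(true, result.scores),
        "f1": micro_f1(true, result.predicted),
        "hl": hamming_loss(true, result.predicted),
        "rl": ranking_loss(true, result.scores),
    }
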
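"""Top-likelihood sampling losses as pure reductions over scored proposals.

During detector training, region proposals receive an objectness score
p_i in [0, 1] and a binary label p_i* (1 = organelle, 0 = background). The
top-likelihood strategy optimizes the hardest examples on both sides:

* L_tploss averages, over the N_pos lowest-scoring positives, the
  classification loss against label 1 plus lambda times the box-regression
  loss;
* L_tnloss averages, over the N_neg highest-scoring negatives (the regions
  most confusable with the target organelle), the classification loss
  against label 0.

The component losses L_cls and L_reg are standard detection losses and are
supplied per anchor, keeping this module framework-free; it documents the
reference semantics for anyone retraining the detector. The companion
similarity penalty between positive and negative proposal features has no
closed form here and is a pluggable slot defaulting to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np

__all__ = ["ScoredAnchor", "select_top_negatives", "select_bottom_positives",
           "top_likelihood_losses", "zero_similarity_loss"]


@dataclass(frozen=True)
class ScoredAnchor:
    """One scored proposal with its supplied per-anchor loss components."""

    score: float               # predicted objectness p_i in [0, 1]
    label: int                 # ground-truth p_i* in {0, 1}
    cls_loss_pos: float = 0.0  # L_cls(p_i, 1)
    cls_loss_neg: float = 0.0  # L_cls(p_i, 0)
    reg_loss: float = 0.0      # L_reg(t_i, t_i*), meaningful for positives

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must lie in [0, 1], got {self.score}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if min(self.cls_loss_pos, self.cls_loss_neg, self.reg_loss) < 0:
            raise ValueError("loss components must be non-negative")


def _stable_take(anchors: Sequence[ScoredAnchor], order: np.ndarray, k: int,
                 kind: str) -> list:
    if k > len(order):
        warnings.warn(
            f"requested {k} {kind} anchors but only {len(order)} available; taking all",
            stacklevel=3)
        k = len(order)
    return [anchors[i] for i in order[:k]]


def select_top_negatives(anchors: Sequence[ScoredAnchor], n_neg: int) -> list:
    """The n_neg highest-scoring negative anchors (hard negatives).

    Ties are broken by input order; if fewer negatives exist, all are
    returned with a warning.
    """
    if n_neg < 1:
        raise ValueError("n_neg must be >= 1")
    idx = np.array([i for i, a in enumerate(anchors) if a.label == 0], dtype=int)
    scores = np.array([anchors[i].score for i in idx])
    order = idx[np.argsort(-scores, kind="stable")]
    return _stable_take(anchors, order, n_neg, "negative")


def select_bottom_positives(anchors: Sequence[ScoredAnchor], n_pos: int) -> list:
    """The n_pos lowest-scoring positive anchors (hard positives)."""
    if n_pos < 1:
        raise ValueError("n_pos must be >= 1")
    idx = np.array([i for i, a in enumerate(anchors) if a.label == 1], dtype=int)
    scores = np.array([anchors[i].score for i in idx])
    order = idx[np.argsort(scores, kind="stable")]
    return _stable_take(anchors, order, n_pos, "positive")


def zero_similarity_loss(positives: Sequence[ScoredAnchor],
                         negatives: Sequence[ScoredAnchor]) -> float:
    """Default similarity penalty: disabled (returns 0)."""
    return 0.0


def top_likelihood_losses(anchors: Sequence[ScoredAnchor], n_pos: int, n_neg: int,
                          lam: float = 1.0,
                          similarity_loss: Optional[Callable] = None,
                          ) -> Tuple[float, float]:
    """The (L_tploss, L_tnloss) pair of top-likelihood reductions.

    L_tploss = (1/N_pos) * sum over the N_pos lowest-scoring positives of
    [L_cls(p_i, 1) + lam * L_reg(t_i, t_i*)]; L_tnloss = (1/N_neg) * sum
    over the N_neg top-scoring negatives of L_cls(p_i, 0). The optional
    ``similarity_loss(positives, negatives)`` scalar is added to L_tnloss
    (zero by default).
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must both be >= 1")
    positives = select_bottom_positives(anchors, n_pos)
    negatives = select_top_negatives(anchors, n_neg)
    if not positives or not negatives:
        raise ValueError("need at least one positive and one negative anchor")
    tploss = sum(a.cls_loss_pos + lam * a.reg_loss for a in positives) / len(positives)
    tnloss = sum(a.cls_loss_neg for a in negatives) / len(negatives)
    if similarity_loss is not None:
        tnloss += float(similarity_loss(positives, negatives))
    return float(tploss), float(tnloss)
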
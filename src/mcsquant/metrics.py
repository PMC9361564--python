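"""Segmentation agreement metrics and the active-learning selection rule."""

from __future__ import annotations

import math
from typing import Mapping, Sequence, Tuple

import numpy as np

from ._errors import ShapeMismatchError

__all__ = ["dice", "iou", "miou", "match_ratio", "active_learning_select"]


def _as_pair(prediction, annotation) -> Tuple[np.ndarray, np.ndarray]:
    p = np.asarray(prediction).astype(bool)
    a = np.asarray(annotation).astype(bool)
    if p.shape != a.shape:
        raise ShapeMismatchError(f"mask shapes differ: {p.shape} vs {a.shape}")
    return p, a


def dice(prediction, annotation) -> float:
    """Dice coefficient 2|P∩A| / (|P| + |A|); 1 when both masks are empty."""
    p, a = _as_pair(prediction, annotation)
    denom = int(p.sum()) + int(a.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & a).sum()) / denom


def iou(prediction, annotation) -> float:
    """Intersection over union |P∩A| / |P∪A|; 1 when both masks are empty."""
    p, a = _as_pair(prediction, annotation)
    union = int((p | a).sum())
    if union == 0:
        return 1.0
    return int((p & a).sum()) / union


def miou(pairs: Sequence[tuple]) -> float:
    """Mean IoU over (prediction, annotation) pairs."""
    if not pairs:
        raise ValueError("miou needs at least one (prediction, annotation) pair")
    return float(np.mean([iou(p, a) for p, a in pairs]))


def match_ratio(prediction, annotation) -> float:
    """Correctly predicted pixels over annotated pixels, in percent.

    This is annotation recall: over-prediction is not penalized, so it is
    reported alongside Dice/mIoU rather than instead of them.
    """
    p, a = _as_pair(prediction, annotation)
    n_annot = int(a.sum())
    if n_annot == 0:
        raise ValueError("match_ratio undefined for an empty annotation")
    return 100.0 * int((p & a).sum()) / n_annot


def active_learning_select(per_image_scores: Mapping[str, float], fraction: float) -> list:
    """The worst ``fraction`` of images by score, for targeted re-annotation.

    Returns the ceil(fraction * N) lowest-scoring image ids (ties broken by
    ascending id); the default workflow routes the worst 10% by mIoU back
    to the annotator.
    """
    if not per_image_scores:
        raise ValueError("no images to select from")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    k = math.ceil(fraction * len(per_image_scores))
    ranked = sorted(per_image_scores.items(), key=lambda kv: (kv[1], kv[0]))
    return [image_id for image_id, _ in ranked[:k]]
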
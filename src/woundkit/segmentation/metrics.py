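"""Overlap metrics for segmentation masks."""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np


def _pair(a, b):
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def dice(a, b) -> float:
    """Dice coefficient 2|a&b| / (|a| + |b|); empty vs empty is 1."""
    a, b = _pair(a, b)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def iou(a, b) -> float:
    """Intersection over union |a&b| / |a|b|; empty vs empty is 1."""
    a, b = _pair(a, b)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def pixel_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of pixels with the correct class label (all classes)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("label grids must share a shape")
    return float((pred == truth).mean())


def per_class_overlap(pred: np.ndarray, truth: np.ndarray,
                      classes: Sequence[int]) -> Dict[int, Dict[str, float]]:
    """Dice and IoU for each listed class label."""
    return {c: {"dice": dice(pred == c, truth == c),
                "iou": iou(pred == c, truth == c)} for c in classes}


def mean_foreground_dice(pred: np.ndarray, truth: np.ndarray,
                         n_classes: int) -> float:
    """Mean dice over the non-background classes (labels 1..K-1)."""
    scores = [dice(pred == c, truth == c) for c in range(1, n_classes)]
    return float(np.mean(scores))


def mean_foreground_iou(pred: np.ndarray, truth: np.ndarray,
                        n_classes: int) -> float:
    scores = [iou(pred == c, truth == c) for c in range(1, n_classes)]
    return float(np.mean(scores))
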
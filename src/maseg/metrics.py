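"""Segmentation and morphometry evaluation metrics.

Dice = 2|X∩Y| / (|X|+|Y|) and IoU = |X∩Y| / |X∪Y| on hard binary masks,
with the convention that two empty masks agree perfectly (score 1.0).
Morphometry predictions are scored by mean squared error against reference
values.
"""

from __future__ import annotations

import numpy as np


def _check_pair(pred: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred)
    t = np.asarray(target)
    if p.shape != t.shape:
        raise ValueError("mask shapes differ")
    for m in (p, t):
        if set(np.unique(m)) - {0, 1}:
            raise ValueError("masks must be binary {0, 1}")
    return p.astype(bool), t.astype(bool)


def dice_coefficient(pred: np.ndarray, target: np.ndarray) -> float:
    p, t = _check_pair(pred, target)
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & t).sum()) / denom


def iou(pred: np.ndarray, target: np.ndarray) -> float:
    p, t = _check_pair(pred, target)
    union = int((p | t).sum())
    if union == 0:
        return 1.0
    return int((p & t).sum()) / union


def mse(pred_values, ref_values) -> float:
    p = np.asarray(pred_values, dtype=np.float64)
    r = np.asarray(ref_values, dtype=np.float64)
    if p.shape != r.shape or p.size == 0:
        raise ValueError("value lists must be nonempty and of equal length")
    return float(np.mean((p - r) ** 2))


def score_summary(scores) -> dict:
    """Mean / std / min / max summary of a list of scores."""
    a = np.asarray(scores, dtype=np.float64)
    return {
        "mean": float(a.mean()),
        "std": float(a.std(ddof=0)),
        "min": float(a.min()),
        "max": float(a.max()),
        "n": int(a.size),
    }
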
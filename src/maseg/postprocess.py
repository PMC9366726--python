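"""Probability-map postprocessing: threshold, clear small fragments, ensemble.

The network's sigmoid output is binarized at 0.5 (a pixel exactly at the
threshold counts as foreground), 8-connected components smaller than an area
threshold (default 1024 px at full 512×512 resolution) are removed as
spurious fragments, and the final prediction is the pixel-wise union of the
three best of ten trained models, ranked by validation performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

DEFAULT_MIN_AREA = 1024


@dataclass(frozen=True)
class EnsembleSpec:
    n_models: int = 10
    n_selected: int = 3
    selection_metric: str = "val_dice"

    def __post_init__(self) -> None:
        if not 1 <= self.n_selected <= self.n_models:
            raise ValueError("need 1 <= n_selected <= n_models")


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map; ``value >= threshold`` maps to foreground."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    p = np.asarray(prob_map, dtype=np.float64)
    return (p >= threshold).astype(np.uint8)


def clear_fragments(mask: np.ndarray, min_area: int = DEFAULT_MIN_AREA) -> np.ndarray:
    """Remove 8-connected components with area strictly below ``min_area``."""
    m = np.asarray(mask)
    if set(np.unique(m)) - {0, 1}:
        raise ValueError("mask must be binary {0, 1}")
    labels, n = measure.label(m.astype(bool), connectivity=2, return_num=True)
    if n == 0:
        return m.astype(np.uint8)
    areas = np.bincount(labels.ravel())
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = areas[1:] >= min_area
    return keep[labels].astype(np.uint8)


def select_and_union(
    masks: list[np.ndarray], val_scores: list[float], spec: EnsembleSpec | None = None
) -> np.ndarray:
    """Union the ``n_selected`` masks with the highest validation scores.

    Ties are broken toward the lower model index (stable descending sort).
    """
    if spec is None:
        spec = EnsembleSpec(n_models=len(masks))
    if len(masks) != len(val_scores):
        raise ValueError("one validation score per mask is required")
    if len(masks) != spec.n_models:
        raise ValueError(f"expected {spec.n_models} masks, got {len(masks)}")
    order = np.argsort(-np.asarray(val_scores, dtype=np.float64), kind="stable")
    chosen = order[: spec.n_selected]
    out = np.zeros_like(np.asarray(masks[0]), dtype=np.uint8)
    for i in chosen:
        m = np.asarray(masks[i])
        if set(np.unique(m)) - {0, 1}:
            raise ValueError("masks must be binary {0, 1}")
        out |= m.astype(np.uint8)
    return out


def postprocess_ensemble(
    prob_maps: list[np.ndarray],
    val_scores: list[float],
    threshold: float = 0.5,
    min_area: int = DEFAULT_MIN_AREA,
    spec: EnsembleSpec | None = None,
    clear_before_union: bool = True,
) -> np.ndarray:
    """Full postprocessing: binarize each map, clear, select-and-union.

    Fragment clearing is applied per model output before the union by
    default; ``clear_before_union=False`` clears the union instead.
    """
    masks = [binarize(p, threshold) for p in prob_maps]
    if clear_before_union:
        masks = [clear_fragments(m, min_area) for m in masks]
    out = select_and_union(masks, val_scores, spec)
    if not clear_before_union:
        out = clear_fragments(out, min_area)
    return out
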
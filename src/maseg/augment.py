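"""Flip / rotate / scale augmentation of image–mask pairs.

Each source pair expands into exactly ``n_rotations`` outputs, one per
deterministic rotation angle 2πk/N (N defaults to 32, so 63 source images
yield 63 × 32 = 2016 pairs).  Per rotation slot, a horizontal and a vertical
flip are each drawn with probability ``flip_prob`` and a scale factor is
drawn uniformly from ``scale_range`` — the enumeration is deterministic, the
flips and scales are seeded randomness.

Image channels are interpolated bilinearly, masks with nearest neighbor so
they stay strictly binary; the canvas size is preserved (rotate/scale about
the center, then center-crop or zero-pad), with out-of-frame regions filled
with the background value 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import transform

from .preprocess import TwoChannelImage


@dataclass(frozen=True)
class AugmentConfig:
    n_rotations: int = 32
    flip_prob: float = 0.5
    scale_range: tuple[float, float] = (0.7, 1.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rotations < 1:
            raise ValueError("n_rotations must be >= 1")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be in [0, 1]")
        lo, hi = self.scale_range
        if not 0 < lo <= hi:
            raise ValueError("scale_range must satisfy 0 < lo <= hi")


def _center_fit(img: np.ndarray, size: int, order: int) -> np.ndarray:
    """Crop or zero-pad ``img`` symmetrically to ``size``×``size``."""
    h, w = img.shape[:2]
    out = img
    if h > size:
        top = (h - size) // 2
        out = out[top : top + size]
    if w > size:
        left = (w - size) // 2
        out = out[:, left : left + size]
    h, w = out.shape[:2]
    if h < size or w < size:
        pt, pl = (size - h) // 2, (size - w) // 2
        pads = [(pt, size - h - pt), (pl, size - w - pl)] + [(0, 0)] * (out.ndim - 2)
        out = np.pad(out, pads, mode="constant")
    return out


def _transform_one(
    arr: np.ndarray, flip_h: bool, flip_v: bool, angle_deg: float, scale: float, order: int
) -> np.ndarray:
    size = arr.shape[0]
    out = arr
    if flip_h:
        out = out[:, ::-1]
    if flip_v:
        out = out[::-1, :]
    if angle_deg != 0.0:
        out = transform.rotate(
            out, angle_deg, resize=False, order=order, mode="constant", cval=0.0,
            preserve_range=True,
        )
    if scale != 1.0:
        out = transform.rescale(
            out,
            scale,
            order=order,
            mode="constant",
            cval=0.0,
            preserve_range=True,
            channel_axis=-1 if out.ndim == 3 else None,
            anti_aliasing=False,
        )
        out = _center_fit(out, size, order)
    return np.ascontiguousarray(out)


def augment_pair(
    image: TwoChannelImage, mask: np.ndarray, config: AugmentConfig
) -> list[tuple[TwoChannelImage, np.ndarray]]:
    """Expand one image/mask pair into ``config.n_rotations`` augmented pairs.

    The k-th output uses rotation angle 2πk/N; flips and the scale factor
    are drawn independently per slot from ``config.seed``.
    """
    img = np.asarray(image.data, dtype=np.float64)
    m = np.asarray(mask)
    if img.shape[:2] != m.shape:
        raise ValueError("image and mask spatial sizes differ")
    if set(np.unique(m)) - {0, 1}:
        raise ValueError("mask must be binary {0, 1}")
    rng = np.random.default_rng(config.seed)
    out: list[tuple[TwoChannelImage, np.ndarray]] = []
    for k in range(config.n_rotations):
        flip_h = bool(rng.random() < config.flip_prob)
        flip_v = bool(rng.random() < config.flip_prob)
        angle = 360.0 * k / config.n_rotations
        scale = float(rng.uniform(*config.scale_range))
        aug_img = _transform_one(img, flip_h, flip_v, angle, scale, order=1)
        aug_mask = _transform_one(m.astype(np.float64), flip_h, flip_v, angle, scale, order=0)
        aug_mask = (aug_mask > 0.5).astype(np.uint8)
        out.append((TwoChannelImage(aug_img), aug_mask))
    return out


def augment_dataset(
    pairs: list[tuple[TwoChannelImage, np.ndarray]], config: AugmentConfig
) -> list[tuple[TwoChannelImage, np.ndarray]]:
    """Augment every pair; source i uses the derived seed ``seed + i``."""
    out = []
    for i, (img, mask) in enumerate(pairs):
        cfg = AugmentConfig(
            n_rotations=config.n_rotations,
            flip_prob=config.flip_prob,
            scale_range=config.scale_range,
            seed=config.seed + i,
        )
        out.extend(augment_pair(img, mask, cfg))
    return out
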
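"""Multimodal preprocessing of AOSLO videos.

Three modalities are derived from a raw video:

1. **Perfusion map** — the per-pixel temporal standard deviation across
   frames.  Moving blood flickers and appears bright; static tissue is dark.
2. **Enhanced image** — the frame average, color-inverted, then local-mean
   filtered; it preserves lesion boundaries where thrombosed (non-perfused)
   regions vanish from the perfusion map.
3. **Two-channel image** — both modalities resampled to the network input
   size and stacked (channel 0 = enhanced, channel 1 = perfusion).

The perfusion map is additionally passed through a denoise–enhance chain:
non-local-means denoising, min–max normalization to [0, 1], contrast-limited
adaptive histogram equalization (CLAHE) and gamma correction, in that order.
The chain is applied to the perfusion channel only; the enhanced-image
channel carries its own smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure, restoration, transform


@dataclass
class VideoStack:
    """Ordered grayscale frames of one acquisition, intensities in [0, 1]."""

    frames: np.ndarray  # (n_frames, H, W)

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=np.float64)
        if f.ndim != 3:
            raise ValueError("frames must be a (n_frames, H, W) array")
        if not np.all(np.isfinite(f)):
            raise ValueError("frames contain non-finite values")
        self.frames = f

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class PerfusionMap:
    image: np.ndarray
    normalized: bool = False


@dataclass
class EnhancedImage:
    image: np.ndarray


@dataclass
class TwoChannelImage:
    """Network input: (H, W, 2) with channel 0 = enhanced, 1 = perfusion."""

    data: np.ndarray

    @property
    def enhanced(self) -> np.ndarray:
        return self.data[..., 0]

    @property
    def perfusion(self) -> np.ndarray:
        return self.data[..., 1]


@dataclass
class EnhanceParams:
    """Parameters of the perfusion-map denoise–enhance chain.

    The chain's algorithms are fixed; every numeric knob is exposed here.
    ``nlm_h_frac`` scales the denoising strength by the input's dynamic
    range; ``clahe_kernel_tiles`` tiles the image into an n-by-n grid.
    """

    nlm_patch_size: int = 7
    nlm_search_window: int = 21
    nlm_h_frac: float = 0.1
    clahe_clip_limit: float = 0.01
    clahe_kernel_tiles: int = 8
    gamma: float = 0.8


def compute_perfusion_map(video: VideoStack) -> PerfusionMap:
    """Per-pixel temporal standard deviation (population convention, ddof=0).

    Requires at least two frames; a single frame has no temporal signal.
    """
    if video.n_frames < 2:
        raise ValueError("perfusion map needs at least two frames")
    return PerfusionMap(np.std(video.frames, axis=0, ddof=0), normalized=False)


def minmax_normalize(image: np.ndarray) -> np.ndarray:
    """Min–max rescale to [0, 1]; a constant image maps to all zeros."""
    lo = float(image.min())
    hi = float(image.max())
    if hi == lo:
        return np.zeros_like(image, dtype=np.float64)
    return (image - lo) / (hi - lo)


def enhance_perfusion(pmap: PerfusionMap, params: EnhanceParams | None = None) -> PerfusionMap:
    """Denoise and enhance a perfusion map.

    Steps, in order: (1) fast non-local-means denoising, (2) min–max
    normalization into [0, 1], (3) CLAHE, (4) gamma correction.
    """
    if params is None:
        params = EnhanceParams()
    img = np.asarray(pmap.image, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("perfusion map contains non-finite values")

    dyn = float(img.max() - img.min())
    if dyn > 0:
        patch_distance = max(1, (params.nlm_search_window - params.nlm_patch_size) // 2)
        img = restoration.denoise_nl_means(
            img,
            patch_size=params.nlm_patch_size,
            patch_distance=patch_distance,
            h=params.nlm_h_frac * dyn,
            fast_mode=True,
        )
    img = minmax_normalize(img)
    if img.max() > img.min():  # CLAHE is undefined on a constant field
        ksize = max(1, min(img.shape) // params.clahe_kernel_tiles)
        img = exposure.equalize_adapthist(
            img, kernel_size=ksize, clip_limit=params.clahe_clip_limit
        )
    img = np.power(img, params.gamma)
    return PerfusionMap(img, normalized=True)


def compute_enhanced_image(video: VideoStack, window: int = 5) -> EnhancedImage:
    """Frame average, inverted, then window×window local mean (reflect border)."""
    if window < 1 or window % 2 == 0:
        raise ValueError("local-mean window must be an odd positive integer")
    avg = video.frames.mean(axis=0)
    inv = 1.0 - avg
    if window == 1:
        return EnhancedImage(inv)
    return EnhancedImage(ndimage.uniform_filter(inv, size=window, mode="reflect"))


def make_two_channel(
    enhanced: EnhancedImage, perfusion: PerfusionMap, size: int = 512
) -> TwoChannelImage:
    """Resample both modalities to ``size``×``size`` (bilinear) and stack."""
    e = np.asarray(enhanced.image, dtype=np.float64)
    p = np.asarray(perfusion.image, dtype=np.float64)
    if e.shape != p.shape:
        raise ValueError("enhanced image and perfusion map shapes differ")
    if e.shape != (size, size):
        e = transform.resize(e, (size, size), order=1, anti_aliasing=False, preserve_range=True)
        p = transform.resize(p, (size, size), order=1, anti_aliasing=False, preserve_range=True)
    return TwoChannelImage(np.stack([e, p], axis=-1))


def resize_mask(mask: np.ndarray, size: int) -> np.ndarray:
    """Nearest-neighbor mask resize; preserves strict binarity."""
    m = np.asarray(mask)
    if m.shape == (size, size):
        return m.astype(np.uint8)
    out = transform.resize(
        m.astype(np.float64), (size, size), order=0, anti_aliasing=False, preserve_range=True
    )
    return (out > 0.5).astype(np.uint8)


def preprocess_video(
    video: VideoStack,
    size: int = 512,
    window: int = 5,
    params: EnhanceParams | None = None,
) -> TwoChannelImage:
    """Full chain: perfusion map -> enhance; frame average -> enhanced; stack."""
    pmap = enhance_perfusion(compute_perfusion_map(video), params)
    enh = compute_enhanced_image(video, window=window)
    return make_two_channel(enh, pmap, size=size)
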
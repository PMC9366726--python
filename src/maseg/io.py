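"""Reading and writing the pipeline's on-disk artifacts.

Videos travel as multi-page float32 TIFF (one page per frame), masks as
single-page PNG with values {0, 255}, probability maps as float32 TIFF, and
structured results (truth records, scores, manifests) as JSON/CSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .preprocess import TwoChannelImage, VideoStack


def read_video(path: str | Path) -> VideoStack:
    frames = tifffile.imread(path)
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.max() > 1.0:  # integer-encoded acquisition
        frames = frames / float(np.iinfo(np.uint16).max if frames.max() > 255 else 255)
    return VideoStack(frames)


def write_video(path: str | Path, video: np.ndarray) -> None:
    tifffile.imwrite(
        path, np.asarray(video, dtype=np.float32), photometric="minisblack"
    )


def read_mask(path: str | Path) -> np.ndarray:
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., 0]
    return (img > 127).astype(np.uint8)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask, dtype=np.uint8) * 255))


def read_two_channel(path: str | Path) -> TwoChannelImage:
    data = np.asarray(tifffile.imread(path), dtype=np.float64)
    if data.ndim != 3 or data.shape[-1] != 2:
        raise ValueError("two-channel image file must be (H, W, 2)")
    return TwoChannelImage(data)


def write_two_channel(path: str | Path, image: TwoChannelImage) -> None:
    tifffile.imwrite(path, np.asarray(image.data, dtype=np.float32))


def write_prob_map(path: str | Path, pmap: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(pmap, dtype=np.float32))


def read_prob_map(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=np.float64)


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
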
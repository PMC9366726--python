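"""Medial-axis morphometry of segmented microaneurysms.

For one segmented object the medial axis (topological skeleton) is computed
together with the Euclidean distance transform, giving the medial radius
d_i — the distance from each skeleton pixel to the nearest background
pixel — at every skeleton point.  From the sorted radius list:

* **LC** (largest caliber)  = 2 · max(d_i): the diameter of the MA body;
* **NC** (narrowest caliber) = 2 · mean of the 10 smallest d_i: the width of
  the narrowest stretch of the parenting vessels (averaging over 10 points
  makes the estimate robust to single-pixel skeleton artifacts);
* **BNR** (body-to-neck ratio) = LC / NC, a shape index associated with MA
  rupture and thrombosis propensity.

Three practical guards: the mask is lightly smoothed (binary opening with a
radius-1 diamond) before skeletonization so that rasterization staircases do
not sprout dendritic branches, short spur branches of the raw skeleton are
pruned (boundary bumps otherwise seed spurs whose tiny radii corrupt NC), and
skeleton points whose radius may be cut short by the image border — a vessel
running out of the imaged patch — are flagged and excluded from the caliber
statistics rather than silently used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve
from skimage import measure, morphology

NC_POINTS = 10


@dataclass
class MedialProfile:
    skeleton_points: np.ndarray  # (N, 2) int pixel coordinates (row, col)
    distances: np.ndarray  # (N,) medial radius at each skeleton point, px
    border_flag: np.ndarray  # (N,) bool, radius possibly cut by image border

    @property
    def n_points(self) -> int:
        return len(self.distances)

    @property
    def d_sorted(self) -> np.ndarray:
        return np.sort(self.distances, kind="stable")

    def usable(self) -> np.ndarray:
        """Radii not contaminated by the border; falls back to all radii."""
        good = self.distances[~self.border_flag]
        return good if good.size else self.distances


@dataclass
class ComponentReport:
    lc: float
    nc: float
    bnr: float
    n_skeleton_points: int
    area_px: int


@dataclass
class MorphometryReport:
    components: list[ComponentReport]
    um_per_px: float | None = None

    @property
    def primary(self) -> ComponentReport:
        """The largest-area component (the MA of interest in a crop)."""
        return max(self.components, key=lambda c: c.area_px)


def _prune_spurs(skeleton: np.ndarray, length: int) -> np.ndarray:
    """Remove up to ``length`` terminal pixels from every skeleton branch."""
    sk = skeleton.copy()
    kernel = np.ones((3, 3), dtype=int)
    for _ in range(length):
        neighbors = convolve(sk.astype(int), kernel, mode="constant") - sk.astype(int)
        endpoints = sk & (neighbors <= 1)
        if not endpoints.any() or endpoints.sum() == sk.sum():
            break
        sk &= ~endpoints
    return sk


def medial_profile(
    mask: np.ndarray,
    prune_length: int = 3,
    largest_component_only: bool = True,
    presmooth: bool = True,
) -> MedialProfile:
    """Skeletonize a binary object and collect its medial radii.

    ``mask`` must be nonempty and binary; when it contains several
    8-connected components the largest is analyzed (use
    :func:`morphometry_report` for a per-component breakdown).
    ``presmooth`` applies a radius-1 binary opening first (skipped when it
    would erase the object, e.g. a single-pixel mask); disable it to obtain
    radii of the raw mask exactly.
    """
    m = np.asarray(mask)
    if set(np.unique(m)) - {0, 1}:
        raise ValueError("mask must be binary {0, 1}")
    obj = m.astype(bool)
    if not obj.any():
        raise ValueError("empty mask has no morphometry")
    if largest_component_only:
        labels, n = measure.label(obj, connectivity=2, return_num=True)
        if n > 1:
            areas = np.bincount(labels.ravel())
            areas[0] = 0
            obj = labels == int(np.argmax(areas))
    if presmooth:
        smoothed = morphology.opening(obj, footprint=morphology.diamond(1))
        if smoothed.any():
            obj = smoothed

    skeleton, dist = morphology.medial_axis(obj, return_distance=True)
    pruned = _prune_spurs(skeleton, prune_length)
    if pruned.any():
        skeleton = pruned
    if not skeleton.any():
        raise ValueError("skeleton empty after pruning")

    rows, cols = np.nonzero(skeleton)
    d = dist[rows, cols].astype(np.float64)
    h, w = obj.shape
    edge_dist = np.minimum.reduce(
        [rows, cols, (h - 1) - rows, (w - 1) - cols]
    ).astype(np.float64)
    # the true nearest background might lie outside the frame
    border_flag = edge_dist <= d
    return MedialProfile(
        skeleton_points=np.column_stack([rows, cols]),
        distances=d,
        border_flag=border_flag,
    )


def largest_caliber(profile: MedialProfile) -> float:
    """LC: twice the largest medial radius."""
    return 2.0 * float(np.max(profile.usable()))


def narrowest_caliber(profile: MedialProfile, k: int = NC_POINTS) -> float:
    """NC: twice the mean of the ``k`` smallest medial radii.

    Skeletons with fewer than ``k`` usable points average over all of them.
    """
    d = np.sort(profile.usable(), kind="stable")
    return 2.0 * float(np.mean(d[: min(k, d.size)]))


def body_to_neck_ratio(lc: float, nc: float) -> float:
    if nc <= 0:
        raise ValueError("NC must be positive")
    return lc / nc


def morphometry_report(
    mask: np.ndarray,
    prune_length: int = 3,
    k: int = NC_POINTS,
    um_per_px: float | None = None,
    presmooth: bool = True,
) -> MorphometryReport:
    """Per-component LC / NC / BNR for every 8-connected object in ``mask``."""
    m = np.asarray(mask)
    if set(np.unique(m)) - {0, 1}:
        raise ValueError("mask must be binary {0, 1}")
    labels, n = measure.label(m.astype(bool), connectivity=2, return_num=True)
    if n == 0:
        raise ValueError("empty mask has no morphometry")
    comps = []
    for i in range(1, n + 1):
        comp = labels == i
        try:
            prof = medial_profile(comp, prune_length=prune_length, presmooth=presmooth)
        except ValueError:
            continue  # degenerate sliver lost entirely to pruning
        lc = largest_caliber(prof)
        nc = narrowest_caliber(prof, k=k)
        comps.append(
            ComponentReport(
                lc=lc,
                nc=nc,
                bnr=body_to_neck_ratio(lc, nc),
                n_skeleton_points=prof.n_points,
                area_px=int(comp.sum()),
            )
        )
    if not comps:
        raise ValueError("no component survived skeletonization")
    return MorphometryReport(components=comps, um_per_px=um_per_px)


def report_to_dict(report: MorphometryReport) -> dict:
    scale = report.um_per_px
    out = {"components": [], "um_per_px": scale}
    for c in report.components:
        entry = {
            "lc_px": c.lc,
            "nc_px": c.nc,
            "bnr": c.bnr,
            "n_skeleton_points": c.n_skeleton_points,
            "area_px": c.area_px,
        }
        if scale is not None:
            entry["lc_um"] = c.lc * scale
            entry["nc_um"] = c.nc * scale
        out["components"].append(entry)
    return out
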
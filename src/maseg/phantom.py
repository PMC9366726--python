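"""Synthetic AOSLO-style phantom videos with known microaneurysm geometry.

The clinical acquisition this emulates is a short video (~75 frames) of a
small retinal patch in which perfused structures — microaneurysm (MA) bodies
and the capillaries feeding and draining them — flicker frame to frame as
blood cells pass, while the surrounding tissue is static but noisy.  A
phantom therefore consists of

* a *video*: static noisy background plus perfused structures whose pixel
  intensities carry i.i.d. zero-mean Gaussian flicker of known standard
  deviation across frames;
* a *mask*: the MA bodies and their attached vessels (distractor vessels are
  perfused but deliberately excluded, mimicking background capillaries that
  are not part of the lesion);
* a *truth* record per MA: body caliber, narrowest attached-vessel width and
  the body-to-neck ratio (BNR) implied by construction.

All geometry is rasterized on an integer pixel grid: a pixel belongs to a
shape iff its center lies strictly inside the continuous shape
(``dist < D/2``).  With this convention an even-valued caliber is recovered
exactly by the medial-axis morphometry, and an odd one to within one pixel.

Feeding/draining vessels and distractors always run to the frame border, as
real capillaries continue beyond the imaged patch; morphometry flags the
resulting border-cut skeleton ends instead of letting them bias the
narrowest-caliber estimate.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

BODY_SHAPES = ("disk", "ellipse", "fusiform")

# Structural intensity levels (fractions of the dynamic range): perfused
# structures are slightly darker than tissue in the raw frames (they appear
# bright only after color inversion and in the perfusion map), the contrast
# is modest, and the flicker survives clipping at either end of the range.
_BACKGROUND_LEVEL = 0.65
_STRUCTURE_LEVEL = 0.40


@dataclass(frozen=True)
class MABody:
    """One microaneurysm body.

    ``diameter`` is the caliber of the body: the diameter of its largest
    inscribed disk.  For the elongated shapes (``ellipse``, ``fusiform``)
    this is the across-body width; ``elongation`` stretches the long axis.
    """

    center: tuple[float, float]  # (row, col)
    diameter: float
    shape: str = "disk"
    elongation: float = 1.4
    axis_angle: float = 0.0  # radians, long-axis orientation

    def __post_init__(self) -> None:
        if self.shape not in BODY_SHAPES:
            raise ValueError(f"unknown body shape {self.shape!r}")
        if self.diameter <= 0:
            raise ValueError("body diameter must be positive")


@dataclass(frozen=True)
class Vessel:
    """A capillary segment rendered as a constant-width stroke.

    ``path`` is a polyline of (row, col) vertices.  ``attached_to`` indexes
    the MABody it feeds/drains, or is None for a free-floating distractor.
    """

    path: tuple[tuple[float, float], ...]
    width: float
    attached_to: int | None = None

    def __post_init__(self) -> None:
        if len(self.path) < 2:
            raise ValueError("vessel path needs at least two vertices")


@dataclass(frozen=True)
class PhantomSpec:
    frame_size: int
    n_frames: int
    ma_bodies: tuple[MABody, ...]
    vessels: tuple[Vessel, ...]
    flicker_amplitude: float = 0.12
    background_noise_sigma: float = 0.05
    intensity_range: tuple[float, float] = (0.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_size <= 0:
            raise ValueError("frame_size must be positive")
        if self.n_frames < 2:
            raise ValueError("need at least two frames")
        if self.flicker_amplitude < 0:
            raise ValueError("flicker_amplitude must be nonnegative")
        lo, hi = self.intensity_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("intensity_range must satisfy 0 <= lo < hi <= 1")
        for v in self.vessels:
            if v.width < 1:
                raise ValueError("vessel width below 1 px cannot be rasterized")
            if v.attached_to is not None and not (
                0 <= v.attached_to < len(self.ma_bodies)
            ):
                raise ValueError("vessel attached to nonexistent body")
        for i, body in enumerate(self.ma_bodies):
            widths = [
                v.width for v in self.vessels if v.attached_to == i
            ]
            if not widths:
                raise ValueError(f"MA body {i} has no attached vessel")
            if body.diameter <= max(widths):
                raise ValueError(
                    f"MA body {i} diameter must exceed its vessel widths"
                )


@dataclass
class PhantomBundle:
    video: np.ndarray  # (n_frames, H, W) float32 in [0, 1]
    mask: np.ndarray  # (H, W) uint8 in {0, 1}
    truth: list[dict]  # per-MA: body_diameter, vessel_width, bnr
    spec: PhantomSpec = None


def _pixel_grid(n: int) -> tuple[np.ndarray, np.ndarray]:
    rr, cc = np.mgrid[0:n, 0:n]
    return rr.astype(float), cc.astype(float)


def _rasterize_body(body: MABody, n: int) -> np.ndarray:
    rr, cc = _pixel_grid(n)
    dr = rr - body.center[0]
    dc = cc - body.center[1]
    # rotate into body frame: u along long axis, v across
    ca, sa = np.cos(body.axis_angle), np.sin(body.axis_angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    r = body.diameter / 2.0
    if body.shape == "disk":
        return dr * dr + dc * dc < r * r
    if body.shape == "ellipse":
        a = r * body.elongation
        return (u / a) ** 2 + (v / r) ** 2 < 1.0
    # fusiform: lens formed by two mirrored circular arcs, thickness
    # `diameter` across the axis, half-length a along it.
    a = r * body.elongation
    big_r = (a * a + r * r) / (2.0 * r)  # arc radius through tips
    off = big_r - r
    d1 = u * u + (v - off) ** 2
    d2 = u * u + (v + off) ** 2
    return (d1 < big_r * big_r) & (d2 < big_r * big_r)


def _rasterize_vessel(vessel: Vessel, n: int) -> np.ndarray:
    rr, cc = _pixel_grid(n)
    out = np.zeros((n, n), dtype=bool)
    half = vessel.width / 2.0
    pts = np.asarray(vessel.path, dtype=float)
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        dr, dc = r1 - r0, c1 - c0
        seg2 = dr * dr + dc * dc
        if seg2 == 0:
            d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        else:
            t = ((rr - r0) * dr + (cc - c0) * dc) / seg2
            t = np.clip(t, 0.0, 1.0)
            d2 = (rr - (r0 + t * dr)) ** 2 + (cc - (c0 + t * dc)) ** 2
        out |= d2 < half * half
    return out


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Render a phantom video, mask and construction truth from ``spec``.

    Raises ``ValueError`` if two MA bodies overlap once rasterized (the
    ground truth would be ill-posed) or the spec violates its invariants.
    Output is bit-identical for identical specs (seed included).
    """
    n = spec.frame_size
    body_masks = [_rasterize_body(b, n) for b in spec.ma_bodies]
    for i in range(len(body_masks)):
        for j in range(i + 1, len(body_masks)):
            if np.any(body_masks[i] & body_masks[j]):
                raise ValueError(f"MA bodies {i} and {j} overlap")

    attached = np.zeros((n, n), dtype=bool)
    distractor = np.zeros((n, n), dtype=bool)
    for v in spec.vessels:
        stroke = _rasterize_vessel(v, n)
        if v.attached_to is None:
            distractor |= stroke
        else:
            attached |= stroke

    bodies = np.zeros((n, n), dtype=bool)
    for m in body_masks:
        bodies |= m
    mask = bodies | attached
    perfused = mask | distractor

    truth = []
    for i, body in enumerate(spec.ma_bodies):
        w = min(v.width for v in spec.vessels if v.attached_to == i)
        truth.append(
            {
                "body_diameter": float(body.diameter),
                "vessel_width": float(w),
                "bnr": float(body.diameter) / float(w),
            }
        )

    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.intensity_range
    span = hi - lo
    base = np.full((n, n), _BACKGROUND_LEVEL, dtype=np.float64)
    base[perfused] = _STRUCTURE_LEVEL
    # static spatial noise, frozen across frames
    base += rng.normal(0.0, spec.background_noise_sigma, size=(n, n))

    video = np.empty((spec.n_frames, n, n), dtype=np.float32)
    n_perf = int(perfused.sum())
    for k in range(spec.n_frames):
        frame = base.copy()
        if n_perf and spec.flicker_amplitude > 0:
            frame[perfused] += rng.normal(
                0.0, spec.flicker_amplitude, size=n_perf
            )
        video[k] = lo + span * frame
    np.clip(video, lo, hi, out=video)

    return PhantomBundle(
        video=video, mask=mask.astype(np.uint8), truth=truth, spec=spec
    )


@dataclass(frozen=True)
class SpecRanges:
    """Parameter ranges from which :func:`make_fixture_set` draws phantoms.

    Defaults reflect the working scale of the pipeline (~1 µm per pixel at
    network resolution): MA body calibers of 20–40 px and capillary widths
    of 8–16 px, one or two MAs per image with two parent vessels each, plus
    background distractor vessels of comparable width.
    """

    frame_size: int = 128
    n_frames: int = 75
    diameter_range: tuple[float, float] = (20.0, 40.0)
    width_range: tuple[float, float] = (8.0, 16.0)
    n_bodies_range: tuple[int, int] = (1, 2)
    n_distractors_range: tuple[int, int] = (1, 2)
    shapes: tuple[str, ...] = BODY_SHAPES
    flicker_amplitude: float = 0.12
    background_noise_sigma: float = 0.05

    def __post_init__(self) -> None:
        for pair in (self.diameter_range, self.width_range):
            if pair[0] > pair[1]:
                raise ValueError("empty range")
        if not self.shapes:
            raise ValueError("no body shapes to draw from")
        if self.width_range[1] >= self.diameter_range[0]:
            raise ValueError("width range must lie below diameter range")


def _border_point(rng: np.random.Generator, n: int) -> tuple[float, float]:
    side = rng.integers(4)
    t = float(rng.uniform(0, n - 1))
    return [(0.0, t), (float(n - 1), t), (t, 0.0), (t, float(n - 1))][side]


def _draw_spec(rng: np.random.Generator, ranges: SpecRanges, seed: int) -> PhantomSpec:
    n = ranges.frame_size
    n_bodies = int(rng.integers(ranges.n_bodies_range[0], ranges.n_bodies_range[1] + 1))
    bodies: list[MABody] = []
    tries = 0
    while len(bodies) < n_bodies:
        tries += 1
        if tries > 200:  # crowded frame: accept fewer bodies, keep >= 1
            if bodies:
                break
            raise RuntimeError("could not place any MA body")
        d = float(rng.uniform(*ranges.diameter_range))
        shape = str(rng.choice(ranges.shapes))
        elong = float(rng.uniform(1.2, 1.7))
        extent = d * (elong if shape != "disk" else 1.0)
        margin = extent / 2 + 4
        if 2 * margin >= n:
            continue
        center = (
            float(rng.uniform(margin, n - 1 - margin)),
            float(rng.uniform(margin, n - 1 - margin)),
        )
        cand = MABody(center, d, shape, elong, float(rng.uniform(0, np.pi)))
        if any(
            np.hypot(cand.center[0] - b.center[0], cand.center[1] - b.center[1])
            < (extent + b.diameter * b.elongation) / 2 + 6
            for b in bodies
        ):
            continue
        bodies.append(cand)

    vessels: list[Vessel] = []
    for i, body in enumerate(bodies):
        w = float(rng.uniform(*ranges.width_range))
        w = min(w, body.diameter - 2.0)
        # feeding and draining vessel on roughly opposite sides, to border
        for _ in range(2):
            end = _border_point(rng, n)
            vessels.append(Vessel((body.center, end), w, attached_to=i))
    n_dis = int(
        rng.integers(ranges.n_distractors_range[0], ranges.n_distractors_range[1] + 1)
    )
    for _ in range(n_dis):
        w = float(rng.uniform(*ranges.width_range))
        p0 = _border_point(rng, n)
        p1 = _border_point(rng, n)
        mid = (
            float(np.clip((p0[0] + p1[0]) / 2 + rng.normal(0, n / 8), 0, n - 1)),
            float(np.clip((p0[1] + p1[1]) / 2 + rng.normal(0, n / 8), 0, n - 1)),
        )
        vessels.append(Vessel((p0, mid, p1), w, attached_to=None))

    return PhantomSpec(
        frame_size=n,
        n_frames=ranges.n_frames,
        ma_bodies=tuple(bodies),
        vessels=tuple(vessels),
        flicker_amplitude=ranges.flicker_amplitude,
        background_noise_sigma=ranges.background_noise_sigma,
        seed=seed,
    )


def make_fixture_set(
    n_images: int, seed: int, spec_ranges: SpecRanges | None = None
) -> list[PhantomBundle]:
    """Draw ``n_images`` diverse phantoms, deterministically under ``seed``."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    ranges = spec_ranges if spec_ranges is not None else SpecRanges()
    master = np.random.default_rng(seed)
    bundles = []
    for k in range(n_images):
        sub_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        for _ in range(50):
            try:
                spec = _draw_spec(rng, ranges, seed=int(rng.integers(0, 2**31 - 1)))
                bundles.append(generate_phantom(spec))
                break
            except (ValueError, RuntimeError):
                continue
        else:
            raise RuntimeError(f"failed to draw a valid phantom for slot {k}")
    return bundles


def save_bundle(bundle: PhantomBundle, out_dir: str | Path, stem: str = "phantom") -> dict:
    """Write video (multi-page float32 TIFF), mask (PNG 0/255) and truth JSON."""
    import imageio.v3 as iio
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    video_path = out / f"{stem}_video.tif"
    mask_path = out / f"{stem}_mask.png"
    truth_path = out / f"{stem}_truth.json"
    tifffile.imwrite(
        video_path, bundle.video.astype(np.float32), photometric="minisblack"
    )
    iio.imwrite(mask_path, (bundle.mask * 255).astype(np.uint8))
    payload = {"truth": bundle.truth}
    if bundle.spec is not None:
        payload["spec"] = _spec_to_json(bundle.spec)
    truth_path.write_text(json.dumps(payload, indent=2))
    return {"video": str(video_path), "mask": str(mask_path), "truth": str(truth_path)}


def _spec_to_json(spec: PhantomSpec) -> dict:
    d = dataclasses.asdict(spec)
    return json.loads(json.dumps(d))  # tuples -> lists, plain types only
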
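"""End-to-end orchestration: phantom → preprocess → augment → train →
predict → postprocess → evaluate → morphometry.

A single :class:`PipelineConfig` (YAML-serializable) carries every module's
parameters plus one global seed; each stage draws its randomness from a
named substream of that seed, so re-running an unchanged config reproduces
all deterministic artifacts bit for bit.  Every run directory receives a
manifest recording the config, the per-stage seeds and a SHA-256 hash of
each output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .augment import AugmentConfig, augment_dataset
from .metrics import dice_coefficient, iou, score_summary
from .model import (
    LossConfig,
    NetworkConfig,
    TrainConfig,
    build_network,
    make_split,
    predict,
    train_model,
)
from .morphometry import morphometry_report, report_to_dict
from .phantom import SpecRanges, make_fixture_set, save_bundle
from .postprocess import DEFAULT_MIN_AREA, EnsembleSpec, binarize, clear_fragments, select_and_union
from .preprocess import EnhanceParams, TwoChannelImage, VideoStack, preprocess_video, resize_mask

log = logging.getLogger("maseg.pipeline")


@dataclass
class PhantomBlock:
    n_images: int = 8
    frame_size: int = 128
    n_frames: int = 75
    flicker_amplitude: float = 0.12
    background_noise_sigma: float = 0.05

    def ranges(self) -> SpecRanges:
        return SpecRanges(
            frame_size=self.frame_size,
            n_frames=self.n_frames,
            flicker_amplitude=self.flicker_amplitude,
            background_noise_sigma=self.background_noise_sigma,
        )


@dataclass
class PreprocessBlock:
    size: int = 512
    window: int = 5
    enhance: EnhanceParams = field(default_factory=EnhanceParams)


@dataclass
class PostprocessBlock:
    threshold: float = 0.5
    min_area: int | None = None  # None: scale 1024 px from 512×512 to `size`
    n_selected: int = 3
    clear_before_union: bool = True

    def resolved_min_area(self, size: int) -> int:
        if self.min_area is not None:
            return self.min_area
        return max(1, round(DEFAULT_MIN_AREA * (size / 512) ** 2))


@dataclass
class MorphometryBlock:
    prune_length: int = 3
    nc_points: int = 10
    um_per_px: float | None = None


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "runs/demo"
    phantom: PhantomBlock = field(default_factory=PhantomBlock)
    preprocess: PreprocessBlock = field(default_factory=PreprocessBlock)
    augment: AugmentConfig = field(default_factory=lambda: AugmentConfig(n_rotations=32))
    network: NetworkConfig = field(default_factory=lambda: NetworkConfig(encoder="tiny"))
    train: TrainConfig = field(default_factory=TrainConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    postprocess: PostprocessBlock = field(default_factory=PostprocessBlock)
    morphometry: MorphometryBlock = field(default_factory=MorphometryBlock)

    def to_dict(self) -> dict:
        return json.loads(json.dumps(dataclasses.asdict(self)))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kw = dict(d)
        for key, sub in (
            ("phantom", PhantomBlock),
            ("preprocess", PreprocessBlock),
            ("augment", AugmentConfig),
            ("network", NetworkConfig),
            ("train", TrainConfig),
            ("loss", LossConfig),
            ("postprocess", PostprocessBlock),
            ("morphometry", MorphometryBlock),
        ):
            if key in kw and isinstance(kw[key], dict):
                block = dict(kw[key])
                if key == "preprocess" and isinstance(block.get("enhance"), dict):
                    block["enhance"] = EnhanceParams(**block["enhance"])
                for tup_key in ("scale_range", "decoder_channels"):
                    if isinstance(block.get(tup_key), list):
                        block[tup_key] = tuple(block[tup_key])
                kw[key] = sub(**block)
        return cls(**kw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic named substream seed derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31 - 1)


def _small_split(n: int, seed: int) -> tuple[list[int], list[int], list[int]]:
    """Train/val/test index split for datasets below the CV protocol's floor."""
    rng = np.random.default_rng(seed)
    perm = list(rng.permutation(n))
    n_test = max(1, n // 5)
    n_val = max(1, (n - n_test) // 5)
    test = perm[:n_test]
    val = perm[n_test : n_test + n_val]
    train = perm[n_test + n_val :]
    return [int(i) for i in train], [int(i) for i in val], [int(i) for i in test]


def _prepare_inputs(config: PipelineConfig, out: Path) -> tuple[list, list[TwoChannelImage], list[np.ndarray]]:
    t0 = time.time()
    bundles = make_fixture_set(
        config.phantom.n_images,
        seed=stage_seed(config.seed, "phantom"),
        spec_ranges=config.phantom.ranges(),
    )
    phantom_dir = out / "phantom"
    for i, b in enumerate(bundles):
        save_bundle(b, phantom_dir, stem=f"{i:03d}")
    log.info("phantom: %d bundles in %.1fs", len(bundles), time.time() - t0)

    t0 = time.time()
    size = config.preprocess.size
    images, masks = [], []
    pre_dir = out / "preprocess"
    pre_dir.mkdir(parents=True, exist_ok=True)
    for i, b in enumerate(bundles):
        img = preprocess_video(
            VideoStack(b.video), size=size,
            window=config.preprocess.window, params=config.preprocess.enhance,
        )
        m = resize_mask(b.mask, size)
        images.append(img)
        masks.append(m)
        mio.write_two_channel(pre_dir / f"{i:03d}_twochannel.tif", img)
        mio.write_mask(pre_dir / f"{i:03d}_mask.png", m)
    log.info("preprocess: %d images in %.1fs", len(images), time.time() - t0)
    return bundles, images, masks


def _evaluate_and_report(
    config: PipelineConfig,
    out: Path,
    bundles,
    masks,
    test_idx: list[int],
    final_masks: dict[int, np.ndarray],
) -> dict:
    rows = []
    morpho_dir = out / "morphometry"
    morpho_dir.mkdir(parents=True, exist_ok=True)
    for i in test_idx:
        pred = final_masks[i]
        d = dice_coefficient(pred, masks[i])
        j = iou(pred, masks[i])
        row = {"image": i, "dice": d, "iou": j}
        try:
            rep = morphometry_report(
                pred,
                prune_length=config.morphometry.prune_length,
                k=config.morphometry.nc_points,
                um_per_px=config.morphometry.um_per_px,
            )
            mio.write_json(morpho_dir / f"{i:03d}_morphometry.json", report_to_dict(rep))
            row.update(
                {"lc": rep.primary.lc, "nc": rep.primary.nc, "bnr": rep.primary.bnr}
            )
        except ValueError:
            row.update({"lc": np.nan, "nc": np.nan, "bnr": np.nan})
        rows.append(row)
    scores = pd.DataFrame(rows)
    scores.to_csv(out / "scores.csv", index=False)
    summary = {
        "dice": score_summary(scores["dice"]),
        "iou": score_summary(scores["iou"]),
    }
    mio.write_json(out / "summary.json", summary)
    return summary


def _write_manifest(out: Path, config: PipelineConfig, extra: dict) -> dict:
    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config": config.to_dict(),
        "stage_seeds": {
            s: stage_seed(config.seed, s)
            for s in ("phantom", "split", "augment", "train")
        },
        "outputs": {str(p.relative_to(out)): mio.sha256_of(p) for p in files},
    }
    manifest.update(extra)
    mio.write_json(out / "manifest.json", manifest)
    return manifest


def run_pipeline(config: PipelineConfig) -> Path:
    """Single-model end-to-end run; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    bundles, images, masks = _prepare_inputs(config, out)
    n = len(images)

    split_seed = stage_seed(config.seed, "split")
    if n >= 15:
        plan = make_split(list(range(n)), seed=split_seed)
        fold = plan.folds[0]
        train_idx, val_idx, test_idx = fold["train_ids"], fold["val_ids"], plan.test_ids
    else:
        train_idx, val_idx, test_idx = _small_split(n, split_seed)

    aug_cfg = AugmentConfig(
        n_rotations=config.augment.n_rotations,
        flip_prob=config.augment.flip_prob,
        scale_range=config.augment.scale_range,
        seed=stage_seed(config.seed, "augment"),
    )
    t0 = time.time()
    train_pairs = augment_dataset([(images[i], masks[i]) for i in train_idx], aug_cfg)
    val_pairs = [(images[i], masks[i]) for i in val_idx]
    log.info("augment: %d -> %d pairs in %.1fs", len(train_idx), len(train_pairs), time.time() - t0)

    net = build_network(dataclasses.replace(config.network, seed=stage_seed(config.seed, "init")))
    tcfg = dataclasses.replace(config.train, seed=stage_seed(config.seed, "train"))
    t0 = time.time()
    net, history = train_model(train_pairs, val_pairs, net, tcfg, config.loss)
    log.info("train: %d epochs in %.1fs", len(history), time.time() - t0)
    mio.write_json(out / "history.json", {"epochs": history})

    pred_dir = out / "predict"
    pred_dir.mkdir(parents=True, exist_ok=True)
    min_area = config.postprocess.resolved_min_area(config.preprocess.size)
    final_masks = {}
    for i in test_idx:
        pmap = predict(net, images[i])
        mio.write_prob_map(pred_dir / f"{i:03d}_prob.tif", pmap)
        m = clear_fragments(binarize(pmap, config.postprocess.threshold), min_area)
        mio.write_mask(pred_dir / f"{i:03d}_mask.png", m)
        final_masks[i] = m

    _evaluate_and_report(config, out, bundles, masks, test_idx, final_masks)
    _write_manifest(
        out,
        config,
        {"split": {"train": train_idx, "val": val_idx, "test": test_idx},
         "n_train_pairs": len(train_pairs)},
    )
    return out


def run_cv_ensemble(config: PipelineConfig, n_models: int = 10) -> Path:
    """Train one model per CV fold, select the 3 best by validation Dice,
    and emit union predictions for every test image."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    bundles, images, masks = _prepare_inputs(config, out)
    n = len(images)
    plan = make_split(list(range(n)), seed=stage_seed(config.seed, "split"))
    if len(plan.folds) < n_models:
        raise ValueError("split plan has fewer folds than requested models")

    min_area = config.postprocess.resolved_min_area(config.preprocess.size)
    fold_nets, val_scores = [], []
    for k in range(n_models):
        fold = plan.folds[k]
        aug_cfg = AugmentConfig(
            n_rotations=config.augment.n_rotations,
            flip_prob=config.augment.flip_prob,
            scale_range=config.augment.scale_range,
            seed=stage_seed(config.seed, f"augment-fold{k}"),
        )
        train_pairs = augment_dataset(
            [(images[i], masks[i]) for i in fold["train_ids"]], aug_cfg
        )
        val_pairs = [(images[i], masks[i]) for i in fold["val_ids"]]
        net = build_network(
            dataclasses.replace(config.network, seed=stage_seed(config.seed, f"init-fold{k}"))
        )
        tcfg = dataclasses.replace(config.train, seed=stage_seed(config.seed, f"train-fold{k}"))
        net, _ = train_model(train_pairs, val_pairs, net, tcfg, config.loss)
        dices = []
        for i in fold["val_ids"]:
            m = clear_fragments(
                binarize(predict(net, images[i]), config.postprocess.threshold), min_area
            )
            dices.append(dice_coefficient(m, masks[i]))
        fold_nets.append(net)
        val_scores.append(float(np.mean(dices)))
        log.info("fold %d: val dice %.3f", k, val_scores[-1])

    spec = EnsembleSpec(n_models=n_models, n_selected=config.postprocess.n_selected)
    selected = list(
        np.argsort(-np.asarray(val_scores), kind="stable")[: spec.n_selected]
    )
    pred_dir = out / "ensemble"
    pred_dir.mkdir(parents=True, exist_ok=True)
    final_masks = {}
    for i in plan.test_ids:
        member_masks = []
        for net in fold_nets:
            m = binarize(predict(net, images[i]), config.postprocess.threshold)
            if config.postprocess.clear_before_union:
                m = clear_fragments(m, min_area)
            member_masks.append(m)
        union = select_and_union(member_masks, val_scores, spec)
        if not config.postprocess.clear_before_union:
            union = clear_fragments(union, min_area)
        mio.write_mask(pred_dir / f"{i:03d}_union.png", union)
        final_masks[i] = union

    _evaluate_and_report(config, out, bundles, masks, list(plan.test_ids), final_masks)
    _write_manifest(
        out,
        config,
        {
            "val_scores": val_scores,
            "selected_models": [int(s) for s in selected],
            "test_ids": [int(i) for i in plan.test_ids],
        },
    )
    return out
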
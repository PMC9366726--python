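"""Encoder–decoder segmentation network, composite loss and training policy.

The network is a 5-level U-shape: an encoder that halves resolution five
times while widening the feature maps, and a decoder of five blocks (two
3×3 convolutions each) that upsamples back to full resolution, concatenating
the matching encoder feature at every level, ending in a 1×1 convolution and
a sigmoid.  Two width presets are provided: ``"efficientnet-b3"``, whose
stage widths mirror the EfficientNet-b3 feature pyramid with the standard
(256, 128, 64, 32, 16) decoder, and ``"tiny"``, a narrow variant of the same
shape for CPU-scale experiments.  The implementation is pure NumPy with
explicit backpropagation (see :mod:`maseg.nn`).

Training minimizes ``BCE + α · (1 − Dice)`` with α = 0.2, where BCE is the
per-pixel mean binary cross-entropy and Dice is the soft Dice similarity
computed on probabilities (the hard pixel count is not differentiable), with
Adam (lr 0.001, weight decay 1e-8), batch size 16, and a plateau scheduler
that divides the learning rate by 10 once the validation loss has not
decreased for five epochs.

Data splitting follows the cross-validation protocol: one fifth of the
images is reserved for testing and the remaining pool is divided into 10
folds, each serving once as the validation set — for 87 images this yields
the 63 : 7 : 17 train/validation/test split.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn import Adam, Conv2d, ConvBlock, MaxPool2, PlateauScheduler, Upsample2, sigmoid
from .preprocess import TwoChannelImage

ENCODER_PRESETS = {
    # stem width, stage widths (5 levels), default decoder channels
    "efficientnet-b3": (40, (24, 32, 48, 136, 384), (256, 128, 64, 32, 16)),
    "tiny": (8, (12, 16, 24, 32, 40), (32, 24, 16, 12, 8)),
}


@dataclass(frozen=True)
class NetworkConfig:
    encoder: str = "efficientnet-b3"
    encoder_depth: int = 5
    decoder_channels: tuple[int, ...] | None = None
    in_channels: int = 2
    pretrained: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.encoder not in ENCODER_PRESETS:
            raise ValueError(f"unknown encoder preset {self.encoder!r}")
        if self.encoder_depth != 5:
            raise ValueError("only encoder depth 5 is supported")
        if self.decoder_channels is not None and len(self.decoder_channels) != self.encoder_depth:
            raise ValueError("decoder_channels length must equal encoder_depth")
        if self.pretrained:
            raise ValueError(
                "pretrained encoder weights are not bundled with this package"
            )


@dataclass(frozen=True)
class LossConfig:
    alpha: float = 0.2
    clip_eps: float = 1e-7

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if not 0 < self.clip_eps < 0.5:
            raise ValueError("clip_eps must lie in (0, 0.5)")


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 0.001
    weight_decay: float = 1e-8
    max_epochs: int = 200
    batch_size: int = 16
    plateau_patience: int = 5
    plateau_factor: float = 0.1
    input_size: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lr, self.weight_decay, self.batch_size, self.input_size) <= 0:
            raise ValueError("lr, weight_decay, batch_size, input_size must be positive")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be nonnegative")
        if not 0 < self.plateau_factor < 1:
            raise ValueError("plateau_factor must lie in (0, 1)")


class SegmentationNetwork:
    """5-level U-shaped encoder–decoder mapping (B, 2, H, W) -> (B, 1, H, W)."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        stem_w, stages, dec_default = ENCODER_PRESETS[config.encoder]
        dec = tuple(config.decoder_channels) if config.decoder_channels else dec_default
        rng = np.random.default_rng(config.seed)
        self.stem = ConvBlock(config.in_channels, stem_w, rng)
        self.pools = [MaxPool2() for _ in range(5)]
        self.enc: list[ConvBlock] = []
        prev = stem_w
        for w in stages:
            self.enc.append(ConvBlock(prev, w, rng))
            prev = w
        skip_widths = (stages[3], stages[2], stages[1], stages[0], stem_w)
        self.ups = [Upsample2() for _ in range(5)]
        self.dec: list[ConvBlock] = []
        for dc, sk in zip(dec, skip_widths):
            self.dec.append(ConvBlock(prev + sk, dc, rng))
            prev = dc
        self.head = Conv2d(prev, 1, 1, rng)
        self.decoder_channels = dec

    @property
    def params(self):
        out = list(self.stem.params)
        for b in self.enc:
            out += b.params
        for b in self.dec:
            out += b.params
        out += self.head.params
        return out

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError("input must be (B, in_channels, H, W)")
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError("spatial size must be a multiple of 32")
        feats = [self.stem.forward(x)]
        y = feats[0]
        for pool, block in zip(self.pools, self.enc):
            y = block.forward(pool.forward(y))
            feats.append(y)
        skips = feats[-2::-1]  # deepest-but-one ... stem
        self._splits = []
        for up, block, skip in zip(self.ups, self.dec, skips):
            y = up.forward(y)
            self._splits.append((y.shape[1], skip.shape[1]))
            y = block.forward(np.concatenate([y, skip], axis=1))
        return self.head.forward(y)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = []
        for up, block, (c_up, c_skip) in zip(
            reversed(self.ups), reversed(self.dec), reversed(self._splits)
        ):
            d = block.backward(d)
            dskips.append(d[:, c_up:])
            d = up.backward(d[:, :c_up])
        # dskips[k] is the skip gradient reaching encoder feature k
        # (last decoder block consumes the stem, so it is appended first)
        denc = d  # gradient flowing into the deepest encoder feature
        for i in range(4, -1, -1):
            denc = self.enc[i].backward(denc)
            denc = self.pools[i].backward(denc)
            denc = denc + dskips[i]
        self.stem.backward(denc)

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params, state):
            p.value[...] = v


def build_network(config: NetworkConfig | None = None) -> SegmentationNetwork:
    return SegmentationNetwork(config or NetworkConfig())


def _as_array(x) -> np.ndarray:
    if isinstance(x, TwoChannelImage):
        return np.transpose(np.asarray(x.data, dtype=np.float64), (2, 0, 1))
    return np.asarray(x, dtype=np.float64)


def predict(net: SegmentationNetwork, image: TwoChannelImage | np.ndarray) -> np.ndarray:
    """Probability map in (0, 1) for one two-channel image; deterministic."""
    x = _as_array(image)
    if x.ndim == 3:
        x = x[None]
    logits = net.forward_logits(x)
    return sigmoid(logits)[0, 0]


def _soft_dice(p: np.ndarray, y: np.ndarray, smooth: float = 1.0) -> float:
    num = 2.0 * float((p * y).sum()) + smooth
    den = float(p.sum()) + float(y.sum()) + smooth
    return num / den


def composite_loss(pred: np.ndarray, target: np.ndarray, config: LossConfig | None = None) -> float:
    """``mean-BCE + α · (1 − soft Dice)`` for one probability map / mask pair.

    The soft Dice uses probabilities directly (Σ xy over Σ x + Σ y, smoothed
    by 1 against empty masks); probabilities are clipped to
    ``[clip_eps, 1 − clip_eps]`` before the logarithms.
    """
    cfg = config or LossConfig()
    p = np.asarray(pred, dtype=np.float64)
    y = np.asarray(target, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError("prediction and target shapes differ")
    pc = np.clip(p, cfg.clip_eps, 1.0 - cfg.clip_eps)
    bce = -float(np.mean(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)))
    return bce + cfg.alpha * (1.0 - _soft_dice(pc, y))


def _batch_loss_and_grad(
    logits: np.ndarray, targets: np.ndarray, cfg: LossConfig
) -> tuple[float, np.ndarray]:
    """Mean composite loss over a batch and its gradient w.r.t. the logits."""
    p = sigmoid(logits)
    pc = np.clip(p, cfg.clip_eps, 1.0 - cfg.clip_eps)
    y = targets
    b = logits.shape[0]
    npix = logits[0].size
    live = (p > cfg.clip_eps) & (p < 1.0 - cfg.clip_eps)

    bce = -float(np.mean(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)))
    dz = np.where(live, (p - y) / (b * npix), 0.0)

    dice_total = 0.0
    smooth = 1.0
    for s in range(b):
        ps, ys = pc[s], y[s]
        num = 2.0 * float((ps * ys).sum()) + smooth
        den = float(ps.sum()) + float(ys.sum()) + smooth
        dice_total += num / den
        ddice_dp = (2.0 * ys * den - num) / (den * den)
        dz[s] += np.where(
            live[s], -cfg.alpha / b * ddice_dp * p[s] * (1.0 - p[s]), 0.0
        )
    loss = bce + cfg.alpha * (1.0 - dice_total / b)
    return loss, dz


@dataclass
class SplitPlan:
    test_ids: list
    folds: list[dict]  # each: {"train_ids": [...], "val_ids": [...]}

    @property
    def pool_ids(self) -> list:
        return sorted(
            {i for f in self.folds for i in f["train_ids"] + f["val_ids"]},
            key=str,
        )


def make_split(ids, seed: int, n_folds: int = 10) -> SplitPlan:
    """Reserve ⌊n/5⌋ ids as the test set; 10-fold CV over the remaining pool."""
    ids = list(ids)
    if len(ids) < 15:
        raise ValueError("need at least 15 ids for the split protocol")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    n_test = len(ids) // 5
    test_ids = perm[:n_test]
    pool = perm[n_test:]
    chunks = np.array_split(np.arange(len(pool)), n_folds)
    folds = []
    for ch in chunks:
        val = [pool[i] for i in ch]
        train = [p for p in pool if p not in val]
        folds.append({"train_ids": train, "val_ids": val})
    return SplitPlan(test_ids=test_ids, folds=folds)


def pairs_to_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    xs = np.stack([_as_array(img) for img, _ in pairs])
    ys = np.stack([np.asarray(m, dtype=np.float64)[None] for _, m in pairs])
    return xs, ys


def train_model(
    train_pairs,
    val_pairs,
    net: SegmentationNetwork,
    train_config: TrainConfig | None = None,
    loss_config: LossConfig | None = None,
) -> tuple[SegmentationNetwork, list[dict]]:
    """Train ``net``; returns the best-validation-loss checkpoint and history.

    ``history`` holds one record per epoch: train loss, validation loss and
    the learning rate in force during that epoch.  Raises ``RuntimeError``
    on divergence (non-finite loss).
    """
    cfg = train_config or TrainConfig()
    lcfg = loss_config or LossConfig()
    if len(train_pairs) == 0 or len(val_pairs) == 0:
        raise ValueError("train and validation sets must be nonempty")
    if cfg.max_epochs == 0:
        return net, []

    xtr, ytr = pairs_to_arrays(train_pairs)
    xva, yva = pairs_to_arrays(val_pairs)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    sched = PlateauScheduler(opt, patience=cfg.plateau_patience, factor=cfg.plateau_factor)

    best_val = np.inf
    best_state = net.state()
    history: list[dict] = []
    n = len(xtr)
    for epoch in range(cfg.max_epochs):
        lr_now = opt.lr
        order = rng.permutation(n)
        train_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            opt.zero_grad()
            logits = net.forward_logits(xtr[idx])
            loss, dz = _batch_loss_and_grad(logits, ytr[idx], lcfg)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch} (loss={loss})")
            net.backward(dz)
            opt.step()
            train_losses.append(loss)

        val_losses = []
        for start in range(0, len(xva), cfg.batch_size):
            logits = net.forward_logits(xva[start : start + cfg.batch_size])
            vl, _ = _batch_loss_and_grad(logits, yva[start : start + cfg.batch_size], lcfg)
            val_losses.append(vl * len(logits))
        val_loss = float(np.sum(val_losses) / len(xva))
        if not np.isfinite(val_loss):
            raise RuntimeError(f"validation loss diverged at epoch {epoch}")

        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(train_losses)),
             "val_loss": val_loss, "lr": lr_now}
        )
        if val_loss < best_val:
            best_val = val_loss
            best_state = net.state()
        sched.step(val_loss)

    net.load_state(best_state)
    return net, history


def save_checkpoint(
    net: SegmentationNetwork, path: str | Path, history: list[dict] | None = None
) -> None:
    """Write parameters as .npz with a JSON sidecar (config + history)."""
    path = Path(path)
    np.savez(path, **{f"p{i}": v for i, v in enumerate(net.state())})
    sidecar = {"network": dataclasses.asdict(net.config), "history": history or []}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> tuple[SegmentationNetwork, list[dict]]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_d = dict(sidecar["network"])
    if cfg_d.get("decoder_channels"):
        cfg_d["decoder_channels"] = tuple(cfg_d["decoder_channels"])
    net = SegmentationNetwork(NetworkConfig(**cfg_d))
    data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    net.load_state([data[k] for k in sorted(data.files, key=lambda s: int(s[1:]))])
    return net, sidecar.get("history", [])
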
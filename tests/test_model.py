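"""Network construction, composite loss, split protocol, training policy."""

import math

import numpy as np
import pytest

from maseg.model import (
    LossConfig,
    NetworkConfig,
    TrainConfig,
    build_network,
    composite_loss,
    load_checkpoint,
    make_split,
    predict,
    save_checkpoint,
    train_model,
)
from maseg.model import _batch_loss_and_grad
from maseg.nn import Adam, Param, PlateauScheduler
from maseg.preprocess import TwoChannelImage


def scalar_loss_oracle(pred, target, alpha=0.2, eps=1e-7):
    """Independent per-pixel loop implementation of BCE + α(1 − soft Dice)."""
    bce_sum = 0.0
    inter = psum = tsum = 0.0
    n = 0
    for x, y in zip(pred.ravel().tolist(), target.ravel().tolist()):
        x = min(max(x, eps), 1 - eps)
        bce_sum += y * math.log(x) + (1 - y) * math.log(1 - x)
        inter += x * y
        psum += x
        tsum += y
        n += 1
    dice = (2 * inter + 1) / (psum + tsum + 1)
    return -bce_sum / n + alpha * (1 - dice)


class TestBuildNetwork:
    def test_shape_and_range_contract(self, rng):
        net = build_network(NetworkConfig(encoder="tiny", seed=0))
        x = rng.random((1, 2, 64, 64))
        pmap = predict(net, x[0])
        assert pmap.shape == (64, 64)
        assert np.all((pmap > 0) & (pmap < 1))

    def test_decoder_has_five_blocks(self):
        net = build_network(NetworkConfig(encoder="tiny", seed=0))
        assert len(net.dec) == 5
        full = build_network(NetworkConfig(seed=0))
        assert full.decoder_channels == (256, 128, 64, 32, 16)

    def test_seeded_init_identical(self):
        a = build_network(NetworkConfig(encoder="tiny", seed=3))
        b = build_network(NetworkConfig(encoder="tiny", seed=3))
        for pa, pb in zip(a.params, b.params):
            assert np.array_equal(pa.value, pb.value)

    def test_bad_configs_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(encoder="resnet50")
        with pytest.raises(ValueError):
            NetworkConfig(decoder_channels=(64, 32, 16))
        with pytest.raises(ValueError):
            NetworkConfig(pretrained=True)

    def test_indivisible_size_rejected(self, rng):
        net = build_network(NetworkConfig(encoder="tiny", seed=0))
        with pytest.raises(ValueError):
            net.forward_logits(rng.random((1, 2, 60, 60)))


class TestCompositeLoss:
    def test_perfect_prediction_tends_to_zero(self):
        t = np.zeros((8, 8))
        t[:4] = 1
        for eps in (1e-3, 1e-5, 1e-7):
            loss = composite_loss(t.copy(), t, LossConfig(clip_eps=eps))
            assert loss < composite_loss(t.copy(), t, LossConfig(clip_eps=10 * eps)) + 1e-12
        assert composite_loss(t.copy(), t, LossConfig(clip_eps=1e-7)) < 1e-4

    def test_uniform_half_gives_ln2_bce(self):
        t = (np.arange(64).reshape(8, 8) % 2).astype(float)
        p = np.full((8, 8), 0.5)
        loss = composite_loss(p, t, LossConfig(alpha=0.0))
        assert loss == pytest.approx(math.log(2))

    def test_matches_scalar_loop_oracle(self, rng):
        for _ in range(5):
            p = rng.random((8, 8))
            t = (rng.random((8, 8)) > 0.5).astype(float)
            assert composite_loss(p, t) == pytest.approx(
                scalar_loss_oracle(p, t), abs=1e-6
            )

    def test_dice_term_flip_invariant(self, rng):
        p = rng.random((8, 8))
        t = (rng.random((8, 8)) > 0.5).astype(float)
        cfg = LossConfig(alpha=5.0)
        flipped = composite_loss(p[::-1, ::-1], t[::-1, ::-1], cfg)
        assert composite_loss(p, t, cfg) == pytest.approx(flipped, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            composite_loss(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_batch_loss_matches_composite_loss(self, rng):
        z = rng.normal(size=(1, 1, 8, 8))
        t = (rng.random((1, 1, 8, 8)) > 0.5).astype(float)
        from maseg.nn import sigmoid

        loss, _ = _batch_loss_and_grad(z, t, LossConfig())
        assert loss == pytest.approx(composite_loss(sigmoid(z)[0, 0], t[0, 0]), abs=1e-12)

    def test_batch_gradient_matches_finite_differences(self, rng):
        z = rng.normal(size=(2, 1, 6, 6))
        t = (rng.random((2, 1, 6, 6)) > 0.5).astype(float)
        cfg = LossConfig()
        _, dz = _batch_loss_and_grad(z, t, cfg)
        eps = 1e-6
        for idx in [(0, 0, 1, 2), (1, 0, 5, 5), (0, 0, 3, 3)]:
            zp, zm = z.copy(), z.copy()
            zp[idx] += eps
            zm[idx] -= eps
            num = (
                _batch_loss_and_grad(zp, t, cfg)[0] - _batch_loss_and_grad(zm, t, cfg)[0]
            ) / (2 * eps)
            assert dz[idx] == pytest.approx(num, rel=1e-5, abs=1e-10)


class TestMakeSplit:
    def test_87_images_reproduce_63_7_17(self):
        plan = make_split(list(range(87)), seed=0)
        assert len(plan.test_ids) == 17
        for fold in plan.folds:
            assert len(fold["val_ids"]) == 7
            assert len(fold["train_ids"]) == 63

    def test_50_images_arithmetic(self):
        plan = make_split(list(range(50)), seed=1)
        assert len(plan.test_ids) == 10
        assert all(len(f["val_ids"]) == 4 and len(f["train_ids"]) == 36 for f in plan.folds)

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_union_disjointness_invariants(self, seed):
        ids = [f"img{i}" for i in range(33)]
        plan = make_split(ids, seed=seed)
        pool = set(ids) - set(plan.test_ids)
        assert not set(plan.test_ids) & pool
        all_val = []
        for fold in plan.folds:
            tr, va = set(fold["train_ids"]), set(fold["val_ids"])
            assert not tr & va
            assert tr | va == pool
            all_val.extend(fold["val_ids"])
        assert sorted(all_val) == sorted(pool)  # each pool id validates once

    def test_determinism_and_too_few(self):
        a = make_split(list(range(20)), seed=5)
        b = make_split(list(range(20)), seed=5)
        assert a.test_ids == b.test_ids and a.folds == b.folds
        with pytest.raises(ValueError):
            make_split(list(range(14)), seed=0)


class TestTrainingPolicy:
    def test_plateau_divides_lr_by_ten_after_five_stale_epochs(self):
        opt = Adam([Param(np.zeros(1))], lr=0.001)
        sched = PlateauScheduler(opt, patience=5, factor=0.1)
        sched.step(1.0)  # initial best
        for i in range(4):
            assert not sched.step(1.0)
            assert opt.lr == pytest.approx(0.001)
        assert sched.step(1.0)  # fifth non-improving epoch triggers
        assert opt.lr == pytest.approx(0.0001)

    def test_improvement_resets_patience(self):
        opt = Adam([Param(np.zeros(1))], lr=0.001)
        sched = PlateauScheduler(opt, patience=5, factor=0.1)
        losses = [1.0, 1.0, 1.0, 0.9, 1.0, 1.0, 1.0, 1.0]
        for lo in losses:
            sched.step(lo)
        assert opt.lr == pytest.approx(0.001)

    def test_zero_epochs_returns_untrained_net(self, rng):
        net = build_network(NetworkConfig(encoder="tiny", seed=0))
        img = TwoChannelImage(rng.random((64, 64, 2)))
        mask = (rng.random((64, 64)) > 0.5).astype(np.uint8)
        before = [p.value.copy() for p in net.params]
        net2, hist = train_model([(img, mask)], [(img, mask)], net,
                                 TrainConfig(max_epochs=0, input_size=64))
        assert hist == []
        for p, b in zip(net2.params, before):
            assert np.array_equal(p.value, b)

    def test_empty_sets_rejected(self, rng):
        net = build_network(NetworkConfig(encoder="tiny", seed=0))
        with pytest.raises(ValueError):
            train_model([], [], net, TrainConfig(max_epochs=1, input_size=64))

    def test_single_phantom_overfit_reduces_loss(self, reference_bundle):
        from maseg.preprocess import VideoStack, preprocess_video, resize_mask

        img = preprocess_video(VideoStack(reference_bundle.video), size=64)
        mask = resize_mask(reference_bundle.mask, 64)
        net = build_network(NetworkConfig(encoder="tiny", seed=1))
        net, hist = train_model(
            [(img, mask)] * 4,
            [(img, mask)],
            net,
            TrainConfig(max_epochs=6, batch_size=4, input_size=64, seed=1),
        )
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]
        assert all(h["lr"] == pytest.approx(0.001) for h in hist[:2])


class TestPredict:
    def test_inference_deterministic(self, rng):
        net = build_network(NetworkConfig(encoder="tiny", seed=0))
        img = TwoChannelImage(rng.random((64, 64, 2)))
        assert np.array_equal(predict(net, img), predict(net, img))

    def test_checkpoint_roundtrip(self, rng, tmp_path):
        net = build_network(NetworkConfig(encoder="tiny", seed=2))
        img = TwoChannelImage(rng.random((64, 64, 2)))
        save_checkpoint(net, tmp_path / "ckpt.npz", history=[{"epoch": 0}])
        net2, hist = load_checkpoint(tmp_path / "ckpt.npz")
        assert hist == [{"epoch": 0}]
        assert np.array_equal(predict(net, img), predict(net2, img))
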
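import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tileseg.model import ModelConfig, build_model
from tileseg.training import (
    AugmentConfig,
    PlateauSchedule,
    TrainConfig,
    augment,
    dice_loss,
    dice_loss_grad,
    fit,
)

IDENTITY_AUG = AugmentConfig(
    p_hflip=0.0, p_rotate=0.0, p_brightness=0.0, p_contrast=0.0,
    p_blur=0.0, p_sharpen=0.0, p_noise=0.0,
)


class TestDiceLoss:
    def test_perfect_agreement(self):
        t = (np.random.default_rng(0).random((2, 4, 6, 6)) > 0.5).astype(np.float64)
        assert t.sum() > 0
        assert dice_loss(t, t, eps=1.0) == pytest.approx(0.0)

    def test_uniform_half_vs_ones(self):
        # dice = 2(0.5n)/(0.5n + n) = 2/3 as eps -> 0, so loss = 1/3
        probs = np.full((1, 4, 8, 8), 0.5)
        targets = np.ones((1, 4, 8, 8))
        assert dice_loss(probs, targets, eps=1e-9) == pytest.approx(1 / 3, rel=1e-6)

    def test_disjoint_single_pixels(self):
        # (2*0 + 1) / (1 + 1 + 1) = 1/3 dice, loss 2/3
        probs = np.zeros((1, 1, 4, 4))
        targets = np.zeros((1, 1, 4, 4))
        probs[0, 0, 0, 0] = 1.0
        targets[0, 0, 3, 3] = 1.0
        # single-channel planes not supported by the 4-channel pipeline, but
        # the loss itself is shape-generic
        assert dice_loss(probs, targets, eps=1.0) == pytest.approx(2 / 3)

    def test_brute_force_cross_check(self):
        rng = np.random.default_rng(1)
        probs = rng.random((2, 4, 5, 5))
        targets = (rng.random((2, 4, 5, 5)) > 0.5).astype(float)
        eps = 1.0
        acc = []
        for n in range(2):
            for c in range(4):
                p, t = probs[n, c].ravel(), targets[n, c].ravel()
                acc.append((2 * float(p @ t) + eps) / (float(p.sum() + t.sum()) + eps))
        assert dice_loss(probs, targets, eps) == pytest.approx(1 - np.mean(acc))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((1, 4, 3, 3)), np.zeros((1, 4, 3, 4)))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_range_and_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        probs = rng.random((1, 4, 4, 4))
        targets = (rng.random((1, 4, 4, 4)) > 0.3).astype(float)
        loss = dice_loss(probs, targets)
        assert 0.0 <= loss <= 1.0
        perm = rng.permutation(16)
        pp = probs.reshape(1, 4, 16)[:, :, perm].reshape(1, 4, 4, 4)
        tt = targets.reshape(1, 4, 16)[:, :, perm].reshape(1, 4, 4, 4)
        assert dice_loss(pp, tt) == pytest.approx(loss)

    def test_zero_iff_equal_binary(self):
        rng = np.random.default_rng(2)
        t = (rng.random((1, 4, 5, 5)) > 0.5).astype(float)
        p = t.copy()
        p[0, 0, 0, 0] = 1.0 - p[0, 0, 0, 0]
        assert dice_loss(t, t) == pytest.approx(0.0)
        assert dice_loss(p, t) > 0.0

    def test_gradient_matches_numeric(self):
        rng = np.random.default_rng(3)
        probs = rng.random((2, 4, 4, 4))
        targets = (rng.random((2, 4, 4, 4)) > 0.5).astype(float)
        grad = dice_loss_grad(probs, targets, eps=1.0)
        eps = 1e-5
        for idx in [(0, 0, 1, 1), (1, 3, 2, 0)]:
            up, down = probs.copy(), probs.copy()
            up[idx] += eps
            down[idx] -= eps
            num = (dice_loss(up, targets) - dice_loss(down, targets)) / (2 * eps)
            assert grad[idx] == pytest.approx(num, rel=1e-3, abs=1e-8)


class TestTrainConfig:
    def test_lr_ordering(self):
        with pytest.raises(ValueError):
            TrainConfig(initial_lr=1e-4, reduced_lr=1e-3)

    def test_patience_positive(self):
        with pytest.raises(ValueError):
            TrainConfig(patience=0)


class TestAugment:
    def _pair(self, seed=0, h=20, w=30):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(h, w), dtype=np.uint8)
        mask = rng.random((4, h, w)) > 0.7
        return img, mask

    def test_identity_with_zero_probs(self):
        img, mask = self._pair()
        out_img, out_mask = augment(img, mask, IDENTITY_AUG, np.random.default_rng(0))
        assert np.allclose(out_img, img.astype(np.float32) / 255.0)
        assert np.array_equal(out_mask, mask)

    def test_mask_stays_binary(self):
        img, mask = self._pair(1)
        aug = AugmentConfig()  # all transforms possible
        for seed in range(10):
            _, out_mask = augment(img, mask, aug, np.random.default_rng(seed))
            assert out_mask.dtype == bool

    def test_hflip_involution(self):
        img, mask = self._pair(2)
        flip_only = AugmentConfig(
            p_hflip=1.0, p_rotate=0.0, p_brightness=0.0, p_contrast=0.0,
            p_blur=0.0, p_sharpen=0.0, p_noise=0.0,
        )
        once_img, once_mask = augment(img, mask, flip_only, np.random.default_rng(0))
        twice_img, twice_mask = augment(once_img, once_mask, flip_only,
                                        np.random.default_rng(1))
        assert np.allclose(twice_img, img.astype(np.float32) / 255.0, atol=1e-6)
        assert np.array_equal(twice_mask, mask)

    def test_geometric_applied_jointly(self):
        # a flip moves image and mask identically
        img, mask = self._pair(3)
        flip_only = AugmentConfig(
            p_hflip=1.0, p_rotate=0.0, p_brightness=0.0, p_contrast=0.0,
            p_blur=0.0, p_sharpen=0.0, p_noise=0.0,
        )
        out_img, out_mask = augment(img, mask, flip_only, np.random.default_rng(0))
        assert np.allclose(out_img, img[:, ::-1].astype(np.float32) / 255.0)
        assert np.array_equal(out_mask, mask[:, :, ::-1])


def brute_force_schedule(val_losses, patience, min_delta=1e-4):
    """Reference implementation of the two-stage plateau rules."""
    best = float("inf")
    bad = 0
    reduced = None
    for epoch, loss in enumerate(val_losses, start=1):
        if loss < best - min_delta:
            best = loss
            bad = 0
            continue
        bad += 1
        if bad >= patience:
            if reduced is None:
                reduced = epoch
                bad = 0
            else:
                return reduced, epoch
    return reduced, None


class TestPlateauSchedule:
    def test_scripted_constant_sequence(self):
        # [.5]*12: reduce after epoch 6, stop after epoch 11 (patience 5)
        sched = PlateauSchedule(patience=5)
        actions = [sched.update(0.5) for _ in range(12)]
        assert actions.index("reduce") == 5  # epoch 6
        assert actions.index("stop") == 10  # epoch 11
        assert actions[:5] == ["continue"] * 5

    def test_improving_never_triggers(self):
        sched = PlateauSchedule(patience=5)
        for k in range(30):
            assert sched.update(1.0 - 0.01 * k) == "continue"

    @given(
        seed=st.integers(0, 10_000),
        patience=st.integers(1, 5),
        n=st.integers(1, 40),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_reference(self, seed, patience, n):
        rng = np.random.default_rng(seed)
        losses = rng.choice([0.1, 0.2, 0.3, 0.4], size=n).tolist()
        sched = PlateauSchedule(patience=patience)
        reduce_epoch, stop_epoch = None, None
        for epoch, loss in enumerate(losses, start=1):
            action = sched.update(loss)
            if action == "reduce":
                assert reduce_epoch is None  # at most one reduction
                reduce_epoch = epoch
            elif action == "stop":
                stop_epoch = epoch
                break
        ref_reduce, ref_stop = brute_force_schedule(losses, patience)
        assert reduce_epoch == ref_reduce
        assert stop_epoch == ref_stop
        if stop_epoch is not None:
            assert reduce_epoch is not None and reduce_epoch < stop_epoch


def _toy_tiles(n, h=16, w=16, seed=0):
    rng = np.random.default_rng(seed)
    tiles = []
    for _ in range(n):
        mask = np.zeros((4, h, w), dtype=bool)
        r, c = rng.integers(2, h - 6), rng.integers(2, w - 6)
        mask[rng.integers(0, 4), r : r + 4, c : c + 4] = True
        img = np.full((h, w), 40, dtype=np.uint8)
        img[mask.any(axis=0)] = 220
        tiles.append((img, mask))
    return tiles


class TestFit:
    CFG = ModelConfig(input_size=16, depth=2, base_width=4)

    def test_empty_split_rejected(self):
        model = build_model(self.CFG, seed=0)
        with pytest.raises(ValueError):
            fit(model, [], _toy_tiles(2), TrainConfig())

    def test_history_contract_and_determinism(self):
        tiles = _toy_tiles(6)
        cfg = TrainConfig(batch_size=4, max_epochs=3, seed=5)
        histories = []
        for _ in range(2):
            model = build_model(self.CFG, seed=5)
            _, hist = fit(model, tiles[:4], tiles[4:], cfg, IDENTITY_AUG)
            histories.append(hist)
        a, b = histories
        assert a.epochs == b.epochs
        assert [e["epoch"] for e in a.epochs] == [1, 2, 3]
        lrs = [e["lr"] for e in a.epochs]
        assert all(x >= y for x, y in zip(lrs, lrs[1:]))  # lr non-increasing
        assert a.stop_epoch <= cfg.max_epochs

    def test_overfit_sanity(self):
        # capacity check: 5 tiles must be memorized
        tiles = _toy_tiles(5, seed=3)
        model = build_model(self.CFG, seed=1)
        cfg = TrainConfig(initial_lr=3e-3, reduced_lr=3e-4, batch_size=1,
                          max_epochs=200, patience=200, seed=1)
        model, hist = fit(model, tiles, tiles, cfg, IDENTITY_AUG)
        assert hist.epochs[-1]["train_loss"] < 0.1

    def test_normalizer_fitted_from_train_split(self):
        tiles = _toy_tiles(6, seed=4)
        model = build_model(self.CFG, seed=0)
        model, _ = fit(model, tiles[:4], tiles[4:],
                       TrainConfig(max_epochs=1, seed=0), IDENTITY_AUG)
        flat = np.concatenate(
            [t[0].astype(np.float32).ravel() / 255.0 for t in tiles[:4]]
        )
        assert model.normalizer.mean == pytest.approx(float(flat.mean()))
        assert model.normalizer.sd == pytest.approx(float(flat.std()))
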
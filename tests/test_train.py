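"""Patch sampling, masked Dice loss, Jaccard, and the training loop."""

import logging

import numpy as np
import pytest

import hepaseg as hs
from hepaseg.train import Trainer, dilate_liver, sample_patch


@pytest.fixture(scope="module")
def tiny_train_cfg(tiny_geometry):
    return hs.TrainConfig(batch_size=1, learning_rate=3e-3, total_iterations=50,
                          val_interval=25, input_patch=tiny_geometry.input_extent)


class TestMaskedDiceLoss:
    def test_perfect_prediction_near_zero(self):
        t = np.zeros((20, 20, 5), np.float32)
        t[4:16, 4:16, 1:4] = 1  # |t| = 432 >= 500 is not needed; smooth shrinks fast
        w = np.ones_like(t)
        assert hs.masked_dice_loss(t, t, w) <= 1e-3

    def test_total_miss_near_one(self):
        p = np.zeros((40, 40, 2), np.float32)
        t = np.zeros_like(p)
        p[:25, :20, 0] = 1  # 500 voxels
        t[:25, :20, 1] = 1  # disjoint 500 voxels
        assert hs.masked_dice_loss(p, t, np.ones_like(p)) >= 0.99

    def test_half_overlap_gives_half_without_smoothing(self):
        p = np.zeros((30, 30, 1), np.float32)
        t = np.zeros_like(p)
        p[0:10, 0:10] = 1            # |p| = 100
        t[5:15, 0:10] = 1            # |t| = 100, overlap 50
        loss = hs.masked_dice_loss(p, t, np.ones_like(p), smooth=0.0)
        assert loss == pytest.approx(0.5)

    def test_voxels_outside_weight_mask_do_not_matter(self):
        rng = np.random.default_rng(0)
        p = rng.random((12, 12, 4)).astype(np.float32)
        t = (rng.random((12, 12, 4)) < 0.4).astype(np.float32)
        w = np.zeros_like(t)
        w[3:9, 3:9, :] = 1
        base = hs.masked_dice_loss(p, t, w)
        t2 = t.copy()
        t2[0, 0, 0] = 1 - t2[0, 0, 0]   # outside the weight mask
        p2 = p.copy()
        p2[11, 11, 3] = 1 - p2[11, 11, 3]
        assert hs.masked_dice_loss(p2, t2, w) == pytest.approx(base, abs=1e-7)

    def test_all_zero_weight_returns_zero(self, caplog):
        p = np.ones((4, 4, 2), np.float32)
        with caplog.at_level(logging.WARNING, logger="hepaseg"):
            loss = hs.masked_dice_loss(p, p, np.zeros_like(p))
        assert loss == 0.0
        assert "degenerate" in caplog.text

    def test_loss_bounded_in_unit_interval(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.random((8, 8, 3)).astype(np.float32)
            t = (rng.random((8, 8, 3)) < 0.5).astype(np.float32)
            w = (rng.random((8, 8, 3)) < 0.7).astype(np.float32)
            assert 0.0 <= hs.masked_dice_loss(p, t, w) <= 1.0

    def test_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(2)
        p = rng.random((6, 6, 2)).astype(np.float64)
        t = (rng.random((6, 6, 2)) < 0.4).astype(np.float64)
        w = (rng.random((6, 6, 2)) < 0.8).astype(np.float64)
        _, grad = hs.masked_dice_loss(p, t, w, with_grad=True)
        eps = 1e-6
        for idx in [(0, 0, 0), (3, 4, 1), (5, 5, 0)]:
            pp, pm = p.copy(), p.copy()
            pp[idx] += eps
            pm[idx] -= eps
            fd = (hs.masked_dice_loss(pp, t, w) - hs.masked_dice_loss(pm, t, w)) / (2 * eps)
            assert fd == pytest.approx(float(grad[idx]), rel=1e-3, abs=1e-9)


class TestJaccard:
    def test_identical_and_disjoint_and_counting(self):
        a = np.zeros((4, 4, 1), np.uint8)
        a[:2, :2, 0] = 1
        assert hs.jaccard(a, a) == 1.0
        b = np.zeros_like(a)
        b[2:, 2:, 0] = 1
        assert hs.jaccard(a, b) == 0.0
        c = np.zeros_like(a)
        c[1:3, :2, 0] = 1           # |a|=|b|=4, overlap 2 -> 2/6
        assert hs.jaccard(a, c) == pytest.approx(1 / 3)

    def test_both_empty_is_one(self):
        z = np.zeros((3, 3, 3), np.uint8)
        assert hs.jaccard(z, z) == 1.0

    def test_jaccard_never_exceeds_dice(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            a = (rng.random((6, 6, 2)) < 0.4).astype(np.uint8)
            b = (rng.random((6, 6, 2)) < 0.4).astype(np.uint8)
            assert hs.jaccard(a, b) <= hs.dice(a, b) + 1e-12


class TestSamplePatch:
    def test_tumor_biased_output_region_always_contains_lesion(
            self, small_cases, tiny_geometry):
        case = small_cases[0]
        rng = np.random.default_rng(4)
        m, o = tiny_geometry.margin, tiny_geometry.output_extent
        core = tuple(slice(mm, mm + oo) for mm, oo in zip(m, o))
        for _ in range(100):
            _, label, _ = sample_patch(case, tiny_geometry, True, rng)
            assert label[core].any()

    def test_unbiased_output_region_contains_liver(self, small_cases, tiny_geometry):
        case = small_cases[0]
        rng = np.random.default_rng(5)
        weight = dilate_liver(case.liver)
        m, o = tiny_geometry.margin, tiny_geometry.output_extent
        core = tuple(slice(mm, mm + oo) for mm, oo in zip(m, o))
        for _ in range(20):
            _, _, w = sample_patch(case, tiny_geometry, False, rng, weight)
            assert w[core].any()

    def test_lesion_free_case_falls_back_to_liver(self, small_cases, tiny_geometry,
                                                  caplog):
        case = small_cases[2]  # generated with 0 lesions
        assert case.lesions.num_voxels == 0
        rng = np.random.default_rng(6)
        with caplog.at_level(logging.INFO, logger="hepaseg"):
            _, label, w = sample_patch(case, tiny_geometry, True, rng)
        assert "falls back" in caplog.text
        assert not label.any()

    def test_patch_shapes_match_input_extent(self, small_cases, tiny_geometry):
        img, label, w = sample_patch(small_cases[1], tiny_geometry, True,
                                     np.random.default_rng(7))
        assert img.shape == label.shape == w.shape == tiny_geometry.input_extent


class TestTrainer:
    def test_patch_mix_follows_ninety_ten_cycle(self, small_cases, tiny_net_cfg,
                                                tiny_train_cfg, monkeypatch):
        net = hs.build_network(tiny_net_cfg, seed=0)
        trainer = Trainer(net, small_cases[:2], small_cases[:1], tiny_train_cfg, seed=0)
        drawn = []
        orig = hs.sample_patch

        def spy(case, geometry, tumor_biased, rng, weight=None):
            drawn.append(tumor_biased)
            return orig(case, geometry, tumor_biased, rng, weight)

        monkeypatch.setattr("hepaseg.train.sample_patch", spy)
        for _ in range(1000):
            trainer._next_patch()
        assert np.mean(drawn) == pytest.approx(0.9, abs=0.03)

    def test_validation_bookkeeping_and_best_selection(self, small_cases,
                                                       tiny_net_cfg, tiny_train_cfg):
        net = hs.build_network(tiny_net_cfg, seed=1)
        state, trainer = hs.train_model(net, small_cases[:2], small_cases[:1],
                                        tiny_train_cfg, seed=1)
        assert [it for it, _ in state.history] == [25, 50]
        best = max(state.history, key=lambda e: (e[1], -e[0]))
        assert state.best_iteration == best[0]
        assert state.best_jaccard == best[1]
        assert all(state.best_jaccard >= j for _, j in state.history)

    def test_fixed_seed_without_augmentation_reproduces_loss_curve(
            self, small_cases, tiny_net_cfg, tiny_train_cfg):
        no_aug = hs.AugmentConfig(enabled=False)
        curves = []
        for _ in range(2):
            net = hs.build_network(tiny_net_cfg, seed=2)
            state, _ = hs.train_model(net, small_cases[:2], small_cases[:1],
                                      tiny_train_cfg, augment_cfg=no_aug, seed=2)
            curves.append(state.losses)
        assert curves[0] == curves[1]

    def test_loss_decreases_on_smoke_task(self, small_cases, tiny_net_cfg,
                                          tiny_geometry):
        """First vs. last 10-iteration mean loss drops for >= 4 of 5 seeds."""
        cfg = hs.TrainConfig(batch_size=1, learning_rate=3e-3,
                             total_iterations=60, val_interval=60,
                             input_patch=tiny_geometry.input_extent)
        wins = 0
        for seed in range(5):
            net = hs.build_network(tiny_net_cfg, seed=seed)
            state, _ = hs.train_model(net, small_cases[:2], small_cases[:1],
                                      cfg, seed=seed)
            losses = [l for _, l in state.losses]
            if np.mean(losses[-10:]) < np.mean(losses[:10]):
                wins += 1
        assert wins >= 4

    def test_requires_cases(self, tiny_net_cfg, tiny_train_cfg, small_cases):
        net = hs.build_network(tiny_net_cfg, seed=3)
        with pytest.raises(ValueError):
            Trainer(net, [], small_cases[:1], tiny_train_cfg)
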
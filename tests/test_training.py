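"""Loss closed forms, augmentation geometry, batch mixing, training loop."""

import math

import numpy as np
import pytest

from uniland import (
    AugmentConfig,
    GU2Net,
    LandmarkSample,
    NetworkConfig,
    Spacing,
    TrainConfig,
    augment,
    cyclic_lr,
    encode_heatmaps,
    heatmap_bce_loss,
    sample_batches,
    train,
)
from uniland.training import _apply_rigid, split_validation


def loop_bce(pred, target, eps=1e-6):
    """Scalar double-loop oracle for the soft-label cross entropy."""
    total = 0.0
    p = pred.reshape(pred.shape[0], -1)
    y = target.reshape(target.shape[0], -1)
    for b in range(p.shape[0]):
        for k in range(p.shape[1]):
            f = min(max(p[b, k], eps), 1 - eps)
            total += -y[b, k] * math.log(f) - (1 - y[b, k]) * math.log(1 - f)
    return total / p.shape[0]


class TestLoss:
    def test_perfect_prediction_is_near_zero(self):
        # with the 1e-6 clamp each pixel contributes -log(1 - 1e-6) ~ 1e-6
        y = np.zeros((1, 2, 4, 4))
        y[0, 0, 1, 1] = 1.0
        assert heatmap_bce_loss(y, y) <= 1.01e-6 * y.size

    def test_half_half_closed_form(self):
        p = np.array([[[[0.5]]]])
        assert heatmap_bce_loss(p, p) == pytest.approx(math.log(2), rel=1e-9)

    def test_matches_loop_oracle(self, rng):
        p = rng.uniform(0.01, 0.99, size=(3, 2, 5, 4))
        y = rng.uniform(0, 1, size=(3, 2, 5, 4))
        assert heatmap_bce_loss(p, y) == pytest.approx(loop_bce(p, y), abs=1e-6)

    def test_nonnegative_and_zero_only_at_match(self, rng):
        p = rng.uniform(0.01, 0.99, size=(1, 1, 6, 6))
        y = rng.uniform(0, 1, size=(1, 1, 6, 6))
        assert heatmap_bce_loss(p, y) > 0

    def test_shape_mismatch_and_nan_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            heatmap_bce_loss(np.zeros((1, 2, 2)), np.zeros((1, 2, 3)))
        bad = np.full((1, 2, 2), np.nan)
        with pytest.raises(ValueError, match="NaN"):
            heatmap_bce_loss(bad, np.zeros((1, 2, 2)))

    def test_gradient_matches_finite_difference(self, rng):
        p = rng.uniform(0.05, 0.95, size=(2, 1, 3, 3))
        y = rng.uniform(0, 1, size=(2, 1, 3, 3))
        _, g = heatmap_bce_loss(p, y, with_grad=True)
        eps = 1e-6
        for idx in [(0, 0, 1, 2), (1, 0, 0, 0), (1, 0, 2, 1)]:
            pp = p.copy(); pp[idx] += eps
            pm = p.copy(); pm[idx] -= eps
            fd = (heatmap_bce_loss(pp, y) - heatmap_bce_loss(pm, y)) / (2 * eps)
            assert g[idx] == pytest.approx(fd, rel=1e-4)


def _sample(w=48, h=48, seed=0):
    rng = np.random.default_rng(seed)
    lm = np.array([[12.0, 15.0], [30.0, 22.0], [20.0, 35.0]])
    return LandmarkSample(0, rng.random((h, w)).astype(np.float32), lm, Spacing.pixel())


class TestAugment:
    def test_identity_when_probabilities_miss(self):
        cfg = AugmentConfig(rotate_prob=0.0, translate_prob=0.0)
        s = _sample()
        out = augment(s, None, np.random.default_rng(0), cfg)
        np.testing.assert_array_equal(out.image, s.image)
        np.testing.assert_array_equal(out.landmarks, s.landmarks)

    def test_pure_translation_shifts_landmarks(self):
        s = _sample()
        out = _apply_rigid(s, 0.0, 10, 0)
        np.testing.assert_allclose(out.landmarks[:, 0], s.landmarks[:, 0] + 10)
        np.testing.assert_allclose(out.landmarks[:, 1], s.landmarks[:, 1])

    def test_rotation_matches_rotation_matrix(self):
        # independent 2x2 matrix computation on centred coordinates
        s = _sample()
        theta = math.radians(2.0)
        out = _apply_rigid(s, theta, 0, 0)
        c = np.array([(s.width - 1) / 2, (s.height - 1) / 2])
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        expected = (s.landmarks - c) @ rot.T + c
        np.testing.assert_allclose(out.landmarks, expected, atol=1e-6)

    def test_image_content_follows_translation(self):
        s = _sample()
        out = _apply_rigid(s, 0.0, 5, -3)
        # pixel (x, y) of the output equals pixel (x-5, y+3) of the input
        np.testing.assert_allclose(
            out.image[0, 10:30, 10:30], s.image[0, 13:33, 5:25], atol=1e-5
        )

    def test_target_stack_reencoded_from_new_landmarks(self):
        s = _sample()
        target = encode_heatmaps(s.landmarks, (s.height, s.width), sigma=3.0)
        cfg = AugmentConfig(rotate_prob=0.0, translate_prob=1.0, translate_px=4)
        out, new_target = augment(s, target, np.random.default_rng(3), cfg)
        expected = encode_heatmaps(out.landmarks, (s.height, s.width), sigma=3.0)
        np.testing.assert_allclose(new_target.values, expected.values)

    def test_out_of_frame_draw_degenerates_to_identity(self):
        # landmark sits at the border: any translation pushes it out
        lm = np.array([[0.0, 0.0]])
        s = LandmarkSample(0, np.zeros((16, 16), np.float32), lm, Spacing.pixel())
        cfg = AugmentConfig(rotate_prob=0.0, translate_prob=1.0, translate_px=10)
        rng = np.random.default_rng(0)
        out = augment(s, None, rng, cfg, max_retries=3)
        # either an in-frame draw (x, y >= 0) or the untouched sample
        assert (out.landmarks >= 0).all() and (out.landmarks < 16).all()


class TestBatchSampling:
    def _sets(self, sizes):
        return {
            d: [_sample(seed=d * 1000 + i) for i in range(n)] for d, n in enumerate(sizes)
        }

    def test_single_domain_visits_every_sample_once(self):
        sets = self._sets([12])
        seen = []
        for d, batch in sample_batches(sets, 4, np.random.default_rng(0)):
            assert d == 0
            seen += [id(s) for s in batch]
        assert len(seen) == 12 and len(set(seen)) == 12

    def test_epoch_length(self):
        sets = self._sets([10, 7])
        batches = list(sample_batches(sets, 4, np.random.default_rng(0)))
        assert len(batches) == 17 // 4

    def test_domain_frequency_proportional_to_size(self):
        sets = self._sets([90, 10])
        rng = np.random.default_rng(42)
        draws = []
        for _ in range(100):  # 100 epochs of 25 batches = 2500 draws
            draws += [d for d, _ in sample_batches(sets, 4, rng)]
        frac = np.mean([d == 0 for d in draws])
        n = len(draws)
        sigma = math.sqrt(0.9 * 0.1 / n)
        assert abs(frac - 0.9) < 3 * sigma + 1e-12

    def test_all_domains_appear_in_window(self):
        sets = self._sets([8, 8, 8, 8])
        rng = np.random.default_rng(7)
        domains = []
        while len(domains) < 200:
            domains += [d for d, _ in sample_batches(sets, 4, rng)]
        assert set(domains[:200]) == {0, 1, 2, 3}

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="non-empty|empty"):
            list(sample_batches({}, 4, np.random.default_rng(0)))


class TestScheduler:
    def test_trace_endpoints(self):
        total, cyc = 500, 100
        lrs = [cyclic_lr(t, total, cyc, 1e-4, 1e-2) for t in range(total)]
        assert lrs[0] == pytest.approx(1e-2)
        assert lrs[-1] == pytest.approx(1e-4, rel=0.05)
        assert min(lrs) >= 1e-4 - 1e-12 and max(lrs) <= 1e-2 + 1e-12

    def test_cycles_dip_and_recover(self):
        lrs = [cyclic_lr(t, 400, 100, 1e-4, 1e-2) for t in range(400)]
        assert lrs[50] < lrs[0]  # mid-cycle dip
        assert lrs[100] > lrs[50]  # next cycle restarts high (with decay)


class TestSplitValidation:
    def test_deterministic_and_disjoint(self):
        samples = [_sample(seed=i) for i in range(20)]
        tr1, va1 = split_validation(samples, 0.1, 3)
        tr2, va2 = split_validation(samples, 0.1, 3)
        assert [id(s) for s in tr1] == [id(s) for s in tr2]
        assert len(va1) == 2 and len(tr1) == 18
        assert not set(map(id, tr1)) & set(map(id, va1))


def _micro_bench(small_bench, domains=(0,)):
    train_sets = {d: small_bench.train[d] for d in domains}
    val_sets = {d: small_bench.val[d] for d in domains}
    return train_sets, val_sets


def _micro_model(small_bench, domains=(0,), seed=2):
    doms = tuple(
        (s.domain_id, 1, s.num_landmarks)
        for s in small_bench.registry
        if s.domain_id in domains
    )
    cfg = NetworkConfig(domains=doms, encoder_widths=(4, 6, 8, 12), global_width=4, seed=seed)
    return GU2Net(cfg)


class TestTrainLoop:
    def test_smoke_one_epoch_writes_history_and_checkpoint(self, small_bench, tmp_path):
        model = _micro_model(small_bench)
        tr, va = _micro_bench(small_bench)
        model, hist = train(model, tr, va, TrainConfig(epochs=1, seed=1), run_dir=tmp_path)
        assert len(hist.train_loss) == 1
        assert len(hist.val_loss_pooled) == 1
        assert hist.best_epoch == 0
        assert (tmp_path / "checkpoint.npz").exists()
        assert (tmp_path / "history.json").exists()

    def test_lr_trace_spans_configured_range(self, small_bench):
        model = _micro_model(small_bench)
        tr, va = _micro_bench(small_bench)
        cfg = TrainConfig(epochs=4, cycle_epochs=4, seed=1)
        _, hist = train(model, tr, va, cfg)
        assert hist.lr_trace[0] == pytest.approx(cfg.lr_max)
        assert hist.lr_trace[-1] < 10 * cfg.lr_min

    def test_full_run_determinism(self, small_bench):
        tr, va = _micro_bench(small_bench)
        cfg = TrainConfig(epochs=2, seed=9)
        _, h1 = train(_micro_model(small_bench), tr, va, cfg)
        _, h2 = train(_micro_model(small_bench), tr, va, cfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss_pooled == h2.val_loss_pooled

    def test_best_epoch_is_argmin_of_pooled_val(self, small_bench):
        model = _micro_model(small_bench)
        tr, va = _micro_bench(small_bench)
        _, hist = train(model, tr, va, TrainConfig(epochs=3, seed=4))
        assert hist.best_epoch == int(np.argmin(hist.val_loss_pooled))

    def test_step_on_one_domain_preserves_other_domains_params(self, small_bench):
        from uniland import partition_params

        model = _micro_model(small_bench, domains=(0, 1))
        part = partition_params(model)
        before = [p.data.copy() for p in part.per_domain[1]]
        tr = {0: small_bench.train[0][:4]}
        va = {0: small_bench.val[0][:2]}
        train(model, tr, va, TrainConfig(epochs=1, seed=1))
        for p, b in zip(part.per_domain[1], before):
            np.testing.assert_array_equal(p.data, b)
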
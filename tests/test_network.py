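"""Architecture contracts: shapes, parameter accounting, routing, swapping."""

import numpy as np
import pytest

from uniland import (
    GU2Net,
    NetworkConfig,
    build_local_network,
    build_unet_baseline,
    count_separable_params,
    count_standard_params,
    load_checkpoint,
    partition_params,
    save_checkpoint,
    swap_domain_params,
)
from uniland._nn import SHARED, Adam, Conv3x3
from uniland.network import SeparableBlock


def _input(b=2, hw=32, seed=0):
    return np.random.default_rng(seed).standard_normal((b, 1, hw, hw)).astype(np.float32)


class TestForwardContracts:
    def test_output_shapes_and_range(self, tiny_model):
        for d, c_lm in [(0, 3), (1, 5)]:
            local, glob, final = tiny_model.forward_batch(_input(), d)
            for arr in (local, glob, final):
                assert arr.shape == (2, c_lm, 32, 32)
            assert final.min() >= 0.0 and final.max() <= 1.0

    def test_single_domain_degenerate(self):
        cfg = NetworkConfig(domains=((0, 1, 2),), encoder_widths=(4, 6, 8, 12), global_width=4)
        m = GU2Net(cfg)
        _, _, final = m.forward_batch(_input(), 0)
        assert final.shape == (2, 2, 32, 32)

    def test_unknown_domain_rejected(self, tiny_model):
        with pytest.raises(KeyError, match="unknown domain"):
            tiny_model.forward_batch(_input(), 7)

    def test_indivisible_size_rejected(self, tiny_model):
        x = np.zeros((1, 1, 24, 24), dtype=np.float32)
        with pytest.raises(ValueError, match="divisible"):
            tiny_model.forward_batch(x, 0)

    def test_local_only_final_equals_local(self, tiny_cfg):
        m = build_local_network(tiny_cfg)
        local, glob, final = m.forward_batch(_input(), 0)
        assert np.all(glob == 1.0)
        np.testing.assert_array_equal(final, local)

    def test_global_only_has_no_shared_params(self, tiny_cfg):
        from uniland import build_global_network

        m = build_global_network(tiny_cfg)
        part = partition_params(m)
        assert part.n_shared == 0
        local, glob, final = m.forward_batch(_input(), 1)
        assert np.all(local == 1.0)
        np.testing.assert_array_equal(final, glob)

    def test_determinism_same_seed_same_params_same_output(self, tiny_cfg):
        m1, m2 = GU2Net(tiny_cfg), GU2Net(tiny_cfg)
        for p1, p2 in zip(m1.params(), m2.params()):
            np.testing.assert_array_equal(p1.data, p2.data)
        x = _input(seed=3)
        out1 = m1.forward_batch(x, 0)[2]
        out2 = m2.forward_batch(x, 0)[2]
        np.testing.assert_array_equal(out1, out2)

    def test_single_image_forward_returns_stacks(self, tiny_model):
        local, glob, final = tiny_model.forward(_input(b=1)[0], 1)
        assert final.role == "final" and local.role == "local" and glob.role == "global"
        assert final.values.shape == (5, 32, 32)


class TestGlobalBranch:
    def test_five_dilated_convs_per_domain(self, tiny_model):
        for d, branch in tiny_model.globals_.items():
            assert len(branch.convs) == 5
            assert tuple(c.d for c in branch.convs) == (1, 2, 5, 2, 1)

    def test_quarter_resolution_internal(self, tiny_model):
        branch = tiny_model.globals_[0]
        x = _input(b=1)
        local = np.full((1, 3, 32, 32), 0.5, dtype=np.float32)
        out = branch.forward(x, local)
        assert out.shape == (1, 3, 32, 32)
        # the pre-upsample map lives at 1/4 resolution
        assert branch.out_act._y.shape[-2:] == (8, 8)

    def test_receptive_field_of_dilated_stack(self):
        # linearized probe: 5 dilated 3x3 convs (1, 2, 5, 2, 1), all-ones
        # weights, no normalization -> a unit impulse spreads to a
        # (1 + 2*sum(d)) = 23-wide square footprint
        rng = np.random.default_rng(0)
        convs = [Conv3x3(rng, 1, 1, f"c{i}", dilation=d, bias=False) for i, d in enumerate((1, 2, 5, 2, 1))]
        for c in convs:
            c.w.data[...] = 1.0
        x = np.zeros((1, 1, 64, 64), dtype=np.float32)
        x[0, 0, 32, 32] = 1.0
        for c in convs:
            x = c.forward(x)
        ys, xs = np.nonzero(x[0, 0])
        assert ys.max() - ys.min() + 1 == 23
        assert xs.max() - xs.min() + 1 == 23

    def test_add_fusion_mode(self):
        cfg = NetworkConfig(
            domains=((0, 1, 3),), encoder_widths=(4, 6, 8, 12), global_width=4,
            fusion_input_mode="add",
        )
        m = GU2Net(cfg)
        assert m.globals_[0].proj is not None
        _, _, final = m.forward_batch(_input(b=1), 0)
        assert final.shape == (1, 3, 32, 32)


class TestParamFormula:
    def test_printed_examples(self):
        # 9*t*N + N*M at t=4, N=M=64: 2304 + 4096
        assert count_separable_params(4, 64, 64) == 6400
        # 9*t*N*M for the t parallel standard 3x3 convolutions
        assert count_standard_params(4, 64, 64) == 9 * 4 * 64 * 64 == 147456
        ratio = count_separable_params(4, 64, 64) / count_standard_params(4, 64, 64)
        assert ratio == pytest.approx(6400 / 147456)

    def test_invalid_args_rejected(self):
        with pytest.raises(ValueError):
            count_separable_params(0, 4, 4)
        with pytest.raises(ValueError):
            count_standard_params(2, -1, 4)

    def test_formula_matches_enumeration_on_every_block(self, tiny_model):
        t = len(tiny_model.domain_ids)
        blocks = [b for b in tiny_model.local.blocks() if isinstance(b, SeparableBlock)]
        assert blocks
        for blk in blocks:
            enumerated = sum(dw.w.size for dw in blk.dw.values()) + blk.pw.w.size
            assert enumerated == count_separable_params(t, blk.c_in, blk.c_out)


class TestPartition:
    def test_disjoint_and_exhaustive(self, tiny_model):
        part = partition_params(tiny_model)
        ids = [id(p) for p in part.shared]
        for ps in part.per_domain.values():
            ids += [id(p) for p in ps]
        assert len(ids) == len(set(ids))
        assert part.n_shared + sum(part.n_per_domain.values()) == tiny_model.num_params()
        assert part.n_shared > 0
        assert all(n > 0 for n in part.n_per_domain.values())

    def test_single_domain_partition(self):
        cfg = NetworkConfig(domains=((0, 1, 2),), encoder_widths=(4, 6, 8, 12), global_width=4)
        part = partition_params(GU2Net(cfg))
        assert list(part.per_domain) == [0]
        assert part.n_shared > 0 and part.n_per_domain[0] > 0

    def test_baseline_has_only_shared_params(self, tiny_cfg):
        part = partition_params(build_unet_baseline(tiny_cfg))
        assert part.n_shared > 0
        assert all(len(ps) == 0 for ps in part.per_domain.values())

    def test_baseline_head_covers_union_of_channels(self, tiny_cfg):
        m = build_unet_baseline(tiny_cfg)
        _, _, final = m.forward_batch(_input(b=1), 0)
        assert final.shape[1] == 3  # only the active domain's channels
        assert m.local.union_head.c_out == 8  # 3 + 5


def _loss_grad(final):
    return (final - 0.5).astype(np.float32)


def _step(model, x, d, lr=1e-3):
    opt = Adam(model.params())
    _, _, final = model.forward_batch(x, d, train=True)
    opt.zero_grad()
    model.backward_batch(_loss_grad(final))
    opt.step(lr)


class TestRouting:
    def test_gradients_of_other_domains_are_exactly_zero(self, tiny_model):
        _, _, final = tiny_model.forward_batch(_input(), 0, train=True)
        tiny_model.zero_grad()
        tiny_model.backward_batch(_loss_grad(final))
        part = partition_params(tiny_model)
        assert all(not p.grad.any() for p in part.per_domain[1])
        assert any(p.grad.any() for p in part.per_domain[0])
        assert any(p.grad.any() for p in part.shared)

    def test_step_leaves_other_domain_bit_identical_and_moves_shared(self, tiny_cfg):
        model = GU2Net(tiny_cfg)
        part = partition_params(model)
        before_other = [p.data.copy() for p in part.per_domain[1]]
        before_shared = [p.data.copy() for p in part.shared]
        _step(model, _input(), 0)
        for p, b in zip(part.per_domain[1], before_other):
            np.testing.assert_array_equal(p.data, b)
        assert any(not np.array_equal(p.data, b) for p, b in zip(part.shared, before_shared))


class TestSwap:
    def test_swap_with_self_is_identity(self, tiny_model):
        before = [p.data.copy() for p in tiny_model.params()]
        _, skipped = swap_domain_params(tiny_model, 0, 0)
        assert skipped == []
        for p, b in zip(tiny_model.params(), before):
            np.testing.assert_array_equal(p.data, b)

    def test_double_swap_restores_bit_exactly(self, tiny_cfg):
        model = GU2Net(tiny_cfg)
        _step(model, _input(), 0)  # give batch-norm stats some structure
        _step(model, _input(seed=5), 1)
        before = {(p.tag, p.key): p.data.copy() for p in model.params()}
        buf_before = {
            (bn.tag, bn._key): (bn.run_mean.copy(), bn.run_var.copy())
            for bn in model.batchnorms()
        }
        swap_domain_params(model, 0, 1)
        swap_domain_params(model, 0, 1)
        for p in model.params():
            np.testing.assert_array_equal(p.data, before[(p.tag, p.key)])
        for bn in model.batchnorms():
            m, v = buf_before[(bn.tag, bn._key)]
            np.testing.assert_array_equal(bn.run_mean, m)
            np.testing.assert_array_equal(bn.run_var, v)

    def test_unequal_heads_are_skipped_and_reported(self, tiny_model):
        before_shared = {
            p.key: p.data.copy() for p in partition_params(tiny_model).shared
        }
        _, skipped = swap_domain_params(tiny_model, 0, 1)  # 3 vs 5 landmarks
        assert any(k.startswith("local.head") for k in skipped)
        assert any(k.startswith("global.conv0") for k in skipped)
        assert any(k.startswith("global.conv4") for k in skipped)
        for p in partition_params(tiny_model).shared:
            np.testing.assert_array_equal(p.data, before_shared[p.key])
        swap_domain_params(tiny_model, 0, 1)  # restore

    def test_strict_mode_raises_on_mismatch(self, tiny_model):
        with pytest.raises(ValueError, match="shape mismatch"):
            swap_domain_params(tiny_model, 0, 1, strict=True)


class TestBaselineSize:
    def test_baseline_larger_than_separable_model(self, tiny_cfg):
        gu = GU2Net(tiny_cfg)
        base = build_unet_baseline(tiny_cfg)
        assert base.num_params() > gu.num_params()


class TestCheckpoint:
    def test_round_trip_restores_forward_exactly(self, tiny_cfg, tmp_path):
        model = GU2Net(tiny_cfg)
        _step(model, _input(), 0)
        x = _input(seed=9)
        ref = model.forward_batch(x, 0)[2]
        save_checkpoint(model, tmp_path / "ck.npz", epoch=3, val_loss=1.5)
        loaded, manifest = load_checkpoint(tmp_path / "ck.npz")
        assert manifest["epoch"] == 3
        assert manifest["config"]["encoder_widths"] == list(tiny_cfg.encoder_widths)
        out = loaded.forward_batch(x, 0)[2]
        np.testing.assert_array_equal(out, ref)


class TestConfigValidation:
    def test_widths_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            NetworkConfig(domains=((0, 1, 2),), encoder_widths=(8, 8, 16, 32))

    def test_dilations_positive(self):
        with pytest.raises(ValueError, match="dilations"):
            NetworkConfig(domains=((0, 1, 2),), global_dilations=(1, 0, 5, 2, 1))

    def test_variant_checked(self):
        with pytest.raises(ValueError, match="variant"):
            NetworkConfig(domains=((0, 1, 2),), variant="resnet")
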
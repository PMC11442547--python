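"""Architecture contracts: unfolding bijectivity, shape ladder, residual
behaviour, slice equivariance, profiling and gradient flow."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from collimap import nn
from collimap.model import (
    ModelConfig,
    MoReT3D,
    MV2Block,
    ViTBlock,
    build_model,
    count_flops,
    count_parameters,
    fold_slices,
    fold_volumes,
    profile_model,
    unfold_slices,
    unfold_volumes,
)

TINY = ModelConfig(in_channels=6, out_phases=5, depth=4,
                   stage_widths=(4, 4, 8, 8, 8), vit_dim=8,
                   bottleneck_channels=16, decoder_widths=(16, 8, 8, 4, 4),
                   L_M=(1, 1), L_V=1, last_stage_valid=False)


class TestUnfolding:
    def test_volume_token_counts(self):
        x = np.arange(8 * 4 * 4 * 4, dtype=float).reshape(8, 4, 4, 4)
        xu = unfold_volumes(x, 2)
        assert xu.shape == (8, 8, 8)  # N = 4*4*4/8, P = p^3

    def test_p1_is_identity_reshape(self):
        x = np.arange(2 * 3 * 4 * 5, dtype=float).reshape(2, 3, 4, 5)
        xu = unfold_volumes(x, 1)
        assert xu.shape == (2, 60, 1)
        np.testing.assert_array_equal(xu[..., 0], x.reshape(2, -1))

    def test_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            unfold_volumes(np.zeros((2, 3, 4, 4)), 2)

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_volume_fold_unfold_identity(self, seed):
        rng = np.random.default_rng(seed)
        C = int(rng.integers(1, 5))
        p = int(rng.integers(1, 4))
        dims = tuple(int(rng.integers(1, 4)) * p for _ in range(3))
        x = rng.standard_normal((C,) + dims)
        np.testing.assert_array_equal(fold_volumes(unfold_volumes(x, p), p, dims), x)

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_slice_fold_unfold_identity(self, seed):
        rng = np.random.default_rng(seed)
        C, D, H, W = (int(rng.integers(1, 6)) for _ in range(4))
        x = rng.standard_normal((C, D, H, W))
        xu = unfold_slices(x)
        assert xu.shape == (C, D, H * W)
        np.testing.assert_array_equal(fold_slices(xu, (H, W)), x)

    def test_batched_unfold_matches_unbatched(self, rng):
        x = rng.standard_normal((2, 3, 4, 4, 4))
        xu = unfold_volumes(x, 2)
        np.testing.assert_array_equal(xu[1], unfold_volumes(x[1], 2))


class TestMV2Block:
    def test_stride2_halves_spatial_keeps_depth(self, rng):
        blk = MV2Block(4, 6, stride=2, rng=np.random.default_rng(0))
        y = blk(rng.standard_normal((1, 4, 5, 8, 8)).astype(np.float32))
        assert y.shape == (1, 6, 5, 4, 4)

    def test_residual_identity_with_zeroed_projection(self, rng):
        blk = MV2Block(4, 4, stride=1, rng=np.random.default_rng(0))
        blk.pw2.conv.weight.data[...] = 0.0  # zero branch => pure residual
        blk.eval()
        x = rng.standard_normal((1, 4, 3, 6, 6)).astype(np.float32)
        y = blk(x)
        np.testing.assert_allclose(y, x + blk.pw2.bn.beta.data[None, :, None, None, None],
                                   atol=1e-6)


class TestViTBlock:
    def test_slice_permutation_equivariance_with_zero_pos(self, rng):
        """With the position embedding zeroed, permuting slices permutes
        the output identically (attention is order-agnostic)."""
        blk = ViTBlock(8, 1, depth=6, rng=np.random.default_rng(0))
        blk.pos.data[...] = 0.0
        blk.eval()
        x = rng.standard_normal((1, 8, 6, 3, 3)).astype(np.float64)
        perm = np.random.default_rng(1).permutation(6)
        with nn.no_grad():
            y = blk(x)
            y_perm = blk(x[:, :, perm])
        np.testing.assert_allclose(y[:, :, perm], y_perm, atol=1e-10)

    def test_position_embedding_breaks_equivariance(self, rng):
        blk = ViTBlock(8, 1, depth=6, rng=np.random.default_rng(0))
        blk.eval()
        x = rng.standard_normal((1, 8, 6, 3, 3)).astype(np.float64)
        perm = np.roll(np.arange(6), 1)
        with nn.no_grad():
            y = blk(x)
            y_perm = blk(x[:, :, perm])
        assert not np.allclose(y[:, :, perm], y_perm, atol=1e-6)


class TestModelContracts:
    def test_reduced_config_shape_and_range(self):
        model = build_model(ModelConfig.reduced(), seed=0)
        x = np.random.default_rng(0).uniform(
            0, 1, size=(40, 20, 64, 64)).astype(np.float32)
        y = model.predict_array(x)
        assert y.shape == (5, 20, 64, 64)
        assert np.all(y > -1.0) and np.all(y < 1.0)
        assert model._bottleneck_shape == (64, 20, 2, 2)

    def test_reference_profile_resolution_ladder(self):
        cfg = ModelConfig.reference()
        assert cfg.encoder_ladder(224) == [112, 56, 28, 14, 6]
        prof = profile_model(cfg, (40, 20, 224, 224))
        assert prof["bottleneck_shape"] == (512, 20, 6, 6)
        assert prof["output_shape"] == (5, 20, 224, 224)

    def test_eval_forward_deterministic(self):
        model = build_model(TINY, seed=1)
        x = np.random.default_rng(2).standard_normal((6, 4, 32, 32)).astype(np.float32)
        y1 = model.predict_array(x)
        y2 = model.predict_array(x)
        np.testing.assert_array_equal(y1, y2)

    def test_gradient_reaches_every_parameter(self):
        model = build_model(TINY, seed=3)
        rng = np.random.default_rng(4)
        x = rng.standard_normal((2, 6, 4, 32, 32)).astype(np.float32)
        model.zero_grad()
        y = model.forward(x)
        model.backward(np.sign(rng.standard_normal(y.shape)).astype(np.float32))
        dead = [i for i, p in enumerate(model.parameters())
                if not np.any(p.grad != 0)]
        assert dead == [], f"parameters with zero gradient: {dead}"

    def test_head_has_five_channels_and_tanh_bounds(self):
        model = build_model(TINY, seed=0)
        assert model.head.cout == 5
        x = np.random.default_rng(0).standard_normal((6, 4, 32, 32)).astype(np.float32)
        # extreme inputs may saturate Tanh to +/-1.0 in float32 but never beyond
        assert np.all(np.abs(model.predict_array(100.0 * x)) <= 1.0)
        # moderate inputs stay strictly inside (-1, 1)
        assert np.all(np.abs(model.predict_array(x)) < 1.0)


class TestProfiling:
    def test_reference_parameter_count_is_stable(self):
        model = build_model(ModelConfig.reference(), seed=0)
        n = count_parameters(model)
        assert n == profile_model(ModelConfig.reference(), (40, 20, 224, 224))["parameters"]
        # forward passes must not change the count
        x = np.random.default_rng(0).standard_normal((40, 20, 64, 64))
        reduced = build_model(ModelConfig.reduced(), seed=0)
        n_before = count_parameters(reduced)
        reduced.predict_array(x.astype(np.float32))
        assert count_parameters(reduced) == n_before

    def test_adding_a_conv_adds_exactly_its_scalars(self):
        rng = np.random.default_rng(0)
        conv = nn.Conv3d(1, 1, 1, bias=True, rng=rng)
        assert sum(p.size for p in conv.parameters()) == 2

    def test_conv_flop_closed_form(self):
        # a single k^3 conv counts 2*k^3*Cin*Cout*out_voxels FLOPs
        from collimap.model import ConvBNAct
        blk = ConvBNAct(3, 5, 3, padding=(1, 1, 1), rng=np.random.default_rng(0))
        out_shape, flops = blk.profile((3, 4, 6, 6))
        assert out_shape == (5, 4, 6, 6)
        assert flops == 2 * 27 * 3 * 5 * 4 * 6 * 6

    def test_doubling_spatial_size_quadruples_stem_flops(self):
        cfg = ModelConfig.reduced()
        m = build_model(cfg, seed=0)
        _, f1 = m.stem.profile((40, 20, 64, 64))
        _, f2 = m.stem.profile((40, 20, 128, 128))
        assert f2 == 4 * f1

    def test_reduced_reports_fewer_flops_and_params(self):
        ref = profile_model(ModelConfig.reference(), (40, 20, 224, 224))
        red = profile_model(ModelConfig.reduced(), (40, 20, 64, 64))
        assert red["parameters"] < ref["parameters"]
        assert red["flops"] < ref["flops"]
        assert "2 FLOPs per multiply-accumulate" in red["flop_convention"]

    def test_heads_must_divide_widths(self):
        with pytest.raises(ValueError, match="heads"):
            ModelConfig(stage_widths=(8, 16, 18, 24, 32))


class TestOverfitSanity:
    def test_reduced_model_overfits_single_phantom_sample(self):
        """A reduced-width model drives the BerHu training loss below 0.01
        on one repeated phantom sample within 200 steps."""
        from collimap.io import SubjectRecord
        from collimap.metrics import berhu_loss_grad
        from collimap.nn import Adam
        from collimap.phantom import PhantomSpec, make_phantom
        from collimap.train import prepare_samples

        ph = make_phantom(PhantomSpec(grid=(40, 8, 32, 32), noise_sigma=0.0,
                                      seed=7))
        rec = SubjectRecord(series=ph.series, mask=ph.brain, targets=ph.maps)
        s = prepare_samples([rec])[0]
        x, y = s.x[None], s.y[None]
        cfg = ModelConfig(in_channels=40, out_phases=5, depth=8,
                          stage_widths=(8, 12, 16, 16, 24), vit_dim=24,
                          bottleneck_channels=32,
                          decoder_widths=(40, 32, 24, 16, 12),
                          L_M=(1, 1), L_V=1, last_stage_valid=False,
                          bn_momentum=0.3, head_bias=-1.0, residual_gamma=0.1)
        model = build_model(cfg, seed=0)
        opt = Adam(model.parameters(), lr=1e-2)
        loss = np.inf
        for step in range(200):
            out = model.forward(x)
            loss, grad = berhu_loss_grad(out, y)
            if loss < 0.01:
                break
            model.zero_grad()
            model.backward(grad)
            opt.step()
        assert loss < 0.01, f"final loss {loss} after {step + 1} steps"
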
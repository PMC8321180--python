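import numpy as np
import pytest

from recistnet.network import (
    ArchitectureSpec,
    DenseBlock,
    NonLocalBlock,
    ResponseNet,
    SeparableConv3d,
    TransitionDown,
)
from recistnet.nn import (
    BatchNorm3d,
    Conv3d,
    DepthwiseConv3d,
    Linear,
    MaxPool3d,
    PointwiseConv3d,
    ReLU,
)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def brute_force_depthwise(x, w):
    """Literal per-channel 3x3x3 convolution, zero padding, python loops."""
    n, c, d, h, hw = x.shape
    out = np.zeros_like(x)
    for ni in range(n):
        for ci in range(c):
            for z in range(d):
                for y in range(h):
                    for xx in range(hw):
                        acc = 0.0
                        for dz in range(3):
                            for dy in range(3):
                                for dx in range(3):
                                    zz, yy, xxx = z + dz - 1, y + dy - 1, xx + dx - 1
                                    if 0 <= zz < d and 0 <= yy < h and 0 <= xxx < hw:
                                        acc += w[ci, dz, dy, dx] * x[ni, ci, zz, yy, xxx]
                        out[ni, ci, z, y, xx] = acc
    return out


def brute_force_nonlocal(x, wt, wp, wb):
    """Literal evaluation of the embedded-Gaussian non-local response:
    y_i = (1/psi) sum_j exp(theta_i . phi_j) beta_j, double loop over
    positions."""
    n, c, d, h, w = x.shape
    p = d * h * w
    xf = x.reshape(n, c, p)
    out = np.zeros_like(xf)
    for ni in range(n):
        theta = wt @ xf[ni]   # (inner, P)
        phi = wp @ xf[ni]
        beta = wb @ xf[ni]    # (C, P)
        for i in range(p):
            logits = np.array([theta[:, i] @ phi[:, j] for j in range(p)])
            logits -= logits.max()
            zeta = np.exp(logits)
            psi = zeta.sum()
            acc = np.zeros(c)
            for j in range(p):
                acc += zeta[j] * beta[:, j]
            out[ni, :, i] = acc / psi
    return out.reshape(x.shape)


# ---------------------------------------------------------------------------
# Separable convolution
# ---------------------------------------------------------------------------

class TestSeparableConv:
    def test_identity_kernels_pass_through(self, rng):
        conv = SeparableConv3d(3, 3, rng)
        conv.depthwise.w.value[...] = 0.0
        conv.depthwise.w.value[:, 1, 1, 1] = 1.0  # delta kernels
        conv.pointwise.w.value[...] = np.eye(3)
        conv.pointwise.b.value[...] = 0.0
        x = rng.normal(size=(2, 3, 4, 5, 5))
        np.testing.assert_allclose(conv.forward(x), x, atol=1e-12)

    def test_matches_brute_force_depthwise_then_pointwise(self, rng):
        # [DERIVED] direct (looped) computation of the factorised convolution
        conv = SeparableConv3d(2, 3, rng)
        x = rng.normal(size=(1, 2, 4, 4, 4))
        expected = brute_force_depthwise(x, conv.depthwise.w.value)
        expected = np.einsum("oc,ncdhw->nodhw", conv.pointwise.w.value, expected) \
            + conv.pointwise.b.value[None, :, None, None, None]
        np.testing.assert_allclose(conv.forward(x), expected, atol=1e-5)

    def test_parameter_count_vs_dense_conv(self, rng):
        # [DERIVED] 27*64 depthwise + 64*64 pointwise (+64 bias) vs 27*64*64
        conv = SeparableConv3d(64, 64, rng)
        n_weights = conv.depthwise.w.size + conv.pointwise.w.size
        assert n_weights == 27 * 64 + 64 * 64 == 5824
        dense = Conv3d(64, 64, rng)
        assert dense.w.size == 27 * 64 * 64 == 110592

    def test_channel_mismatch_raises(self, rng):
        conv = SeparableConv3d(2, 3, rng)
        with pytest.raises(ValueError, match="expected input"):
            conv.forward(rng.normal(size=(1, 4, 4, 4, 4)))

    def test_spatial_shape_preserved(self, rng):
        conv = SeparableConv3d(2, 5, rng)
        out = conv.forward(rng.normal(size=(1, 2, 3, 7, 6)))
        assert out.shape == (1, 5, 3, 7, 6)


class TestStemConv:
    def test_matches_scipy_correlate(self, rng):
        from scipy.ndimage import correlate

        conv = Conv3d(1, 2, rng)
        x = rng.normal(size=(1, 1, 5, 5, 5))
        out = conv.forward(x)
        for o in range(2):
            expected = correlate(x[0, 0], conv.w.value[o, 0], mode="constant") + conv.b.value[o]
            np.testing.assert_allclose(out[0, o], expected, atol=1e-10)


# ---------------------------------------------------------------------------
# Dense blocks and transitions
# ---------------------------------------------------------------------------

class TestDenseBlock:
    def test_32_in_6_layers_growth_16_gives_128(self, rng):
        block = DenseBlock(32, 6, 16, rng)
        out = block.forward(rng.normal(size=(1, 32, 2, 4, 4)))
        assert out.shape[1] == 128

    def test_zero_layers_identity(self, rng):
        block = DenseBlock(8, 0, 16, rng)
        x = rng.normal(size=(1, 8, 2, 4, 4))
        np.testing.assert_array_equal(block.forward(x), x)

    def test_channel_ledger_matches_published_plan(self):
        # [DERIVED] recompute from the spec invariant: 32 + cumsum([6,8,8,8,8,6]*16)
        spec = ArchitectureSpec()
        assert spec.channel_ledger() == [128, 256, 384, 512, 640, 736]

    def test_each_layer_consumes_all_previous(self, rng):
        # perturbing the block input changes every later feature (dense connectivity)
        block = DenseBlock(2, 3, 2, rng)
        x = rng.normal(size=(1, 2, 2, 3, 3))
        base = block.forward(x)
        x2 = x.copy()
        x2[0, 0, 0, 0, 0] += 1.0
        out = block.forward(x2)
        for layer_idx in range(3):
            sl = slice(2 + layer_idx * 2, 4 + layer_idx * 2)
            assert not np.allclose(base[:, sl], out[:, sl])


class TestTransitionDown:
    def test_halves_each_spatial_dim(self, rng):
        t = TransitionDown(128, rng)
        out = t.forward(rng.normal(size=(1, 128, 16, 64, 64)))
        assert out.shape == (1, 128, 8, 32, 32)

    def test_depth_one_map_clamps_kernel(self, rng):
        t = TransitionDown(640, rng)
        out = t.forward(rng.normal(size=(1, 640, 1, 4, 4)))
        assert out.shape == (1, 640, 1, 2, 2)

    def test_constant_input_pooled_constant(self, rng):
        t = TransitionDown(3, rng)
        x = np.ones((1, 3, 4, 4, 4))
        out = t.forward(x)
        for c in range(3):
            assert np.ptp(out[0, c]) == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Non-local blocks
# ---------------------------------------------------------------------------

class TestNonLocal:
    def test_single_position_returns_beta(self, rng):
        # softmax over one element is 1, so y = beta(x)
        block = NonLocalBlock(4, 2, rng, residual=False)
        x = rng.normal(size=(1, 4, 1, 1, 1))
        expected = np.tensordot(block.beta.w.value, x, axes=([1], [1])).transpose(1, 0, 2, 3, 4)
        np.testing.assert_allclose(block.forward(x), expected, atol=1e-10)

    def test_zero_affinity_uniform_attention(self, rng):
        block = NonLocalBlock(3, 2, rng, residual=False)
        block.theta.w.value[...] = 0.0
        block.phi.w.value[...] = 0.0
        x = rng.normal(size=(1, 3, 2, 2, 2))
        beta = np.tensordot(block.beta.w.value, x, axes=([1], [1])).transpose(1, 0, 2, 3, 4)
        mean_beta = beta.reshape(1, 3, -1).mean(axis=2)
        out = block.forward(x).reshape(1, 3, -1)
        for pos in range(out.shape[2]):
            np.testing.assert_allclose(out[:, :, pos], mean_beta, atol=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_double_loop(self, seed):
        # [DERIVED] literal pairwise-affinity evaluation on random 2x3x3x3 maps
        r = np.random.default_rng(seed)
        block = NonLocalBlock(2, 2, r, residual=False)
        x = r.normal(size=(1, 2, 3, 3, 3))
        expected = brute_force_nonlocal(
            x, block.theta.w.value, block.phi.w.value, block.beta.w.value)
        np.testing.assert_allclose(block.forward(x), expected, atol=1e-5)

    def test_residual_adds_input(self, rng):
        r1 = np.random.default_rng(0)
        r2 = np.random.default_rng(0)
        with_res = NonLocalBlock(3, 2, r1, residual=True)
        without = NonLocalBlock(3, 2, r2, residual=False)
        x = rng.normal(size=(1, 3, 2, 2, 2))
        np.testing.assert_allclose(with_res.forward(x), x + without.forward(x), atol=1e-12)

    def test_output_shape_equals_input_shape(self, rng):
        block = NonLocalBlock(5, 2, rng)
        x = rng.normal(size=(2, 5, 2, 3, 4))
        assert block.forward(x).shape == x.shape

    def test_permutation_equivariance(self, rng):
        # attention has no positional encoding: permuting positions permutes output
        block = NonLocalBlock(3, 2, rng, residual=False)
        x = rng.normal(size=(1, 3, 2, 2, 2))
        p = 8
        perm = rng.permutation(p)
        xf = x.reshape(1, 3, p)
        out = block.forward(x).reshape(1, 3, p)
        out_perm = block.forward(xf[:, :, perm].reshape(x.shape)).reshape(1, 3, p)
        np.testing.assert_allclose(out_perm, out[:, :, perm], atol=1e-10)

    def test_large_affinities_stay_finite(self, rng):
        block = NonLocalBlock(2, 2, rng, residual=False)
        x = rng.normal(size=(1, 2, 2, 2, 2)) * 1e3  # affinities ~1e6 pre-stabilisation
        assert np.all(np.isfinite(block.forward(x)))


# ---------------------------------------------------------------------------
# Full model
# ---------------------------------------------------------------------------

class TestResponseNetSmall:
    def test_probabilities_sum_to_one(self, tiny_spec, rng):
        model = ResponseNet(tiny_spec, seed=0)
        probs, _ = model.forward(rng.normal(size=(3, 4, 6, 6)), rng.normal(size=(3, 3)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_zero_weights_give_half_half(self, tiny_spec, rng):
        model = ResponseNet(tiny_spec, seed=0)
        last = model.fc_layers[-1]
        last.w.value[...] = 0.0
        last.b.value[...] = 0.0
        probs, _ = model.forward(rng.normal(size=(1, 4, 6, 6)), rng.normal(size=(1, 3)))
        np.testing.assert_allclose(probs, 0.5, atol=1e-12)

    def test_all_zero_voi_finite(self, tiny_spec):
        model = ResponseNet(tiny_spec, seed=0)
        probs, info = model.forward(np.zeros((1, 4, 6, 6)), np.zeros((1, 3)))
        assert np.all(np.isfinite(probs))
        assert np.all(np.isfinite(info["embedding"]))

    def test_wrong_input_shape_raises(self, tiny_spec):
        model = ResponseNet(tiny_spec, seed=0)
        with pytest.raises(ValueError, match="shape"):
            model.forward(np.zeros((1, 5, 6, 6)), np.zeros((1, 3)))

    def test_clinical_dimension_mismatch_raises(self, tiny_spec):
        model = ResponseNet(tiny_spec, seed=0)
        with pytest.raises(ValueError, match="clinical"):
            model.forward(np.zeros((1, 4, 6, 6)), np.zeros((1, 5)))

    def test_missing_clinical_raises(self, tiny_spec):
        model = ResponseNet(tiny_spec, seed=0)
        with pytest.raises(ValueError, match="clinical"):
            model.forward(np.zeros((1, 4, 6, 6)))

    def test_visual_only_variant_skips_concatenation(self, tiny_spec, rng):
        import dataclasses

        spec = dataclasses.replace(tiny_spec, clinical_dim=0)
        model = ResponseNet(spec, seed=0)
        probs, info = model.forward(rng.normal(size=(1, 4, 6, 6)))
        assert info["fused"].shape[1] == spec.embedding_dim
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_same_seed_same_init(self, tiny_spec):
        a = ResponseNet(tiny_spec, seed=5).state_dict()
        b = ResponseNet(tiny_spec, seed=5).state_dict()
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_state_dict_round_trip(self, tiny_spec, rng):
        a = ResponseNet(tiny_spec, seed=1)
        b = ResponseNet(tiny_spec, seed=2)
        b.load_state_dict(a.state_dict())
        x, cl = rng.normal(size=(1, 4, 6, 6)), rng.normal(size=(1, 3))
        np.testing.assert_array_equal(a.forward(x, cl)[0], b.forward(x, cl)[0])

    def test_backbone_and_classifier_split_agree_with_forward(self, tiny_spec, rng):
        model = ResponseNet(tiny_spec, seed=4)
        x, cl = rng.normal(size=(2, 4, 6, 6)), rng.normal(size=(2, 3))
        probs, info = model.forward(x, cl)
        emb = model.backbone_forward(x)
        np.testing.assert_allclose(emb, info["embedding"], atol=1e-12)
        probs2, fused = model.classifier_forward(emb, cl)
        np.testing.assert_allclose(probs2, probs, atol=1e-12)
        np.testing.assert_allclose(fused, info["fused"], atol=1e-12)

    def test_classifier_forward_rejects_wrong_embedding(self, tiny_spec):
        model = ResponseNet(tiny_spec, seed=0)
        with pytest.raises(ValueError, match="embedding"):
            model.classifier_forward(np.zeros((1, 10)), np.zeros((1, 3)))

    def test_gradient_matches_finite_differences(self, tiny_spec, rng):
        from recistnet.training import nll_loss

        model = ResponseNet(tiny_spec, seed=1)
        x = rng.normal(size=(2, 4, 6, 6))
        cl = rng.normal(size=(2, 3))
        y = np.array([0, 1])
        onehot = np.eye(2)[y]

        probs, _ = model.forward(x, cl, train=True)
        model.zero_grad()
        model.backward(probs - onehot)
        eps = 1e-6
        picker = np.random.default_rng(0)
        for name, par in model.named_parameters():
            flat = par.value.ravel()
            idx = int(picker.integers(flat.size))
            old = flat[idx]
            flat[idx] = old + eps
            lp = nll_loss(model.forward(x, cl, train=True)[0], y)
            flat[idx] = old - eps
            lm = nll_loss(model.forward(x, cl, train=True)[0], y)
            flat[idx] = old
            num = (lp - lm) / (2 * eps)
            assert par.grad.ravel()[idx] == pytest.approx(num, abs=1e-4, rel=1e-3), name


class TestSpecValidation:
    def test_mismatched_stage_lists_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureSpec(dense_block_layers=(6, 8), nonlocal_counts=(0,))

    def test_default_invariants(self):
        spec = ArchitectureSpec()
        assert spec.stem_channels + sum(n * spec.growth for n in spec.dense_block_layers) == 736
        assert spec.embedding_dim == 736
        assert spec.fused_dim == 751

    def test_yaml_dict_round_trip(self):
        spec = ArchitectureSpec.small()
        assert ArchitectureSpec.from_dict(spec.to_dict()) == spec
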
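"""The SE and attention operators against trivial cases and loop oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from casenet import nn
from casenet.core_blocks import (
    AttentionGate,
    AttentionGateParams,
    ExcitationParams,
    SEBlock,
    attention_gate,
    conv_block,
    excite,
    scale,
    se_block,
    squeeze,
    transposed_conv_up,
)

import oracles


class TestSqueeze:
    def test_constant_channels(self):
        fm = np.stack([np.full((4, 4), 5.0), np.full((4, 4), -1.0)])
        np.testing.assert_array_equal(squeeze(fm), [5.0, -1.0])

    def test_single_channel_mean(self):
        fm = np.array([[1.0, 2.0], [3.0, 4.0]])[None]
        assert squeeze(fm) == pytest.approx([2.5])

    def test_matches_loop_oracle(self, rng):
        fm = rng.uniform(-1, 1, (3, 5, 7))
        np.testing.assert_allclose(squeeze(fm), oracles.squeeze_loops(fm), atol=1e-6)

    def test_rejects_non_finite(self):
        fm = np.ones((1, 2, 2))
        fm[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            squeeze(fm)


class TestExcite:
    def test_zero_weights_give_half(self):
        p = ExcitationParams(np.zeros((1, 8)), np.zeros(1), np.zeros((8, 1)), np.zeros(8))
        np.testing.assert_allclose(excite(np.arange(8.0), p), np.full(8, 0.5))

    def test_one_unit_bottleneck(self):
        # C=8, g=8: all-ones weights, z = e1 -> every gate = sigmoid(relu(1))
        p = ExcitationParams(np.ones((1, 8)), np.zeros(1), np.ones((8, 1)), np.zeros(8))
        z = np.zeros(8)
        z[0] = 1.0
        expected = 1.0 / (1.0 + np.exp(-1.0))
        np.testing.assert_allclose(excite(z, p), np.full(8, expected))

    def test_matches_loop_oracle(self, rng):
        C, g = 16, 8
        p = ExcitationParams.init(C, g, rng=rng)
        z = rng.standard_normal(C)
        ref = oracles.excite_loops(z, p.w1, p.b1, p.w2, p.b2)
        np.testing.assert_allclose(excite(z, p), ref, atol=1e-6)

    def test_indivisible_reduction_rejected_at_construction(self):
        with pytest.raises(ValueError, match="divisible"):
            ExcitationParams.init(10, 8)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_gates_strictly_inside_unit_interval(self, seed):
        # moderate activations: beyond |logit| ~ 37 the float64 sigmoid
        # saturates to exactly 0/1 even though the gate is open analytically
        r = np.random.default_rng(seed)
        p = ExcitationParams.init(8, 4, rng=r)
        s = excite(r.standard_normal(8), p)
        assert np.all(s > 0) and np.all(s < 1)


class TestScaleAndSEBlock:
    def test_ones_identity_zeros_annihilate(self, rng):
        fm = rng.standard_normal((3, 4, 4))
        np.testing.assert_array_equal(scale(fm, np.ones(3)), fm)
        np.testing.assert_array_equal(scale(fm, np.zeros(3)), np.zeros_like(fm))

    def test_matches_loop_oracle(self, rng):
        fm = rng.standard_normal((4, 3, 5))
        s = rng.uniform(0, 1, 4)
        np.testing.assert_allclose(scale(fm, s), oracles.scale_loops(fm, s), atol=1e-6)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="length"):
            scale(rng.standard_normal((3, 2, 2)), np.ones(4))

    def test_se_block_constant_input_zero_weights(self):
        fm = np.full((8, 4, 4), 2.0)
        p = ExcitationParams(np.zeros((1, 8)), np.zeros(1), np.zeros((8, 1)), np.zeros(8))
        np.testing.assert_allclose(se_block(fm, p), 0.5 * fm)

    def test_se_block_with_unit_gates_is_identity(self, rng):
        fm = rng.standard_normal((4, 4, 4))
        np.testing.assert_allclose(scale(fm, np.ones(4)), fm)

    def test_se_block_matches_composed_oracles(self, rng):
        fm = rng.standard_normal((8, 6, 6))
        p = ExcitationParams.init(8, 4, rng=rng)
        z = oracles.squeeze_loops(fm)
        s = oracles.excite_loops(z, p.w1, p.b1, p.w2, p.b2)
        np.testing.assert_allclose(se_block(fm, p), oracles.scale_loops(fm, s), atol=1e-6)

    def test_squeeze_scale_linearity(self, rng):
        # mean is linear: squeeze(scale(fm, s)) == s * squeeze(fm)
        fm = rng.standard_normal((5, 3, 3))
        s = rng.uniform(-2, 2, 5)
        np.testing.assert_allclose(
            squeeze(scale(fm, s)), s * squeeze(fm), atol=1e-6
        )


class TestAttentionGate:
    def test_zero_weights_halve_skip(self, rng):
        skip = rng.standard_normal((3, 4, 4))
        gate = rng.standard_normal((2, 4, 4))
        p = AttentionGateParams(
            np.zeros((2, 3)), np.zeros((2, 2)), np.zeros(2), np.zeros(2), np.zeros(2)
        )
        out, alpha = attention_gate(skip, gate, p)
        np.testing.assert_allclose(alpha, 0.5)
        np.testing.assert_allclose(out, 0.5 * skip)

    def test_zero_skip_gives_zero_output(self, rng):
        skip = np.zeros((2, 4, 4))
        gate = rng.standard_normal((2, 4, 4))
        p = AttentionGateParams.init(2, 2, rng=rng)
        out, _ = attention_gate(skip, gate, p)
        np.testing.assert_array_equal(out, np.zeros_like(skip))

    def test_matches_loop_oracle(self, rng):
        skip = rng.standard_normal((1, 3, 3))
        gate = rng.standard_normal((1, 3, 3))
        p = AttentionGateParams.init(1, 1, inter_channels=2, rng=rng)
        out, alpha = attention_gate(skip, gate, p)
        ref_out, ref_alpha = oracles.attention_gate_loops(
            skip, gate, p.wx, p.bx, p.wg, p.bg, p.psi, p.bpsi
        )
        np.testing.assert_allclose(alpha, ref_alpha, atol=1e-6)
        np.testing.assert_allclose(out, ref_out, atol=1e-6)
        assert np.all(alpha > 0) and np.all(alpha < 1)

    def test_spatial_mismatch_rejected_with_both_shapes(self, rng):
        p = AttentionGateParams.init(1, 1, rng=rng)
        with pytest.raises(ValueError, match=r"\(1, 3, 3\).*\(1, 4, 4\)"):
            attention_gate(np.ones((1, 3, 3)), np.ones((1, 4, 4)), p)

    def test_layer_agrees_with_functional(self, rng):
        layer = AttentionGate(3, 2, rng=42)
        skip = rng.standard_normal((1, 3, 6, 6)).astype(np.float32)
        gate = rng.standard_normal((1, 2, 6, 6)).astype(np.float32)
        got = layer(nn.Tensor(skip), nn.Tensor(gate)).data[0]
        p = AttentionGateParams(
            wx=layer.wx.data[:, :, 0, 0],
            wg=layer.wg.data[:, :, 0, 0],
            psi=layer.psi.data[0, :, 0, 0],
            bx=layer.bx.data,
            bg=layer.bg.data,
            bpsi=float(layer.bpsi.data[0]),
        )
        ref, _ = attention_gate(skip[0], gate[0], p)
        np.testing.assert_allclose(got, ref, atol=1e-5)


class TestConvPrimitives:
    def test_delta_kernel_identity(self, rng):
        fm = rng.standard_normal((1, 5, 5))
        w = np.zeros((1, 1, 3, 3))
        w[0, 0, 1, 1] = 1.0
        out = conv_block(fm, [w], activation="linear")
        np.testing.assert_allclose(out, fm, atol=1e-6)

    def test_zero_input_gives_activated_bias(self):
        fm = np.zeros((1, 4, 4))
        w = np.ones((2, 1, 3, 3))
        b = np.array([1.5, -2.0])
        out = conv_block(fm, [w], [b], activation="relu")
        np.testing.assert_allclose(out[0], 1.5)
        np.testing.assert_allclose(out[1], 0.0)

    def test_matches_sliding_window_oracle(self, rng):
        fm = rng.standard_normal((1, 7, 7))
        w = rng.standard_normal((1, 1, 5, 5))
        b = rng.standard_normal(1)
        out = conv_block(fm, [w], [b], activation="linear")
        np.testing.assert_allclose(out, oracles.conv2d_loops(fm, w, b), atol=1e-6)

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError, match="even"):
            conv_block(np.ones((1, 4, 4)), [np.ones((1, 1, 4, 4))])

    def test_preserves_spatial_size(self, rng):
        fm = rng.standard_normal((2, 8, 8))
        w1 = rng.standard_normal((4, 2, 5, 5)) * 0.1
        w2 = rng.standard_normal((4, 4, 5, 5)) * 0.1
        out = conv_block(fm, [w1, w2])
        assert out.shape == (4, 8, 8)

    def test_transposed_conv_tiles_input(self):
        fm = np.array([[1.0, 2.0], [3.0, 4.0]])[None]
        w = np.ones((1, 1, 2, 2))
        out = transposed_conv_up(fm, w)
        expected = np.repeat(np.repeat(fm[0], 2, 0), 2, 1)
        np.testing.assert_array_equal(out[0], expected)

    def test_transposed_conv_zero_input(self):
        out = transposed_conv_up(np.zeros((2, 3, 3)), np.ones((2, 1, 2, 2)))
        np.testing.assert_array_equal(out, np.zeros((1, 6, 6)))

    def test_transposed_conv_matches_scatter_oracle(self, rng):
        fm = rng.standard_normal((2, 3, 3))
        w = rng.standard_normal((2, 3, 2, 2))
        b = rng.standard_normal(3)
        out = transposed_conv_up(fm, w, b)
        ref = oracles.conv_transpose_loops(fm, w, b)
        assert out.shape == (3, 6, 6)
        np.testing.assert_allclose(out, ref, atol=1e-6)


class TestFinitenessAndShapes:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_se_block_preserves_shape_and_finiteness(self, seed):
        r = np.random.default_rng(seed)
        fm = r.standard_normal((8, 6, 6)) * r.uniform(0.1, 50)
        p = ExcitationParams.init(8, 8, rng=r)
        out = se_block(fm, p)
        assert out.shape == fm.shape
        assert np.all(np.isfinite(out))

    def test_se_layer_agrees_with_functional(self, rng):
        layer = SEBlock(8, reduction=4, rng=11)
        fm = rng.standard_normal((1, 8, 5, 5)).astype(np.float32)
        got = layer(nn.Tensor(fm)).data[0]
        p = ExcitationParams(layer.w1.data, layer.b1.data, layer.w2.data, layer.b2.data)
        np.testing.assert_allclose(got, se_block(fm[0], p), atol=1e-5)
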
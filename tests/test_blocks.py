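"""Tests of the network building blocks: gates, residual algebra, shapes."""

import numpy as np
import pytest

from apunet import nn
from apunet.blocks import (
    ChannelAttention,
    ConvBlock,
    HybridAttention,
    MFABlock,
    SpatialAttention,
    TwoModalBlock,
)
from apunet.nn import Tensor


def rand(shape, seed=0, lo=-1.0, hi=1.0):
    return Tensor(np.random.default_rng(seed).uniform(lo, hi, size=shape))


def np_sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def zero_params(module):
    for p in module.parameters():
        p.data[...] = 0.0


class TestConvBlock:
    def test_shape_and_nonnegativity(self):
        block = ConvBlock(16, 32, np.random.default_rng(0))
        out = block(rand((1, 16, 50, 50)))
        assert out.shape == (1, 32, 50, 50)
        assert out.data.min() >= 0.0

    def test_zero_input_zero_params_gives_zero(self):
        block = ConvBlock(3, 4, np.random.default_rng(0))
        zero_params(block)
        for m in block.modules():
            if isinstance(m, nn.BatchNorm2d):
                m.gamma.data[...] = 1.0  # eval-mode identity normalization
        block.eval()
        out = block(Tensor(np.zeros((1, 3, 8, 8))))
        np.testing.assert_array_equal(out.data, 0.0)


class TestTwoModalBlock:
    def test_concat_doubles_channels(self):
        block = TwoModalBlock(16, np.random.default_rng(0))
        out = block(rand((1, 16, 50, 50), 1), rand((1, 16, 50, 50), 2))
        assert out.shape == (1, 32, 50, 50)

    def test_zero_convs_give_half_concat(self):
        """All-zero gate pre-activations: sigmoid(0)=0.5 scales the concat."""
        block = TwoModalBlock(2, np.random.default_rng(0))
        zero_params(block)
        x1, x2 = rand((1, 2, 4, 4), 1), rand((1, 2, 4, 4), 2)
        out = block(x1, x2)
        expected = 0.5 * np.concatenate([x1.data, x2.data], axis=1)
        np.testing.assert_allclose(out.data, expected, rtol=1e-6)

    def test_matches_independent_gate_recomputation(self):
        """Recompute cat * sigmoid(conv3x3(relu(conv1x1(cat)))) in plain numpy."""
        block = TwoModalBlock(2, np.random.default_rng(3))
        x1, x2 = rand((1, 2, 4, 4), 1), rand((1, 2, 4, 4), 2)
        out = block(x1, x2).data

        cat = np.concatenate([x1.data, x2.data], axis=1)  # (1, 4, 4, 4)
        w1, b1 = block.conv1.weight.data, block.conv1.bias.data
        pre = np.zeros_like(cat)
        for co in range(4):
            pre[0, co] = sum(cat[0, ci] * w1[co, ci, 0, 0] for ci in range(4)) + b1[co]
        hid = np.maximum(pre, 0.0)
        w2, b2 = block.conv2.weight.data, block.conv2.bias.data
        padded = np.pad(hid, ((0, 0), (0, 0), (1, 1), (1, 1)))
        gate_pre = np.zeros_like(cat)
        for co in range(4):
            for r in range(4):
                for c in range(4):
                    acc = b2[co]
                    for ci in range(4):
                        acc += np.sum(padded[0, ci, r:r + 3, c:c + 3] * w2[co, ci])
                    gate_pre[0, co, r, c] = acc
        expected = cat * np_sigmoid(gate_pre)
        np.testing.assert_allclose(out, expected, rtol=1e-5, atol=1e-7)

    def test_gate_variant_conv1x1(self):
        block = TwoModalBlock(4, np.random.default_rng(0), gate_variant="conv1x1")
        assert block.conv2.weight.shape[2:] == (1, 1)
        with pytest.raises(ValueError):
            TwoModalBlock(4, np.random.default_rng(0), gate_variant="conv5x5")

    def test_shape_mismatch(self):
        block = TwoModalBlock(2, np.random.default_rng(0))
        with pytest.raises(ValueError, match="mismatch"):
            block(rand((1, 2, 4, 4)), rand((1, 2, 5, 5)))


class TestSpatialAttention:
    def test_residual_limits(self):
        att = SpatialAttention(np.random.default_rng(0))
        x = rand((2, 3, 6, 6), 5)
        att.gate_override = 0.0
        np.testing.assert_array_equal(att(x).data, x.data)
        att.gate_override = 1.0
        np.testing.assert_allclose(att(x).data, 2 * x.data)

    def test_channel_max_finds_hot_pixel(self):
        x = np.zeros((1, 3, 4, 4))
        x[0, 1, 2, 3] = 10.0
        mx = nn.channel_max(Tensor(x)).data[0, 0]
        assert np.unravel_index(mx.argmax(), mx.shape) == (2, 3)
        # brute force over channels
        np.testing.assert_array_equal(mx, x[0].max(axis=0))


class TestChannelAttention:
    def test_residual_limits(self):
        att = ChannelAttention(6, np.random.default_rng(0))
        x = rand((2, 6, 5, 5), 1)
        att.gate_override = 0.0
        np.testing.assert_array_equal(att(x).data, x.data)
        att.gate_override = 1.0
        np.testing.assert_allclose(att(x).data, 2 * x.data)

    def test_hidden_width_is_third_of_channels(self):
        att = ChannelAttention(96, np.random.default_rng(0))
        assert att.fc1.weight.shape == (32, 96)
        assert att.fc2.weight.shape == (96, 32)

    def test_too_few_channels(self):
        with pytest.raises(ValueError, match="3 channels"):
            ChannelAttention(2, np.random.default_rng(0))


class TestHybridAttention:
    def test_concat_arithmetic(self):
        att = HybridAttention(96, np.random.default_rng(0))
        out = att(rand((1, 32, 25, 25), 1), rand((1, 64, 25, 25), 2))
        assert out.shape == (1, 96, 25, 25)

    def test_double_residual_identity(self):
        att = HybridAttention(8, np.random.default_rng(0))
        att.channel.gate_override = 0.0
        att.spatial.gate_override = 0.0
        a, b = rand((1, 4, 6, 6), 1), rand((1, 4, 6, 6), 2)
        expected = np.concatenate([a.data, b.data], axis=1)
        np.testing.assert_array_equal(att(a, b).data, expected)

    def test_finite_on_wide_range_inputs(self):
        att = HybridAttention(8, np.random.default_rng(0))
        out = att(rand((1, 4, 6, 6), 1, -10, 10), rand((1, 4, 6, 6), 2, -10, 10))
        assert np.all(np.isfinite(out.data))

    def test_spatial_mismatch(self):
        att = HybridAttention(8, np.random.default_rng(0))
        with pytest.raises(ValueError, match="mismatch"):
            att(rand((1, 4, 6, 6)), rand((1, 4, 5, 5)))


class TestMFABlock:
    def default_pairs(self, seed=0, size_top=6):
        """Four decoder scales: (A,B) channels (128,256)..(16,32), coarse first."""
        sizes = [6, 12, 25, 50]
        chans = [(128, 256), (64, 128), (32, 64), (16, 32)]
        rng = np.random.default_rng(seed)
        return [
            (Tensor(rng.normal(size=(1, ca, s, s))),
             Tensor(rng.normal(size=(1, cb, s, s))))
            for (ca, cb), s in zip(chans, sizes)
        ]

    def test_f_has_64_channels_at_full_resolution(self):
        block = MFABlock([(128, 256), (64, 128), (32, 64), (16, 32)],
                         np.random.default_rng(0), out_size=50)
        f = block.aggregate(self.default_pairs())
        assert f.shape == (1, 64, 50, 50)
        assert block.fc1.weight.shape == (21, 64)  # hidden width floor(64/3)

    def test_gate_limits(self):
        block = MFABlock([(4, 8)] * 4, np.random.default_rng(0), out_size=8)
        pairs = [(rand((1, 4, s, s), i), rand((1, 8, s, s), 10 + i))
                 for i, s in enumerate((2, 4, 6, 8))]
        f = block.aggregate(pairs).data
        block.alpha_override, block.beta_override = 1.0, 0.0
        np.testing.assert_allclose(block(pairs).data, 2 * f, rtol=1e-6)
        block.alpha_override, block.beta_override = 0.0, None
        np.testing.assert_allclose(block(pairs).data, f, rtol=1e-6)

    def test_combination_algebra_against_elementwise_recomputation(self):
        """F*alpha*beta + F*alpha + F recomputed from extracted gates."""
        block = MFABlock([(2, 3)] * 4, np.random.default_rng(1), out_size=4)
        pairs = [(rand((1, 2, s, s), i), rand((1, 3, s, s), 20 + i))
                 for i, s in enumerate((4, 4, 4, 4))]
        f = block.aggregate(pairs).data
        # alpha from the MLP on the pooled F
        pooled = f.mean(axis=(2, 3))
        hid = np.maximum(pooled @ block.fc1.weight.data.T, 0.0)
        alpha = np_sigmoid(hid @ block.fc2.weight.data.T)[:, :, None, None]
        fa = f * alpha
        # beta from conv1x1(relu(conv3x3(F*alpha)))
        w3, b3 = block.conv3.weight.data, block.conv3.bias.data
        pad = np.pad(fa, ((0, 0), (0, 0), (1, 1), (1, 1)))
        c = fa.shape[1]
        conv3 = np.zeros_like(fa)
        for co in range(c):
            for r in range(4):
                for cc in range(4):
                    conv3[0, co, r, cc] = b3[co] + np.sum(
                        pad[0, :, r:r + 3, cc:cc + 3] * w3[co])
        act = np.maximum(conv3, 0.0)
        w1, b1 = block.conv1.weight.data, block.conv1.bias.data
        beta = np_sigmoid(
            np.einsum("oc,nchw->nohw", w1[:, :, 0, 0], act) + b1[None, :, None, None])
        expected = fa * beta + fa + f
        np.testing.assert_allclose(block(pairs).data, expected, rtol=1e-4,
                                   atol=1e-6)

    def test_wrong_scale_count(self):
        block = MFABlock([(4, 8)] * 4, np.random.default_rng(0), out_size=8)
        with pytest.raises(ValueError, match="scales"):
            block(self.default_pairs()[:3])


class TestGateRanges:
    def test_all_gates_within_unit_interval(self):
        """Extracted gate = output/input - 1 for residual blocks stays in [0,1]."""
        rng = np.random.default_rng(0)
        x = Tensor(np.abs(rng.normal(size=(1, 6, 8, 8))) + 0.5)
        sa = SpatialAttention(np.random.default_rng(1))
        ca = ChannelAttention(6, np.random.default_rng(2))
        for att in (sa, ca):
            ratio = att(x).data / x.data - 1.0
            assert ratio.min() >= -1e-6 and ratio.max() <= 1.0 + 1e-6
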
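"""Network blocks: convolution stacks, attention mechanisms, C3, SPPF.

Each attention block is checked against an independent hand-rolled NumPy
evaluation of its defining formula, and against the analytic fixed point
``0.5 * X`` reached when every learned parameter is zero.
"""

import numpy as np
import pytest
from scipy.special import expit

from greenfruit.blocks import (
    C3,
    SPPF,
    Bottleneck,
    ChannelAttention,
    ConvAT,
    ConvBnAct,
    SpatialAttention,
)
from greenfruit.nn import Tensor, avgpool2d, concat, maxpool2d


def rand_input(rng, c=4, h=8, w=8, n=1):
    return Tensor(rng.normal(size=(n, c, h, w)).astype(np.float64))


def zero_params(module):
    for p in module.parameters():
        p.data = np.zeros_like(p.data)


class TestConvBnAct:
    def test_spatial_arithmetic_k3_s2(self, rng):
        block = ConvBnAct(3, 8, 3, stride=2, rng=rng).eval()
        out = block(rand_input(rng, 3, 64, 64))
        assert out.shape == (1, 8, 32, 32)

    def test_output_channels_contract(self, rng):
        block = ConvBnAct(4, 16, 1, rng=rng).eval()
        assert block(rand_input(rng)).shape == (1, 16, 8, 8)

    def test_relu_zeroes_negative_preactivation(self, rng):
        block = ConvBnAct(4, 8, 3, activation="relu", rng=rng).eval()
        zero_params(block)
        block.bn.beta.data = np.full(8, -1.0, dtype=np.float32)  # BN shift below zero
        out = block(rand_input(rng))
        assert np.all(out.data == 0.0)

    def test_unknown_activation_rejected(self, rng):
        with pytest.raises(ValueError):
            ConvBnAct(4, 8, activation="tanh", rng=rng)


def eq5_oracle(x, w1, w2):
    """Hand-rolled channel attention: X * sigmoid(MLP(avg) + MLP(max))."""
    avg = x.mean(axis=(2, 3))  # (N, C)
    mx = x.max(axis=(2, 3))

    def mlp(v):
        return np.maximum(v @ w1, 0.0) @ w2

    gate = expit(mlp(avg) + mlp(mx))
    return x * gate[:, :, None, None]


def eq6_oracle(x, mix_w):
    """Hand-rolled spatial attention: X * sigmoid(1x1-mix(avg | max))."""
    avg = x.mean(axis=1, keepdims=True)
    mx = x.max(axis=1, keepdims=True)
    stacked = np.concatenate([avg, mx], axis=1)  # (N, 2, H, W)
    mixed = np.einsum("nchw,oc->nohw", stacked, mix_w.reshape(1, 2))
    return x * expit(mixed)


class TestChannelAttention:
    def test_zero_parameters_fixed_point(self, rng):
        ca = ChannelAttention(4, reduction=2, rng=rng)
        zero_params(ca)
        x = rand_input(rng)
        assert np.allclose(ca(x).data, 0.5 * x.data, atol=0.0)

    def test_spatially_constant_input_symmetry(self, rng):
        """Constant spatial maps make avg and max pools coincide, so the gate
        is sigmoid(2 * MLP(v))."""
        ca = ChannelAttention(4, reduction=2, rng=rng)
        v = rng.normal(size=(1, 4)).astype(np.float64)
        x = Tensor(np.broadcast_to(v[:, :, None, None], (1, 4, 8, 8)).copy())
        out = ca(x)
        mlp_v = np.maximum(v @ ca.fc1.weight.data, 0) @ ca.fc2.weight.data
        gate = expit(2.0 * mlp_v)
        assert np.allclose(out.data, x.data * gate[:, :, None, None], atol=1e-6)

    def test_matches_hand_rolled_formula(self, rng):
        ca = ChannelAttention(4, reduction=2, rng=rng)
        x = rand_input(rng, 4, 8, 8)
        expected = eq5_oracle(x.data, ca.fc1.weight.data.astype(np.float64),
                              ca.fc2.weight.data.astype(np.float64))
        assert np.allclose(ca(x).data, expected, atol=1e-6)

    def test_gate_strictly_in_unit_interval_and_shape_kept(self, rng):
        ca = ChannelAttention(8, rng=rng)
        x = rand_input(rng, 8, 6, 6)
        out = ca(x)
        assert out.shape == x.shape
        with np.errstate(divide="ignore", invalid="ignore"):
            gate = np.where(x.data != 0, out.data / x.data, 0.5)
        assert (gate > 0).all() and (gate < 1).all()

    def test_invalid_reduction_rejected(self, rng):
        with pytest.raises(ValueError):
            ChannelAttention(4, reduction=0, rng=rng)


class TestSpatialAttention:
    def test_zero_parameters_fixed_point(self, rng):
        sa = SpatialAttention(rng=rng)
        zero_params(sa)
        x = rand_input(rng)
        assert np.allclose(sa(x).data, 0.5 * x.data, atol=0.0)

    def test_channelwise_constant_input_gives_uniform_gate(self, rng):
        sa = SpatialAttention(rng=rng)
        x = Tensor(np.full((1, 4, 8, 8), 1.7))
        out = sa(x)
        gate = out.data / x.data
        assert np.allclose(gate, gate.flat[0], atol=1e-9)

    def test_matches_hand_rolled_formula(self, rng):
        sa = SpatialAttention(rng=rng)
        x = rand_input(rng, 4, 8, 8)
        expected = eq6_oracle(x.data, sa.mix.weight.data.astype(np.float64))
        assert np.allclose(sa(x).data, expected, atol=1e-6)


class TestConvAT:
    def test_output_channels_and_downsampling(self, rng):
        block = ConvAT(8, 16, stride=2, reduction=2, rng=rng).eval()
        out = block(rand_input(rng, 8, 16, 16))
        assert out.shape == (1, 16, 8, 8)

    def test_intermediate_concat_widths(self, rng):
        block = ConvAT(8, 16, stride=2, reduction=2, rng=rng).eval()
        x = rand_input(rng, 8, 16, 16)
        p = concat([block._downsample(block.ca(x)), block.cbr1(x)], axis=1)
        assert p.shape[1] == 8 + 16 // 2  # c_in + first CBR width

    def test_equals_stagewise_composition(self, rng):
        """The block must equal the explicit composition
        P = [CA(X); CBR1(X)], H = [CBR2(P); SA(X)], W = [CBR3(H); CBR4(X)],
        Y = BN(CBR5(W)) evaluated from its own tested sub-blocks."""
        block = ConvAT(8, 16, stride=2, reduction=2, rng=rng).eval()
        x = rand_input(rng, 8, 16, 16)
        p = concat([avgpool2d(block.ca(x), 2), block.cbr1(x)], axis=1)
        h = concat([block.cbr2(p), avgpool2d(block.sa(x), 2)], axis=1)
        w = concat([block.cbr3(h), block.cbr4(x)], axis=1)
        y = block.bn_out(block.cbr5(w))
        assert np.allclose(block(x).data, y.data, atol=1e-6)

    def test_odd_output_channels_rejected(self, rng):
        with pytest.raises(ValueError):
            ConvAT(8, 15, rng=rng)


class TestC3:
    def test_shape_contract(self, rng):
        block = C3(8, 16, n=2, rng=rng).eval()
        out = block(rand_input(rng, 8, 8, 8))
        assert out.shape == (1, 16, 8, 8)

    def test_zero_bottlenecks_degenerates_to_projections(self, rng):
        block = C3(8, 16, n=0, rng=rng).eval()
        x = rand_input(rng, 8, 8, 8)
        manual = block.cv3(concat([block.cv1(x), block.cv2(x)], axis=1))
        assert np.allclose(block(x).data, manual.data, atol=1e-7)

    def test_zeroed_bottleneck_is_residual_identity(self, rng):
        """With conv weights zeroed and default BN stats (eval mode), the
        bottleneck's residual path passes the input through unchanged."""
        b = Bottleneck(4, shortcut=True, rng=rng).eval()
        for p in (b.cv1.conv.weight, b.cv2.conv.weight):
            p.data = np.zeros_like(p.data)
        x = rand_input(rng, 4, 6, 6)
        assert np.allclose(b(x).data, x.data, atol=1e-7)

    def test_odd_channels_rejected(self, rng):
        with pytest.raises(ValueError):
            C3(8, 15, rng=rng)


class TestSPPF:
    def test_constant_input_pools_to_itself(self, rng):
        x = Tensor(np.full((1, 4, 8, 8), 3.25))
        pooled = maxpool2d(x, 5)
        assert np.allclose(pooled.data, x.data)

    def test_cascaded_pools_equal_single_larger_pools(self, rng):
        x = rand_input(rng, 2, 12, 12)
        y1 = maxpool2d(x, 5)
        y2 = maxpool2d(y1, 5)
        y3 = maxpool2d(y2, 5)
        assert np.allclose(y2.data, maxpool2d(x, 9).data)
        assert np.allclose(y3.data, maxpool2d(x, 13).data)

    def test_shape_contract(self, rng):
        block = SPPF(8, 16, rng=rng).eval()
        out = block(rand_input(rng, 8, 8, 8))
        assert out.shape == (1, 16, 8, 8)


def test_all_blocks_finite_for_random_inputs(rng):
    blocks = [
        ConvBnAct(4, 8, 3, rng=rng).eval(),
        ChannelAttention(4, reduction=2, rng=rng),
        SpatialAttention(rng=rng),
        ConvAT(4, 8, stride=2, reduction=2, rng=rng).eval(),
        C3(4, 8, rng=rng).eval(),
        SPPF(4, 8, rng=rng).eval(),
    ]
    for _ in range(20):
        x = rand_input(rng, 4, 8, 8)
        for block in blocks:
            assert np.isfinite(block(x).data).all()
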
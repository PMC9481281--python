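"""Dilated causal convolution and residual blocks against brute-force
oracles."""

import numpy as np
import pytest

from anobeat import nn
from anobeat.tcn import (
    CausalConv1d,
    TCNBlock,
    TCNBlockSpec,
    causal_dilated_conv,
    receptive_field,
)


def conv_oracle(x: np.ndarray, w: np.ndarray, d: int) -> np.ndarray:
    """Direct triple-loop summation: y[t, o] = sum_j sum_c w[j,c,o] *
    x[t - j*d, c] with zero padding."""
    t_len, cin = x.shape
    k, _, cout = w.shape
    y = np.zeros((t_len, cout))
    for t in range(t_len):
        for j in range(k):
            src = t - j * d
            if src >= 0:
                y[t] += x[src] @ w[j]
    return y


class TestCausalConv:
    def test_identity_kernel(self):
        x = np.arange(6.0)
        y = causal_dilated_conv(x, np.ones(1), dilation=1)
        np.testing.assert_allclose(y, x)

    def test_hand_worked_example(self):
        y = causal_dilated_conv(np.array([1.0, 2, 3, 4]),
                                np.array([1.0, 1.0]), dilation=2)
        np.testing.assert_allclose(y, [1, 2, 4, 6])

    def test_matches_direct_summation_oracle(self, rng):
        for _ in range(100):
            t_len = int(rng.integers(2, 64))
            cin = int(rng.integers(1, 5))
            cout = int(rng.integers(1, 5))
            k = int(rng.integers(1, 5))
            d = int(rng.integers(1, 5))
            x = rng.standard_normal((t_len, cin))
            w = rng.standard_normal((k, cin, cout))
            got = causal_dilated_conv(x, w, dilation=d)
            np.testing.assert_allclose(got, conv_oracle(x, w, d), atol=1e-6)

    @pytest.mark.parametrize("k", [1, 2, 3, 9])
    @pytest.mark.parametrize("d", [1, 2, 4])
    def test_causality_by_perturbation(self, k, d, rng):
        x = rng.standard_normal((40, 2))
        w = rng.standard_normal((k, 2, 3))
        y = causal_dilated_conv(x, w, dilation=d)
        t0 = 25
        xp = x.copy()
        xp[t0] += 1.0
        yp = causal_dilated_conv(xp, w, dilation=d)
        np.testing.assert_array_equal(y[:t0], yp[:t0])
        assert np.any(y[t0] != yp[t0])

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            causal_dilated_conv(np.ones(4), np.ones(2), dilation=0)
        with pytest.raises(ValueError):
            CausalConv1d(1, 1, kernel_size=0)
        with pytest.raises(ValueError):
            TCNBlockSpec(1, 1, dilation=0)

    def test_layer_output_matches_functional(self, rng):
        with nn.default_dtype(np.float64):
            layer = CausalConv1d(2, 3, 4, dilation=2, weight_norm=True,
                                 rng=rng)
        w = rng.standard_normal((4, 2, 3))
        layer.set_kernel(w)
        layer.b.value[...] = 0.0
        x = rng.standard_normal((1, 30, 2))
        np.testing.assert_allclose(layer.forward(x)[0],
                                   causal_dilated_conv(x[0], w, 2),
                                   atol=1e-10)


class TestTCNBlock:
    def test_zero_f_weights_give_identity_for_nonneg_input(self, rng):
        with nn.default_dtype(np.float64):
            block = TCNBlock(TCNBlockSpec(3, 3, 5, 2, dropout_rate=0.0), rng)
        for conv in (block.conv1, block.conv2):
            conv.v.value[...] = 0.0
            conv.g.value[...] = 0.0
            conv.b.value[...] = 0.0
        x = np.abs(rng.standard_normal((2, 20, 3)))
        np.testing.assert_allclose(block.forward(x), x, atol=1e-12)

    def test_output_shape_with_channel_change(self, rng):
        block = TCNBlock(TCNBlockSpec(1, 32, 9, 1), rng)
        x = rng.standard_normal((2, 250, 1)).astype(np.float32)
        assert block.forward(x).shape == (2, 250, 32)

    def test_deterministic_in_inference_mode(self, rng):
        block = TCNBlock(TCNBlockSpec(2, 4, 3, 1, dropout_rate=0.5), rng)
        x = rng.standard_normal((2, 15, 2)).astype(np.float32)
        np.testing.assert_array_equal(block.forward(x), block.forward(x))

    def test_block_is_causal(self, rng):
        block = TCNBlock(TCNBlockSpec(1, 4, 3, 2), rng)
        x = rng.standard_normal((1, 30, 1)).astype(np.float32)
        y = block.forward(x)
        xp = x.copy()
        xp[0, 20] += 1.0
        yp = block.forward(xp)
        np.testing.assert_array_equal(y[0, :20], yp[0, :20])


class TestReceptiveField:
    def test_pointwise_kernel(self):
        assert receptive_field(1, (1, 2, 4)) == 1

    def test_empty_stack(self):
        assert receptive_field(9, ()) == 1

    @pytest.mark.parametrize(
        "k,dilations,expected",
        [(9, (1, 2, 4), 113), (2, (1,), 3), (3, (1, 2), 13)],
    )
    def test_formula_matches_perturbation_oracle(self, k, dilations, expected):
        """The analytic receptive field equals the earliest input sample
        that can reach the last output of a two-conv-per-block stack."""
        assert receptive_field(k, dilations) == expected

        t_len = expected + 20
        x = np.zeros(t_len)

        def stack(sig):
            out = sig
            for d in dilations:
                for _ in range(2):  # two convolutions per residual block
                    out = causal_dilated_conv(out, np.ones(k), dilation=d)
            return out

        base = stack(x)
        affecting = []
        for idx in range(t_len):
            xp = x.copy()
            xp[idx] = 1.0
            if stack(xp)[-1] != base[-1]:
                affecting.append(idx)
        assert (t_len - 1) - min(affecting) + 1 == expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            receptive_field(0, (1,))
        with pytest.raises(ValueError):
            receptive_field(3, (0,))
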
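"""The operational convolution against independent plain-convolution oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import correlate2d

from mwbrain.core_ops import (
    NodalWeights,
    OperationalLayerSpec,
    nodal_transform,
    operational_conv_forward,
    tanh_activation,
)
from mwbrain.nn import OperationalConv2d


def oracle_conv(x_hwc, banks, bias, pad_same):
    """Independent oracle: sum over q of per-channel scipy correlations of x**q."""
    q_order, out_c, in_c = banks.shape[0], banks.shape[1], banks.shape[2]
    mode = "same" if pad_same else "valid"
    out = None
    for q in range(q_order):
        xp = x_hwc ** (q + 1)
        maps = []
        for o in range(out_c):
            acc = sum(correlate2d(xp[:, :, c], banks[q, o, c], mode=mode)
                      for c in range(in_c))
            maps.append(acc)
        t = np.stack(maps, axis=-1)
        out = t if out is None else out + t
    return out + bias


class TestNodalTransform:
    @pytest.mark.parametrize("w,y,expected", [
        ((1, 0, 0), 0.5, 0.5),        # identity coefficient, higher orders zero
        ((1, 1, 1), 0.5, 0.875),      # 0.5 + 0.25 + 0.125
        ((2.5,), 0.3, 0.75),          # linear reduction at Q=1
        ((3.0, 0, 0, 0, 0), -0.2, -0.6),  # linear reduction at Q=5
    ])
    def test_polynomial_evaluation(self, w, y, expected):
        assert nodal_transform(np.array(w, dtype=float), y) == pytest.approx(expected)

    def test_empty_coefficients_rejected(self):
        with pytest.raises(ValueError):
            nodal_transform(np.array([]), 0.5)

    @given(c=st.floats(-3, 3), y=st.floats(-2, 2), q=st.integers(1, 6))
    @settings(deadline=None, max_examples=50)
    def test_linear_coefficients_reduce_to_scaling(self, c, y, q):
        """(c, 0, ..., 0) acts as c*y for any order Q."""
        w = np.zeros(q)
        w[0] = c
        assert nodal_transform(w, y) == pytest.approx(c * y, abs=1e-12)


class TestOperationalConvForward:
    def test_q1_matches_plain_convolution_oracle(self, rng):
        spec = OperationalLayerSpec(in_channels=2, out_channels=3, kernel_size=3,
                                    q_order=1)
        w = NodalWeights(banks=rng.standard_normal((1, 3, 2, 3, 3)),
                         bias=rng.standard_normal(3))
        x = rng.standard_normal((8, 8, 2))
        out = operational_conv_forward(x, w, spec)
        ref = oracle_conv(x, w.banks, w.bias, pad_same=True)
        np.testing.assert_allclose(out, ref, rtol=1e-12, atol=1e-12)

    @pytest.mark.parametrize("padding", ["same", "valid"])
    def test_q3_decomposes_into_power_convolutions(self, rng, padding):
        """Output equals the sum of Q plain convolutions of x, x^2, x^3."""
        spec = OperationalLayerSpec(in_channels=2, out_channels=2, kernel_size=3,
                                    q_order=3, padding=padding)
        w = NodalWeights(banks=rng.standard_normal((3, 2, 2, 3, 3)),
                         bias=rng.standard_normal(2))
        x = rng.standard_normal((7, 8, 2))
        out = operational_conv_forward(x, w, spec)
        ref = oracle_conv(x, w.banks, w.bias, pad_same=(padding == "same"))
        np.testing.assert_allclose(out, ref, rtol=1e-10, atol=1e-12)

    def test_constant_half_input_gives_nodal_value(self):
        """1x1 kernels with unit coefficients: each pixel is psi((1,1,1), 0.5)."""
        spec = OperationalLayerSpec(in_channels=1, out_channels=1, kernel_size=1,
                                    q_order=3)
        w = NodalWeights(banks=np.ones((3, 1, 1, 1, 1)), bias=np.zeros(1))
        out = operational_conv_forward(np.full((2, 2, 1), 0.5), w, spec)
        np.testing.assert_allclose(out, 0.875)

    def test_zero_input_returns_bias(self, rng):
        spec = OperationalLayerSpec(in_channels=1, out_channels=2, kernel_size=3,
                                    q_order=3)
        w = NodalWeights(banks=rng.standard_normal((3, 2, 1, 3, 3)),
                         bias=np.array([0.7, -1.2]))
        out = operational_conv_forward(np.zeros((6, 6, 1)), w, spec)
        np.testing.assert_allclose(out[..., 0], 0.7)
        np.testing.assert_allclose(out[..., 1], -1.2)

    def test_channel_mismatch_raises(self, rng):
        spec = OperationalLayerSpec(in_channels=2, out_channels=1, q_order=1)
        w = NodalWeights(banks=rng.standard_normal((1, 1, 2, 3, 3)),
                         bias=np.zeros(1))
        with pytest.raises(ValueError, match="channel mismatch"):
            operational_conv_forward(np.zeros((5, 5, 3)), w, spec)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            OperationalLayerSpec(in_channels=1, out_channels=1, q_order=0)


class TestTanhActivation:
    def test_odd_and_bounded(self, rng):
        x = rng.standard_normal((4, 4, 2)) * 10
        y = tanh_activation(x)
        assert np.all(y >= -1) and np.all(y <= 1)
        np.testing.assert_allclose(tanh_activation(-x), -y, rtol=1e-12)
        assert tanh_activation(np.zeros((1, 1, 1))).item() == 0.0

    def test_saturates_below_one(self):
        y = tanh_activation(np.array([[[5.0]]])).item()
        assert 0.999 < y < 1.0


class TestLayerGradients:
    """Analytic gradients of the trainable layer vs central finite differences."""

    def _finite_diff(self, fn, arr, eps=1e-6):
        num = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = arr[i]
            arr[i] = orig + eps
            lp = fn()
            arr[i] = orig - eps
            lm = fn()
            arr[i] = orig
            num[i] = (lp - lm) / (2 * eps)
        return num

    @pytest.mark.parametrize("q_order", [1, 3])
    def test_gradient_contract(self, rng, q_order):
        """Every bank coefficient, the bias and the input: <= 1e-4 relative error."""
        layer = OperationalConv2d(2, 3, kernel_size=3, q_order=q_order,
                                  rng=rng, dtype=np.float64)
        x = rng.standard_normal((2, 2, 6, 6))
        dy = rng.standard_normal((2, 3, 6, 6))

        def loss():
            return float((layer.forward(x) * dy).sum())

        layer.forward(x)
        layer.zero_grad()
        dx = layer.backward(dy)
        num_dx = self._finite_diff(loss, x)
        assert np.abs(num_dx - dx).max() <= 1e-4 * max(np.abs(num_dx).max(), 1.0)
        for name in ("banks", "bias"):
            analytic = layer.grads[name].copy()
            num = self._finite_diff(loss, layer.params[name])
            assert np.abs(num - analytic).max() <= 1e-4 * max(np.abs(num).max(), 1.0)
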
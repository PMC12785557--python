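"""The NumPy Double U-Net engine: dice loss, architecture, gradients."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rishquant.nn.layers as nn_layers
import rishquant.nn.network as nn_network
from rishquant.nn import DoubleUNet, dice_loss, dice_loss_grad


class TestDiceLoss:
    def test_perfect_overlap_is_zero(self):
        m = np.zeros((6, 6))
        m[1:3, 1:4] = 1  # 6 px; any nonempty overlap works
        m[4, 4:8] = 1
        assert m.sum() == 8
        assert dice_loss(m, m, eps=1e-12) == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_masks_is_one(self):
        a = np.zeros((6, 6))
        b = np.zeros((6, 6))
        a[0, :] = 1
        b[5, :] = 1
        assert dice_loss(a, b, eps=1e-12) == pytest.approx(1.0, abs=1e-9)

    def test_superset_prediction_hand_computed(self):
        # truth 10 px; prediction = truth + 10 extra px on an enumerated grid:
        # intersection 10, sums 20 + 10 -> loss = 1 - 20/30 = 1/3
        truth = np.zeros((6, 6))
        truth.flat[:10] = 1
        pred = np.zeros((6, 6))
        pred.flat[:20] = 1
        assert dice_loss(pred, truth, eps=1e-12) == pytest.approx(1 / 3, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((3, 3)), np.zeros((4, 4)))

    @given(st.integers(0, 2**31 - 1))
    def test_bounded_and_symmetric_on_binary_masks(self, seed):
        rng = np.random.default_rng(seed)
        a = (rng.random((8, 8)) > 0.6).astype(float)
        b = (rng.random((8, 8)) > 0.6).astype(float)
        loss = dice_loss(a, b)
        assert 0.0 <= loss <= 1.0
        assert loss == pytest.approx(dice_loss(b, a), abs=1e-12)

    def test_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(0)
        p = rng.random((5, 5))
        g = (rng.random((5, 5)) > 0.5).astype(float)
        grad = dice_loss_grad(p, g)
        eps = 1e-6
        for idx in [(0, 0), (2, 3), (4, 4)]:
            pp = p.copy()
            pp[idx] += eps
            pm = p.copy()
            pm[idx] -= eps
            num = (dice_loss(pp, g) - dice_loss(pm, g)) / (2 * eps)
            assert grad[idx] == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestArchitecture:
    def test_output_shape_and_sigmoid_range(self):
        net = DoubleUNet(3, depth=3, base_filters=16, seed=0)
        x = np.random.default_rng(0).random((2, 64, 64, 3)).astype(np.float32)
        p = net.forward(x, train=False)
        assert p.shape == (2, 64, 64, 1)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_indivisible_input_rejected(self):
        net = DoubleUNet(3, depth=3, base_filters=8, seed=0)
        with pytest.raises(ValueError, match="divisible"):
            net.forward(np.zeros((1, 60, 60, 3), np.float32))

    def test_same_seed_same_initial_weights(self):
        a = DoubleUNet(3, depth=2, base_filters=8, seed=42)
        b = DoubleUNet(3, depth=2, base_filters=8, seed=42)
        for sa, sb in zip(a.state_arrays().values(), b.state_arrays().values()):
            assert np.array_equal(sa, sb)
        c = DoubleUNet(3, depth=2, base_filters=8, seed=43)
        assert any(
            not np.array_equal(x, y)
            for x, y in zip(a.state_arrays().values(), c.state_arrays().values())
        )

    def test_bridge_options(self):
        x = np.random.default_rng(1).random((1, 16, 16, 3)).astype(np.float32)
        for bridge in ("multiply", "concat"):
            net = DoubleUNet(3, depth=2, base_filters=4, bridge=bridge, seed=1)
            assert net.forward(x, train=False).shape == (1, 16, 16, 1)
        with pytest.raises(ValueError):
            DoubleUNet(3, bridge="add")


def test_backprop_matches_finite_differences_float64():
    """End-to-end analytic gradients agree with central differences.

    Run in float64 (the engine's compute dtype is switchable at module
    level) so finite differences are not drowned by rounding noise.
    """
    saved = nn_layers._F32, nn_network._F32
    nn_layers._F32 = nn_network._F32 = np.float64
    try:
        net = DoubleUNet(3, depth=2, base_filters=4, seed=1)
        rng = np.random.default_rng(0)
        x = rng.random((2, 8, 8, 3))
        g = (rng.random((2, 8, 8, 1)) > 0.7).astype(float)
        p = net.forward(x, train=True)
        net.backward(dice_loss_grad(p, g))
        layers = [lay for lay in net.layers() if lay.params]
        checked = 0
        for li in [0, 3, len(layers) // 2, len(layers) - 1]:
            lay = layers[li]
            grads = {k: v.copy() for k, v in lay.grads.items()}
            for key in lay.params:
                flat = lay.params[key].ravel()
                for idx in (0, flat.size // 2):
                    eps = 1e-6
                    orig = flat[idx]
                    flat[idx] = orig + eps
                    lp = dice_loss(net.forward(x, train=True), g)
                    flat[idx] = orig - eps
                    lm = dice_loss(net.forward(x, train=True), g)
                    flat[idx] = orig
                    num = (lp - lm) / (2 * eps)
                    ana = grads[key].ravel()[idx]
                    assert ana == pytest.approx(num, rel=5e-3, abs=1e-7)
                    checked += 1
        assert checked >= 12
    finally:
        nn_layers._F32, nn_network._F32 = saved
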
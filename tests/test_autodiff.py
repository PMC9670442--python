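"""Finite-difference verification of the autodiff primitives.

Every structured primitive the network uses (grouped/strided/padded conv,
max pooling, fused batch norm, the pointwise nonlinearities) is checked
against a central-difference numerical gradient in float64.
"""

import numpy as np
import pytest

from cardiov.nn import (
    Tensor,
    batch_norm_train,
    conv1d,
    max_pool1d,
    relu,
    sigmoid,
    softplus,
    swish,
)


def numerical_grad(f, arrays, wrt, eps=1e-6):
    base = arrays[wrt]
    g = np.zeros_like(base)
    for idx in np.ndindex(base.shape):
        plus = [a.copy() for a in arrays]
        minus = [a.copy() for a in arrays]
        plus[wrt][idx] += eps
        minus[wrt][idx] -= eps
        g[idx] = (f(plus) - f(minus)) / (2 * eps)
    return g


def assert_grads_match(build, arrays, tol=1e-6):
    """build maps a list of Tensors to a scalar Tensor."""
    tensors = [Tensor(a.copy(), requires_grad=True) for a in arrays]
    build(tensors).backward()

    def value(arrs):
        return float(build([Tensor(a) for a in arrs]).data)

    for w, t in enumerate(tensors):
        num = numerical_grad(value, [a.copy() for a in arrays], w)
        assert np.abs(t.grad - num).max() < tol, f"arg {w} gradient mismatch"


@pytest.fixture(scope="module")
def arrays():
    r = np.random.default_rng(7)
    return {
        "x": r.normal(size=(2, 4, 20)),
        "w_grouped": r.normal(size=(6, 2, 5)),
        "w_full": r.normal(size=(6, 4, 5)),
        "w_point": r.normal(size=(5, 4, 1)),
        "weight2d": r.normal(size=(2, 4, 20)),
        "small": r.normal(size=(3, 5)),
    }


class TestConv:
    def test_grouped_strided_padded(self, arrays):
        assert_grads_match(
            lambda t: conv1d(t[0], t[1], stride=2, pad_left=2, pad_right=1,
                             groups=2).sum(),
            [arrays["x"], arrays["w_grouped"]])

    def test_dense_stride1(self, arrays):
        assert_grads_match(
            lambda t: (conv1d(t[0], t[1], pad_left=2, pad_right=2) ** 2.0).sum(),
            [arrays["x"], arrays["w_full"]])

    def test_pointwise_fast_path(self, arrays):
        assert_grads_match(
            lambda t: (conv1d(t[0], t[1]) ** 2.0).sum(),
            [arrays["x"], arrays["w_point"]])

    def test_output_matches_naive_correlation(self, arrays):
        x, w = arrays["x"], arrays["w_full"]
        out = conv1d(Tensor(x), Tensor(w), stride=2, pad_left=1,
                     pad_right=2).data
        xp = np.pad(x, ((0, 0), (0, 0), (1, 2)))
        n, cout, lout = out.shape
        naive = np.zeros_like(out)
        for o in range(cout):
            for l in range(lout):
                naive[:, o, l] = (xp[:, :, 2 * l:2 * l + 5] * w[o]).sum((1, 2))
        assert np.allclose(out, naive, atol=1e-12)

    def test_incompatible_groups_rejected(self, arrays):
        with pytest.raises(ValueError):
            conv1d(Tensor(arrays["x"]), Tensor(arrays["w_full"]), groups=3)


class TestPoolingAndNorm:
    def test_max_pool_gradient(self, arrays):
        wgt = arrays["weight2d"][:, :, :10]
        assert_grads_match(lambda t: (max_pool1d(t[0]) * wgt).sum(),
                           [arrays["x"]])

    def test_max_pool_drops_trailing_odd_sample(self, arrays):
        out = max_pool1d(Tensor(arrays["x"][:, :, :9])).data
        assert out.shape == (2, 4, 4)

    def test_batch_norm_gradients(self, arrays):
        wgt = arrays["weight2d"]

        def build(t):
            out, _, _ = batch_norm_train(t[0], t[1], t[2])
            return (out * wgt).sum()

        gamma = np.random.default_rng(3).normal(size=4) + 1.0
        beta = np.random.default_rng(4).normal(size=4)
        assert_grads_match(build, [arrays["x"], gamma, beta], tol=5e-6)

    def test_batch_norm_standardizes(self, arrays):
        out, mu, var = batch_norm_train(Tensor(arrays["x"]),
                                        Tensor(np.ones(4)),
                                        Tensor(np.zeros(4)))
        assert np.allclose(out.data.mean(axis=(0, 2)), 0.0, atol=1e-10)
        assert np.allclose(out.data.std(axis=(0, 2)), 1.0, atol=1e-3)
        assert mu.shape == var.shape == (4,)


class TestPointwise:
    @pytest.mark.parametrize("op", [sigmoid, softplus, swish, relu])
    def test_gradients(self, op, arrays):
        wgt = np.random.default_rng(11).normal(size=(3, 5))
        assert_grads_match(lambda t: (op(t[0]) * wgt).sum(),
                           [arrays["small"] * 2.0])

    def test_swish_values(self):
        x = np.array([-50.0, 0.0, 50.0])
        out = swish(Tensor(x)).data
        assert out[1] == 0.0
        assert out[2] == pytest.approx(50.0)
        assert abs(out[0]) < 1e-10


class TestTensorAlgebra:
    def test_broadcast_add_mul(self):
        a = np.random.default_rng(0).normal(size=(3, 4))
        b = np.random.default_rng(1).normal(size=(4,))
        assert_grads_match(lambda t: ((t[0] + t[1]) * t[1]).sum(), [a, b])

    def test_matmul_mean_getitem(self):
        a = np.random.default_rng(2).normal(size=(3, 4))
        b = np.random.default_rng(3).normal(size=(4, 2))
        assert_grads_match(
            lambda t: (t[0] @ t[1]).mean() + t[0][np.array([0, 2]),
                                                  np.array([1, 1])].sum(),
            [a, b])

    def test_gradient_accumulates_across_reuse(self):
        x = Tensor(np.array([2.0]), requires_grad=True)
        (x * x + x).backward()   # d/dx (x^2 + x) = 2x + 1
        assert x.grad[0] == pytest.approx(5.0)

    def test_backward_requires_scalar(self):
        x = Tensor(np.ones(3), requires_grad=True)
        with pytest.raises(ValueError):
            (x * 2).backward()
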
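"""Unit tests for the autodiff ops: forward values against scalar-loop
oracles, gradients against central finite differences, and the exact
inverse/bijection properties of the resampling ops."""

import numpy as np
import pytest

from coralseg.nn import Tensor, ops
from coralseg.nn.autograd import Parameter

from conftest import numeric_grad, ref_conv2d


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kernel,stride,pad,dilation", [
    (1, 1, 0, 1),
    (3, 1, 1, 1),
    (3, 2, 1, 1),
    (7, 2, 3, 1),
    (3, 1, 6, 6),
    (3, 1, 12, 12),
])
def test_conv2d_matches_scalar_loop_oracle(rng, kernel, stride, pad, dilation):
    x = rng.normal(size=(2, 3, 13, 11))
    w = rng.normal(size=(4, 3, kernel, kernel))
    b = rng.normal(size=4)
    out = ops.conv2d(Tensor(x), Tensor(w), Tensor(b), stride=stride, pad=pad,
                     dilation=dilation)
    ref = ref_conv2d(x, w, b, stride=stride, pad=pad, dilation=dilation)
    np.testing.assert_allclose(out.data, ref, atol=1e-10)


def test_conv2d_rejects_channel_mismatch(rng):
    with pytest.raises(ValueError, match="channels"):
        ops.conv2d(Tensor(rng.normal(size=(1, 2, 4, 4))),
                   Tensor(rng.normal(size=(3, 5, 3, 3))))


@pytest.mark.parametrize("wrt", ["x", "w", "b"])
def test_conv2d_gradients_match_finite_differences(rng, wrt):
    x0 = rng.normal(size=(2, 2, 6, 6))
    w0 = rng.normal(size=(3, 2, 3, 3))
    b0 = rng.normal(size=3)
    co = rng.normal(size=(2, 3, 3, 3))  # random cotangent -> scalar loss

    def run(x, w, b):
        return float((ops.conv2d(Tensor(x), Tensor(w), Tensor(b), stride=2,
                                 pad=1).data * co).sum())

    xt, wt, bt = Parameter(x0), Parameter(w0), Parameter(b0)
    out = ops.conv2d(xt, wt, bt, stride=2, pad=1)
    out.backward(co)
    analytic = {"x": xt.grad, "w": wt.grad, "b": bt.grad}[wrt]
    target = {"x": x0, "w": w0, "b": b0}[wrt]
    numeric = numeric_grad(
        lambda v: run(v if wrt == "x" else x0,
                      v if wrt == "w" else w0,
                      v if wrt == "b" else b0), target)
    np.testing.assert_allclose(analytic, numeric, atol=1e-6)


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def test_max_pool_matches_brute_force(rng):
    x = rng.normal(size=(2, 3, 9, 9))
    out = ops.max_pool2d(Tensor(x), 3, 2, 1)
    n, c, h, w = x.shape
    expect = np.empty((n, c, 5, 5))
    xp = np.full((n, c, h + 2, w + 2), -np.inf)
    xp[:, :, 1:-1, 1:-1] = x
    for oh in range(5):
        for ow in range(5):
            expect[:, :, oh, ow] = xp[:, :, 2 * oh:2 * oh + 3,
                                      2 * ow:2 * ow + 3].max(axis=(2, 3))
    np.testing.assert_array_equal(out.data, expect)


def test_max_pool_gradient_routes_to_argmax(rng):
    x0 = rng.normal(size=(1, 2, 6, 6))
    co = rng.normal(size=(1, 2, 3, 3))
    xt = Parameter(x0)
    ops.max_pool2d(xt, 3, 2, 1).backward(co)
    numeric = numeric_grad(
        lambda v: float((ops.max_pool2d(Tensor(v), 3, 2, 1).data * co).sum()),
        x0)
    np.testing.assert_allclose(xt.grad, numeric, atol=1e-6)


def test_global_avg_pool_mean_and_gradient(rng):
    x0 = rng.normal(size=(2, 3, 4, 5))
    xt = Parameter(x0)
    out = ops.global_avg_pool(xt)
    np.testing.assert_allclose(out.data[..., 0, 0], x0.mean(axis=(2, 3)))
    out.backward(np.ones_like(out.data))
    np.testing.assert_allclose(xt.grad, np.full_like(x0, 1 / 20))


# ---------------------------------------------------------------------------
# batch normalisation
# ---------------------------------------------------------------------------

def test_batch_norm_normalises_and_matches_finite_differences(rng):
    x0 = rng.normal(2.0, 3.0, size=(4, 3, 5, 5))
    gamma0, beta0 = rng.normal(size=3), rng.normal(size=3)
    rm, rv = np.zeros(3), np.ones(3)
    xt, gt, bt = Parameter(x0), Parameter(gamma0), Parameter(beta0)
    out = ops.batch_norm2d(xt, gt, bt, rm.copy(), rv.copy(), training=True)
    # normalised activations have per-channel mean beta, std |gamma|
    np.testing.assert_allclose(out.data.mean(axis=(0, 2, 3)), beta0, atol=1e-6)
    co = rng.normal(size=out.data.shape)
    out.backward(co)

    def run(x, g, b):
        return float((ops.batch_norm2d(Tensor(x), Tensor(g), Tensor(b),
                                       np.zeros(3), np.ones(3),
                                       training=True).data * co).sum())

    for analytic, target, name in ((xt.grad, x0, "x"), (gt.grad, gamma0, "g"),
                                   (bt.grad, beta0, "b")):
        numeric = numeric_grad(
            lambda v, name=name: run(v if name == "x" else x0,
                                     v if name == "g" else gamma0,
                                     v if name == "b" else beta0), target)
        np.testing.assert_allclose(analytic, numeric, atol=1e-5,
                                   err_msg=f"grad wrt {name}")


def test_batch_norm_eval_uses_running_stats(rng):
    x = rng.normal(size=(2, 2, 3, 3))
    rm = np.array([1.0, -1.0])
    rv = np.array([4.0, 0.25])
    out = ops.batch_norm2d(Tensor(x), Tensor(np.ones(2)), Tensor(np.zeros(2)),
                           rm, rv, training=False, eps=0.0)
    expect = (x - rm[:, None, None]) / np.sqrt(rv)[:, None, None]
    np.testing.assert_allclose(out.data, expect, atol=1e-12)


# ---------------------------------------------------------------------------
# resampling: space-to-depth / depth-to-space
# ---------------------------------------------------------------------------

def test_s2d_d2s_inverse_pair_on_many_random_shapes():
    rng = np.random.default_rng(7)
    for _ in range(200):
        r = int(rng.integers(1, 5))
        c = int(rng.integers(1, 6))
        h = r * int(rng.integers(1, 7))
        w = r * int(rng.integers(1, 7))
        x = rng.normal(size=(1, c, h, w))
        down = ops.space_to_depth(Tensor(x), r)
        assert down.shape == (1, c * r * r, h // r, w // r)
        # volume conserved and values are a permutation of the input
        assert down.data.size == x.size
        np.testing.assert_array_equal(np.sort(down.data.ravel()),
                                      np.sort(x.ravel()))
        back = ops.depth_to_space(down, r)
        np.testing.assert_array_equal(back.data, x)


def test_s2d_block_order_convention():
    # channel c, block offset (i, j) -> output channel c*r*r + i*r + j
    x = np.arange(16, dtype=float).reshape(1, 1, 4, 4)
    out = ops.space_to_depth(Tensor(x), 2).data
    np.testing.assert_array_equal(out[0, 0], [[0, 2], [8, 10]])   # offset (0,0)
    np.testing.assert_array_equal(out[0, 1], [[1, 3], [9, 11]])   # offset (0,1)
    np.testing.assert_array_equal(out[0, 2], [[4, 6], [12, 14]])  # offset (1,0)
    np.testing.assert_array_equal(out[0, 3], [[5, 7], [13, 15]])  # offset (1,1)


def test_s2d_d2s_identity_at_r1_and_shape_errors(rng):
    x = rng.normal(size=(1, 3, 4, 4))
    np.testing.assert_array_equal(ops.space_to_depth(Tensor(x), 1).data, x)
    np.testing.assert_array_equal(ops.depth_to_space(Tensor(x), 1).data, x)
    with pytest.raises(ValueError, match="divisible"):
        ops.space_to_depth(Tensor(rng.normal(size=(1, 1, 5, 4))), 2)
    with pytest.raises(ValueError, match="divisible"):
        ops.depth_to_space(Tensor(rng.normal(size=(1, 3, 4, 4))), 2)


def test_s2d_d2s_gradients_are_the_inverse_rearrangement(rng):
    x0 = rng.normal(size=(1, 2, 4, 4))
    xt = Parameter(x0)
    co = rng.normal(size=(1, 8, 2, 2))
    ops.space_to_depth(xt, 2).backward(co)
    np.testing.assert_array_equal(xt.grad,
                                  ops.depth_to_space(Tensor(co), 2).data)


# ---------------------------------------------------------------------------
# bilinear resize
# ---------------------------------------------------------------------------

def test_bilinear_resize_preserves_constants_and_broadcasts_1x1(rng):
    c = ops.bilinear_resize(Tensor(np.full((1, 2, 4, 4), 3.5)), 9, 7)
    np.testing.assert_allclose(c.data, 3.5)
    v = rng.normal(size=(1, 3, 1, 1))
    up = ops.bilinear_resize(Tensor(v), 5, 5)
    np.testing.assert_allclose(up.data, np.broadcast_to(v, (1, 3, 5, 5)))


def test_bilinear_resize_known_values_and_adjoint(rng):
    # doubling [[0, 1], [2, 3]] with half-pixel centres
    x = np.array([[[[0.0, 1.0], [2.0, 3.0]]]])
    out = ops.bilinear_resize(Tensor(x), 4, 4).data[0, 0]
    np.testing.assert_allclose(out[0], [0.0, 0.25, 0.75, 1.0])
    np.testing.assert_allclose(out[:, 0], [0.0, 0.5, 1.5, 2.0])
    x0 = rng.normal(size=(1, 2, 3, 5))
    xt = Parameter(x0)
    co = rng.normal(size=(1, 2, 6, 10))
    ops.bilinear_resize(xt, 6, 10).backward(co)
    numeric = numeric_grad(
        lambda v: float((ops.bilinear_resize(Tensor(v), 6, 10).data * co).sum()),
        x0)
    np.testing.assert_allclose(xt.grad, numeric, atol=1e-6)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def test_cross_entropy_gradient_matches_finite_differences(rng):
    logits0 = rng.normal(size=(1, 2, 2, 2))
    labels = rng.integers(0, 2, size=(1, 2, 2))
    lt = Parameter(logits0)
    ops.softmax_cross_entropy(lt, labels).backward()
    numeric = numeric_grad(
        lambda v: float(ops.softmax_cross_entropy(Tensor(v), labels).data),
        logits0)
    np.testing.assert_allclose(lt.grad, numeric, atol=1e-4)


def test_linear_and_relu_gradients(rng):
    x0 = rng.normal(size=(3, 4))
    w0 = rng.normal(size=(2, 4))
    b0 = rng.normal(size=2)
    xt, wt, bt = Parameter(x0), Parameter(w0), Parameter(b0)
    out = ops.relu(ops.linear(xt, wt, bt))
    co = rng.normal(size=(3, 2))
    out.backward(co)
    numeric = numeric_grad(
        lambda v: float((np.maximum(v @ w0.T + b0, 0) * co).sum()), x0)
    np.testing.assert_allclose(xt.grad, numeric, atol=1e-6)
    numeric_w = numeric_grad(
        lambda v: float((np.maximum(x0 @ v.T + b0, 0) * co).sum()), w0)
    np.testing.assert_allclose(wt.grad, numeric_w, atol=1e-6)
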
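"""Numerical gradient checks and behavioral tests for the autodiff core.

Every custom-backward operation is checked against central finite
differences in float64 on small random instances; shape and mode
semantics (train/eval batch norm, pooling ties, resize geometry) get
targeted assertions.
"""

import numpy as np
import pytest

from odseg import nn
from odseg.nn import functional as F
from odseg.nn.tensor import Tensor


RNG = np.random.default_rng(20260928)


def numeric_grad(fn, arrays, wrt, eps=1e-6):
    """Central-difference gradient of scalar fn(*arrays) w.r.t. arrays[wrt]."""
    base = arrays[wrt]
    g = np.zeros_like(base)
    it = np.nditer(base, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = base[idx]
        base[idx] = orig + eps
        hi = fn(*arrays)
        base[idx] = orig - eps
        lo = fn(*arrays)
        base[idx] = orig
        g[idx] = (hi - lo) / (2 * eps)
    return g


def check_op(build, arrays, tol=1e-6):
    """build(*tensors) -> Tensor; compares autodiff grads to numeric ones."""
    tensors = [Tensor(a, requires_grad=True) for a in arrays]
    out = build(*tensors)
    w = RNG.standard_normal(out.shape)  # random cotangent
    (out * Tensor(w)).sum().backward()

    def scalar(*arrs):
        return float((build(*[Tensor(a) for a in arrs]).data * w).sum())

    for i, t in enumerate(tensors):
        num = numeric_grad(scalar, [a.copy() for a in arrays], i)
        assert np.allclose(t.grad, num, atol=tol), f"arg {i}: max err {np.abs(t.grad - num).max()}"


@pytest.mark.parametrize(
    "build,shapes",
    [
        (lambda a, b: a + b, [(3, 4), (3, 4)]),
        (lambda a, b: a * b, [(3, 4), (1, 4)]),  # broadcast
        (lambda a, b: a / (b * b + 1.0), [(2, 3), (2, 3)]),
        (lambda a, b: a @ b, [(4, 3), (3, 5)]),
        (lambda a, b: a @ b, [(2, 4, 3), (2, 3, 5)]),  # batched matmul
        (lambda a: a.relu(), [(5, 5)]),
        (lambda a: a.sigmoid(), [(5, 5)]),
        (lambda a: (a * a + 1.0).log(), [(4, 4)]),
        (lambda a: (a * a + 0.5).sqrt(), [(4, 4)]),
        (lambda a: a.softmax(axis=-1), [(3, 7)]),
        (lambda a: a.reshape(2, 6).transpose(1, 0), [(3, 4)]),
        (lambda a: a.sum(axis=1), [(3, 4)]),
        (lambda a: a.mean(), [(3, 4)]),
    ],
)
def test_elementwise_and_linear_grads(build, shapes):
    arrays = [RNG.standard_normal(s) for s in shapes]
    check_op(build, arrays)


@pytest.mark.parametrize("stride,padding,k", [(1, 0, 1), (1, 1, 3), (2, 1, 3), (2, 3, 7)])
def test_conv2d_grads(stride, padding, k):
    x = RNG.standard_normal((2, 3, 8, 8))
    w = RNG.standard_normal((4, 3, k, k)) * 0.5
    b = RNG.standard_normal(4)
    check_op(lambda x, w, b: F.conv2d(x, w, b, stride, padding), [x, w, b], tol=1e-5)


def test_conv2d_matches_scipy_correlation():
    from scipy.signal import correlate2d

    x = RNG.standard_normal((1, 2, 9, 9))
    w = RNG.standard_normal((3, 2, 3, 3))
    y = F.conv2d(Tensor(x), Tensor(w), None, stride=1, padding=1).data
    for co in range(3):
        ref = sum(
            correlate2d(x[0, ci], w[co, ci], mode="same") for ci in range(2)
        )
        assert np.allclose(y[0, co], ref, atol=1e-10)


def test_conv_transpose_grads_and_shape():
    x = RNG.standard_normal((2, 3, 5, 5))
    w = RNG.standard_normal((3, 4, 3, 3)) * 0.5
    b = RNG.standard_normal(4)
    out = F.conv_transpose2d(Tensor(x), Tensor(w), Tensor(b))
    assert out.shape == (2, 4, 10, 10)  # stride-2 deconv doubles H and W
    check_op(lambda x, w, b: F.conv_transpose2d(x, w, b), [x, w, b], tol=1e-5)


def test_conv_transpose_adjoint_of_conv():
    """<conv(x), y> == <x, conv_transpose(y)> when weights are shared."""
    x = RNG.standard_normal((1, 3, 8, 8))
    w = RNG.standard_normal((5, 3, 3, 3))
    y = RNG.standard_normal((1, 5, 4, 4))
    cx = F.conv2d(Tensor(x), Tensor(w), None, stride=2, padding=1).data
    # transposed conv with the (Cin,Cout) axes of w swapped is conv's adjoint
    wt = np.ascontiguousarray(w)  # (Cout=5, Cin=3, 3, 3) -> interpret as (Cin', Cout')
    ty = F.conv_transpose2d(Tensor(y), Tensor(wt), None, stride=2, padding=1,
                            output_padding=1).data
    assert np.isclose((cx * y).sum(), (x * ty).sum(), rtol=1e-10)


@pytest.mark.parametrize("k,s,p", [(2, 2, 0), (3, 2, 1), (4, 4, 0)])
def test_max_pool_grads(k, s, p):
    # continuous random values: ties have measure zero, finite differences valid
    x = RNG.standard_normal((2, 3, 8, 8))
    check_op(lambda x: F.max_pool2d(x, k, s, p), [x], tol=1e-5)


def test_bilinear_resize_exact_on_linear_ramp():
    """Bilinear interpolation reproduces an affine function exactly (interior)."""
    h = np.arange(8, dtype=np.float64)
    x = (h[:, None] + 2.0 * h[None, :])[None, None]
    y = F.bilinear_resize(Tensor(x), (16, 16)).data[0, 0]
    rows = (np.arange(16) + 0.5) * 0.5 - 0.5
    expected = rows[:, None] + 2.0 * rows[None, :]
    interior = np.s_[2:-2, 2:-2]
    assert np.allclose(y[interior], expected[interior], atol=1e-12)


def test_bilinear_resize_grads():
    x = RNG.standard_normal((2, 3, 4, 6))
    check_op(lambda x: F.bilinear_resize(x, (7, 9)), [x], tol=1e-6)


def test_batch_norm_train_grads_and_stats():
    x = RNG.standard_normal((4, 3, 5, 5)) * 2 + 1
    gamma = RNG.standard_normal(3)
    beta = RNG.standard_normal(3)

    def build(x, gamma, beta):
        return F.batch_norm2d(x, gamma, beta, np.zeros(3), np.ones(3), training=True)

    check_op(build, [x, gamma, beta], tol=1e-5)
    # normalized output has ~zero mean / unit variance per channel (gamma=1, beta=0)
    out = F.batch_norm2d(Tensor(x), Tensor(np.ones(3)), Tensor(np.zeros(3)),
                         np.zeros(3), np.ones(3), training=True)
    assert np.allclose(out.data.mean(axis=(0, 2, 3)), 0.0, atol=1e-10)
    assert np.allclose(out.data.var(axis=(0, 2, 3)), 1.0, atol=1e-6)


def test_batch_norm_eval_uses_running_stats():
    x = RNG.standard_normal((2, 3, 4, 4))
    rm, rv = np.array([1.0, 2.0, 3.0]), np.array([4.0, 1.0, 0.25])
    out = F.batch_norm2d(Tensor(x), Tensor(np.ones(3)), Tensor(np.zeros(3)),
                         rm.copy(), rv.copy(), training=False)
    expected = (x - rm[None, :, None, None]) / np.sqrt(rv + 1e-5)[None, :, None, None]
    assert np.allclose(out.data, expected, atol=1e-7)


def test_module_state_dict_roundtrip():
    nn.manual_seed(3)
    m = nn.Sequential(nn.Conv2d(3, 4, 3, padding=1), nn.BatchNorm2d(4), nn.ReLU(),
                      nn.Conv2d(4, 2, 1))
    sd = m.state_dict()
    nn.manual_seed(99)
    m2 = nn.Sequential(nn.Conv2d(3, 4, 3, padding=1), nn.BatchNorm2d(4), nn.ReLU(),
                       nn.Conv2d(4, 2, 1))
    x = RNG.standard_normal((1, 3, 6, 6))
    assert not np.allclose(m.eval()(Tensor(x)).data, m2.eval()(Tensor(x)).data)
    m2.load_state_dict(sd)
    assert np.allclose(m(Tensor(x)).data, m2(Tensor(x)).data)


def test_adam_minimizes_quadratic():
    w = nn.Parameter(np.array([5.0, -3.0], dtype=np.float32))
    opt = nn.Adam([w], lr=0.1)
    for _ in range(300):
        opt.zero_grad()
        loss = (w * w).sum()
        loss.backward()
        opt.step()
    assert np.abs(w.data).max() < 1e-3


def test_weight_decay_shrinks_stationary_weights():
    w = nn.Parameter(np.array([1.0], dtype=np.float32))
    opt = nn.Adam([w], lr=0.01, weight_decay=0.1)
    for _ in range(50):
        opt.zero_grad()
        (w * 0.0).sum().backward()  # zero data gradient
        opt.step()
    assert w.data[0] < 1.0
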
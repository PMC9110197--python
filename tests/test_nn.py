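"""Gradient and contract checks for the numpy network engine.

Every primitive's hand-written backward is validated against central
finite differences on small random inputs.
"""

import numpy as np
import pytest

from apunet import nn
from apunet.nn import Tensor
from apunet.nn.tensor import _col2im, _im2col


def numeric_grad(fn, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central finite-difference gradient of a scalar-valued fn."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        hi = fn()
        x[idx] = orig - eps
        lo = fn()
        x[idx] = orig
        g[idx] = (hi - lo) / (2 * eps)
        it.iternext()
    return g


def check_grad(op, shapes, seed=0, atol=1e-5, **kwargs):
    """Compare analytic and numeric gradients of sum(op(*inputs))."""
    rng = np.random.default_rng(seed)
    tensors = [Tensor(rng.normal(size=s), requires_grad=True) for s in shapes]

    out = op(*tensors, **kwargs)
    out.backward()
    for t in tensors:
        num = numeric_grad(lambda: op(*[Tensor(u.data) for u in tensors],
                                      **kwargs).data.sum(), t.data)
        np.testing.assert_allclose(t.grad, num, atol=atol,
                                   err_msg=f"gradient mismatch for shape {t.shape}")


class TestPrimitiveGradients:
    def test_elementwise_and_reductions(self):
        check_grad(lambda a, b: a * b + a, [(2, 3, 4, 4), (2, 3, 4, 4)])
        check_grad(nn.sigmoid, [(2, 3, 4, 4)])
        check_grad(nn.relu, [(2, 3, 4, 4)], seed=3)
        check_grad(lambda a, b: nn.concat([a, b], axis=1),
                   [(1, 2, 3, 3), (1, 4, 3, 3)])
        check_grad(nn.global_avg_pool2d, [(2, 3, 4, 4)])
        check_grad(nn.global_max_pool2d, [(2, 3, 4, 4)])
        check_grad(nn.channel_mean, [(2, 3, 4, 4)])
        check_grad(nn.channel_max, [(2, 3, 4, 4)])

    def test_broadcast_mul_gate_shapes(self):
        # (N,1,H,W) spatial gate and (N,C,1,1) channel gate against (N,C,H,W)
        check_grad(lambda x, g: x * g, [(2, 3, 4, 4), (2, 1, 4, 4)])
        check_grad(lambda x, g: x * g, [(2, 3, 4, 4), (2, 3, 1, 1)])

    @pytest.mark.parametrize("stride,padding,kernel", [(1, 1, 3), (1, 0, 1), (2, 1, 3)])
    def test_conv2d(self, stride, padding, kernel):
        check_grad(lambda x, w, b: nn.conv2d(x, w, b, stride, padding),
                   [(2, 3, 6, 6), (4, 3, kernel, kernel), (4,)])

    @pytest.mark.parametrize("output_padding", [0, 1])
    def test_conv_transpose2d(self, output_padding):
        check_grad(lambda x, w, b: nn.conv_transpose2d(x, w, b, 2, output_padding),
                   [(2, 3, 3, 3), (3, 4, 2, 2), (4,)])

    def test_max_pool_and_resize(self):
        check_grad(nn.max_pool2d, [(2, 3, 5, 5)])
        check_grad(lambda x: nn.bilinear_resize(x, 7), [(2, 3, 4, 4)])
        check_grad(lambda x: nn.bilinear_resize(x, 3), [(1, 2, 5, 5)])

    def test_linear(self):
        check_grad(lambda x, w, b: nn.linear(x, w, b), [(4, 5), (3, 5), (3,)])

    @pytest.mark.parametrize("training", [True, False])
    def test_batch_norm(self, training):
        rm = np.array([0.1, -0.2, 0.05])
        rv = np.array([1.2, 0.8, 1.0])
        check_grad(lambda x, g, b: nn.batch_norm2d(
            x, g, b, rm.copy(), rv.copy(), training), [(3, 3, 4, 4), (3,), (3,)],
            atol=3e-5)

    def test_cross_entropy(self):
        rng = np.random.default_rng(0)
        target = rng.integers(0, 2, size=(2, 4, 4))
        check_grad(lambda z: nn.cross_entropy_with_logits(z, target),
                   [(2, 2, 4, 4)])


class TestOpSemantics:
    def test_im2col_col2im_adjoint(self):
        """<im2col(x), y> == <x, col2im(y)> for random x, y (adjoint pair)."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=(2, 3, 6, 6))
        cols, ho, wo = _im2col(x, 3, 3, 1, 1)
        y = rng.normal(size=cols.shape)
        lhs = np.sum(cols * y)
        rhs = np.sum(x * _col2im(y, x.shape, 3, 3, 1, 1))
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_max_pool_floor_sizes(self):
        x = Tensor(np.zeros((1, 1, 50, 50)))
        sizes = []
        for _ in range(4):
            x = nn.max_pool2d(x)
            sizes.append(x.shape[2])
        assert sizes == [25, 12, 6, 3]

    def test_conv_transpose_output_padding_sizes(self):
        """The decoder ladder 3->6->12->25->50 is exactly recovered."""
        rng = np.random.default_rng(0)
        w = Tensor(rng.normal(size=(1, 1, 2, 2)))
        x = Tensor(rng.normal(size=(1, 1, 3, 3)))
        for target in (6, 12, 25, 50):
            opad = target - 2 * x.shape[2]
            x = nn.conv_transpose2d(x, w, None, 2, opad)
            assert x.shape[2] == target

    def test_bilinear_resize_constant_preserved(self):
        x = Tensor(np.full((1, 2, 6, 6), 3.5))
        out = nn.bilinear_resize(x, 50)
        np.testing.assert_allclose(out.data, 3.5)

    def test_batch_norm_running_stats_converge(self):
        """Repeated identical batches drive the running stats to the batch's."""
        bn = nn.BatchNorm2d(2)
        rng = np.random.default_rng(0)
        x = rng.normal(1.0, 2.0, size=(4, 2, 5, 5))
        for _ in range(300):
            bn(Tensor(x))
        np.testing.assert_allclose(bn.running_mean, x.mean(axis=(0, 2, 3)),
                                   rtol=1e-3)

    def test_cross_entropy_closed_forms(self):
        target = np.zeros((1, 2, 2), dtype=int)
        # perfect confidence on the correct class: loss ~ 0
        perfect = np.zeros((1, 2, 2, 2))
        perfect[:, 0] = 50.0
        assert nn.cross_entropy_with_logits(Tensor(perfect), target).data < 1e-12
        # uniform logits with 2 classes: loss = ln 2 per pixel
        uniform = np.zeros((1, 2, 2, 2))
        assert nn.cross_entropy_with_logits(Tensor(uniform), target).data == \
            pytest.approx(np.log(2.0))

    def test_dropout_identity_eval_and_determinism(self):
        rng = np.random.default_rng(0)
        x = Tensor(rng.normal(size=(2, 3, 4, 4)))
        drop = nn.Dropout(0.5, seed=7)
        drop.eval()
        np.testing.assert_array_equal(drop(x).data, x.data)
        drop.train()
        drop.reseed(7)
        a = drop(x).data.copy()
        drop.reseed(7)
        b = drop(x).data.copy()
        np.testing.assert_array_equal(a, b)

    def test_adam_descends_quadratic(self):
        p = nn.Parameter(np.array([5.0, -3.0]))
        opt = nn.Adam([p], lr=0.1)
        for _ in range(300):
            lossval = (p * p).data.sum()
            opt.zero_grad()
            (p * p).backward()
            opt.step()
        assert np.abs(p.data).max() < 1e-2

    def test_module_state_dict_roundtrip(self):
        rng = np.random.default_rng(0)
        m = nn.Sequential(nn.Conv2d(1, 3, 3, rng), nn.BatchNorm2d(3), nn.ReLU())
        m(Tensor(rng.normal(size=(2, 1, 5, 5))))  # move running stats
        state = m.state_dict()
        m2 = nn.Sequential(nn.Conv2d(1, 3, 3, np.random.default_rng(9)),
                           nn.BatchNorm2d(3), nn.ReLU())
        m2.load_state_dict(state)
        m.eval(), m2.eval()
        x = Tensor(rng.normal(size=(1, 1, 5, 5)))
        np.testing.assert_array_equal(m(x).data, m2(x).data)
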
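"""Autodiff engine and denoiser network: gradient checks, contracts, ablation."""

import numpy as np
import pytest

from residiff.nn import autodiff as ad
from residiff.nn.autodiff import Tensor
from residiff.nn.layers import SwinBlock
from residiff.nn.optim import Adam, RAdam
from residiff.nn.unet import (
    TINY,
    DenoiserConfig,
    DenoiserConfigError,
    UNetDenoiser,
    build_denoiser,
    timestep_embedding,
)


def numerical_grad(fn, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar-valued function."""
    g = np.zeros_like(x)
    flat = x.ravel()
    gf = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = fn(x)
        flat[i] = orig - eps
        lo = fn(x)
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * eps)
    return g


def check_gradient(build, x: np.ndarray, atol=1e-6, rtol=1e-4):
    """Compare autodiff gradient of sum(build(Tensor)) against finite differences."""
    t = Tensor(x.copy(), requires_grad=True)
    out = build(t).sum()
    out.backward()
    num = numerical_grad(lambda arr: float(build(Tensor(arr)).sum().data), x.copy())
    np.testing.assert_allclose(t.grad, num, atol=atol, rtol=rtol)


class TestAutodiffPrimitives:
    def test_add_mul_broadcast(self):
        rng = np.random.default_rng(0)
        b = Tensor(rng.standard_normal((1, 3, 1)), requires_grad=True)
        x = rng.standard_normal((2, 3, 4))
        t = Tensor(x.copy(), requires_grad=True)
        out = ((t + b) * b).sum()
        out.backward()
        np.testing.assert_allclose(t.grad, np.broadcast_to(b.data, x.shape), rtol=1e-12)

    @pytest.mark.parametrize(
        "name,build,shape",
        [
            ("silu", lambda t: ad.silu(t), (3, 4)),
            ("sigmoid", lambda t: ad.sigmoid(t), (3, 4)),
            ("softmax", lambda t: ad.softmax(t) * Tensor(np.arange(12.0).reshape(3, 4)), (3, 4)),
            ("power", lambda t: (t * t + 1.0) ** -0.5, (3, 4)),
            ("mean", lambda t: t.mean(axis=1, keepdims=True) * t, (3, 4)),
            ("transpose", lambda t: t.transpose((1, 0)) @ Tensor(np.ones((3, 2))), (3, 4)),
            ("reshape", lambda t: (t.reshape((2, 6)) ** 2.0), (3, 4)),
            ("avg_pool", lambda t: ad.avg_pool2d(t, 2) ** 2.0, (1, 2, 4, 4)),
            ("upsample", lambda t: ad.upsample_nearest2d(t, 2) ** 2.0, (1, 2, 3, 3)),
            ("reflect_pad", lambda t: ad.reflect_pad2d(t, 2) ** 2.0, (1, 1, 5, 5)),
            ("concat", lambda t: ad.concat([t, t * 2.0], axis=1) ** 2.0, (1, 2, 3, 3)),
        ],
    )
    def test_primitive_gradients(self, name, build, shape):
        x = np.random.default_rng(hash(name) % 2**31).standard_normal(shape)
        check_gradient(build, x)

    def test_matmul_batched_gradient(self):
        rng = np.random.default_rng(1)
        w = Tensor(rng.standard_normal((4, 5)), requires_grad=True)
        x = rng.standard_normal((2, 3, 4))

        def build(t):
            return (t @ w) ** 2.0

        check_gradient(build, x)
        # weight gradient too (reset accumulation from the pass above)
        w.grad = None
        t = Tensor(x, requires_grad=False)
        out = ((t @ w) ** 2.0).sum()
        out.backward()
        num = numerical_grad(
            lambda arr: float((((x @ arr)) ** 2).sum()), w.data.copy()
        )
        np.testing.assert_allclose(w.grad, num, atol=1e-6, rtol=1e-4)

    def test_conv2d_gradients(self):
        rng = np.random.default_rng(2)
        w = Tensor(rng.standard_normal((3, 2, 3, 3)), requires_grad=True)
        b = Tensor(rng.standard_normal(3), requires_grad=True)
        x = rng.standard_normal((2, 2, 5, 5))

        def build(t):
            return ad.conv2d_valid(ad.reflect_pad2d(t, 1), w, b) ** 2.0

        check_gradient(build, x)
        w.grad = None
        t = Tensor(x)
        out = (ad.conv2d_valid(ad.reflect_pad2d(t, 1), w, b) ** 2.0).sum()
        out.backward()

        def loss_w(arr):
            ww = Tensor(arr)
            return float((ad.conv2d_valid(ad.reflect_pad2d(Tensor(x), 1), ww, b.detach()) ** 2.0).sum().data)

        np.testing.assert_allclose(w.grad, numerical_grad(loss_w, w.data.copy()), atol=1e-5, rtol=1e-4)

    def test_composite_block_gradients(self):
        """Full Swin block and ResBlock differentiate correctly end to end."""
        rng = np.random.default_rng(3)
        blk = SwinBlock(rng, channels=4, window=2, n_heads=2)
        for p in blk.parameters():
            p.data = p.data.astype(np.float64)
        x = rng.standard_normal((1, 4, 4, 4))
        check_gradient(lambda t: blk(t) ** 2.0, x, atol=1e-5, rtol=1e-3)

    def test_scalar_promotes_to_operand_dtype(self):
        t = Tensor(np.ones((2, 2), dtype=np.float32))
        assert (t + 1.0).data.dtype == np.float32
        assert (t * 0.5 - 2.0).data.dtype == np.float32


class TestTimestepEmbedding:
    def test_t_zero_alternating_pattern(self):
        emb = timestep_embedding(0, 8)
        np.testing.assert_array_equal(emb[0::2], 0.0)
        np.testing.assert_array_equal(emb[1::2], 1.0)

    def test_injective_over_training_range(self):
        embs = [tuple(np.round(timestep_embedding(t, 64), 12)) for t in range(16)]
        assert len(set(embs)) == 16

    def test_matches_direct_sinusoid_formula(self):
        dim, t = 16, 11
        emb = timestep_embedding(t, dim)
        for i in range(dim // 2):
            freq = 10000.0 ** (-i / (dim // 2))
            assert emb[2 * i] == pytest.approx(np.sin(t * freq), abs=1e-6)
            assert emb[2 * i + 1] == pytest.approx(np.cos(t * freq), abs=1e-6)

    def test_odd_dim_rejected(self):
        with pytest.raises(ValueError):
            timestep_embedding(3, 7)


class TestDenoiser:
    def test_shape_and_finiteness_contract(self):
        model = build_denoiser(TINY, seed=0)
        rng = np.random.default_rng(4)
        x = rng.random((32, 32)).astype(np.float32)
        for t in (1, 7, 15):
            out = model.predict(x, x, t)
            assert out.shape == (32, 32)
            assert np.isfinite(out).all()

    def test_swin_toggle_changes_param_count(self):
        with_swin = build_denoiser(TINY, seed=0)
        without = build_denoiser(DenoiserConfig(use_swin=False), seed=0)
        assert with_swin.param_count > without.param_count

    def test_seeded_init_reproducible(self):
        a = build_denoiser(TINY, seed=5)
        b = build_denoiser(TINY, seed=5)
        for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert na == nb
            np.testing.assert_array_equal(pa.data, pb.data)
        c = build_denoiser(TINY, seed=6)
        assert any(
            not np.array_equal(pa.data, pc.data)
            for (_, pa), (_, pc) in zip(a.named_parameters(), c.named_parameters())
        )

    def test_divisibility_validation(self):
        model = build_denoiser(TINY, seed=0)
        with pytest.raises(DenoiserConfigError, match="divisible"):
            model.predict(np.zeros((30, 30), np.float32), np.zeros((30, 30), np.float32), 1)

    @pytest.mark.parametrize("use_swin", [True, False])
    def test_gradient_reaches_every_parameter(self, use_swin):
        cfg = DenoiserConfig(base_width=8, depth=2, window_size=2, use_swin=use_swin, n_heads=2)
        model = UNetDenoiser(cfg, seed=1)
        rng = np.random.default_rng(5)
        x_t = Tensor(rng.standard_normal((2, 1, 8, 8)).astype(np.float32))
        x_lr = Tensor(rng.standard_normal((2, 1, 8, 8)).astype(np.float32))
        out = model.forward(x_t, x_lr, np.array([3, 9]))
        (out**2.0).mean().backward()
        dead = [n for n, p in model.named_parameters() if p.grad is None or not np.any(p.grad)]
        assert dead == []


class TestOptimizers:
    @pytest.mark.parametrize("cls", [Adam, RAdam])
    def test_quadratic_convergence(self, cls):
        p = Tensor(np.array([5.0, -3.0]), requires_grad=True)
        opt = cls([p], lr=0.1)
        for _ in range(300):
            opt.zero_grad()
            loss = (p * p).sum()
            loss.backward()
            opt.step()
        assert np.abs(p.data).max() < 1e-2

    def test_state_round_trip(self):
        p = Tensor(np.array([1.0, 2.0]), requires_grad=True)
        opt = Adam([p], lr=0.05)
        for _ in range(3):
            opt.zero_grad()
            ((p * p).sum()).backward()
            opt.step()
        state = {k: v.copy() for k, v in opt.state_arrays().items()}
        p2 = Tensor(p.data.copy(), requires_grad=True)
        opt2 = Adam([p2], lr=0.05)
        opt2.load_state_arrays(state)
        for o in (opt, opt2):
            o.zero_grad()
        ((p * p).sum()).backward()
        ((p2 * p2).sum()).backward()
        opt.step(); opt2.step()
        np.testing.assert_array_equal(p.data, p2.data)
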
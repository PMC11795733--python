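"""Unrolled reconstruction: regularizer, data consistency, and gradients."""

import numpy as np
import pytest

from mrcprecon import (
    EncodingOperator,
    data_consistency_step,
    load_checkpoint,
    regularizer_denoise,
    save_checkpoint,
    unrolled_reconstruct,
)
from mrcprecon.fourier import ifft2c
from mrcprecon.nn import Adam, ResNetConfig, ResNetRegularizer
from mrcprecon.unrolled import (
    UnrolledParams,
    unrolled_backward,
    unrolled_forward_cached,
)
from tests.conftest import dense_matrix


def tiny_params(zero=False, n_unrolls=3, dc_iters=8, seed=1, dtype=np.float32):
    net = ResNetRegularizer(
        ResNetConfig(n_blocks=2, channels=8), seed=seed, dtype=dtype, zero_init=zero
    )
    return UnrolledParams(net, n_unrolls=n_unrolls, dc_iters=dc_iters)


class TestRegularizer:
    def test_zero_weights_identity(self):
        params = tiny_params(zero=True)
        rng = np.random.default_rng(0)
        x = (rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))).astype(
            np.complex64
        )
        assert np.array_equal(regularizer_denoise(params, x), x)

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        a = regularizer_denoise(tiny_params(seed=3), x)
        b = regularizer_denoise(tiny_params(seed=3), x)
        assert np.array_equal(a, b)

    def test_non_finite_rejected(self):
        x = np.full((8, 8), np.nan, complex)
        with pytest.raises(FloatingPointError):
            regularizer_denoise(tiny_params(), x)

    def test_gradients_match_finite_differences(self):
        """Backprop through the ResNet agrees with central differences."""
        net = ResNetRegularizer(ResNetConfig(2, 6), seed=1, dtype=np.float64)
        rng = np.random.default_rng(2)
        x = rng.standard_normal((2, 8, 8))
        gout = rng.standard_normal((2, 8, 8))
        _, cache = net.forward(x, want_cache=True)
        gx, grads = net.backward(gout, cache)

        def scalar_loss():
            return float((net.forward(x) * gout).sum())

        eps = 1e-6
        for pi in (0, 2, 4, len(net.params) - 2):  # weights of several layers
            p = net.params[pi]
            for idx in [
                tuple(rng.integers(0, s) for s in p.shape) for _ in range(3)
            ]:
                orig = p[idx]
                p[idx] = orig + eps
                fp = scalar_loss()
                p[idx] = orig - eps
                fm = scalar_loss()
                p[idx] = orig
                fd = (fp - fm) / (2 * eps)
                if abs(fd) > 1e-9:
                    assert abs(fd - grads[pi][idx]) / abs(fd) < 1e-3
        for _ in range(4):  # input gradient too
            idx = tuple(rng.integers(0, s) for s in x.shape)
            orig = x[idx]
            x[idx] = orig + eps
            fp = scalar_loss()
            x[idx] = orig - eps
            fm = scalar_loss()
            x[idx] = orig
            fd = (fp - fm) / (2 * eps)
            assert abs(fd - gx[idx]) / max(abs(fd), 1e-12) < 1e-3


class TestDataConsistency:
    def test_unit_coil_full_mask_closed_form(self):
        op = EncodingOperator(np.ones((1, 16, 16), complex), None)
        rng = np.random.default_rng(0)
        y = rng.standard_normal((1, 16, 16)) + 1j * rng.standard_normal((1, 16, 16))
        z = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        x = data_consistency_step(y, op, z, lam=1.0, dc_iters=10)
        assert np.allclose(x, (ifft2c(y)[0] + z) / 2, atol=1e-10)

    def test_prior_dominated_limit(self, small_operator):
        rng = np.random.default_rng(1)
        y = small_operator.forward(rng.standard_normal((16, 16)) + 0j)
        z = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        x = data_consistency_step(y, small_operator, z, lam=1e8, dc_iters=20)
        assert np.linalg.norm(x - z) / np.linalg.norm(z) < 1e-3

    def test_matches_dense_solve(self, small_operator):
        rng = np.random.default_rng(2)
        y = small_operator.forward(rng.standard_normal((16, 16)) + 0j)
        z = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        lam = 0.3
        e_mat = dense_matrix(small_operator)
        xd = np.linalg.solve(
            e_mat.conj().T @ e_mat + lam * np.eye(256),
            e_mat.conj().T @ y.ravel() + lam * z.ravel(),
        )
        x = data_consistency_step(y, small_operator, z, lam, dc_iters=80)
        assert np.linalg.norm(x.ravel() - xd) / np.linalg.norm(xd) < 1e-5

    def test_inner_objective_not_increased(self, small_operator):
        """The CG solve does not worsen the unroll's inner objective vs z."""
        rng = np.random.default_rng(3)
        y = small_operator.forward(rng.standard_normal((16, 16)) + 0j)
        z = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        lam = 0.1

        def inner(x):
            return float(
                np.linalg.norm(small_operator.forward(x) - y) ** 2
                + lam * np.linalg.norm(x - z) ** 2
            )

        x = data_consistency_step(y, small_operator, z, lam, dc_iters=10)
        assert inner(x) <= inner(z) + 1e-8

    def test_lam_zero_undersampled_warns(self, small_operator):
        y = small_operator.forward(np.ones((16, 16), complex))
        with pytest.warns(RuntimeWarning):
            data_consistency_step(y, small_operator, np.zeros((16, 16), complex), 0.0, 3)


class TestUnrolled:
    def test_zero_unrolls_returns_adjoint(self, small_operator):
        rng = np.random.default_rng(0)
        y = small_operator.forward(rng.standard_normal((16, 16)) + 0j)
        params = tiny_params(n_unrolls=0)
        res = unrolled_reconstruct(y, small_operator, params)
        assert np.allclose(res.image, small_operator.adjoint(y), atol=1e-12)

    def test_identity_network_stays_at_fixed_point(self, small_operator):
        """With N = identity, a fixed point of the DC map (any solution of
        EhE x = Eh y) is preserved by further data-consistency steps."""
        from mrcprecon.classical import cg_solve

        rng = np.random.default_rng(1)
        y = small_operator.forward(rng.standard_normal((16, 16)) + 0j)
        b = small_operator.adjoint(y)
        x_star = cg_solve(small_operator.normal, b, n_iters=500, tol=1e-14)
        x = x_star.copy()
        for _ in range(5):
            x = data_consistency_step(y, small_operator, x, lam=0.05, dc_iters=30)
        assert np.linalg.norm(x - x_star) / np.linalg.norm(x_star) < 1e-6

    def test_identity_network_full_mask_fixed_point(self):
        """Full sampling: the unique fixed point is Eh y and the unrolled
        iteration with an identity network stays on it."""
        op = EncodingOperator(np.ones((1, 16, 16), complex), None)
        rng = np.random.default_rng(6)
        y = rng.standard_normal((1, 16, 16)) + 1j * rng.standard_normal((1, 16, 16))
        params = tiny_params(zero=True, n_unrolls=10, dc_iters=10)
        x_star = op.adjoint(y)  # EhE = I: x0 is already the fixed point
        res = unrolled_reconstruct(y, op, params)
        assert np.linalg.norm(res.image - x_star) / np.linalg.norm(x_star) < 1e-6

    def test_parameter_count_independent_of_unrolls(self):
        assert tiny_params(n_unrolls=2).n_parameters() == tiny_params(
            n_unrolls=12
        ).n_parameters()

    def test_lambda_positive_by_construction(self):
        params = tiny_params()
        params.log_lam[0] = -30.0
        assert params.lam > 0

    def test_checkpoint_round_trip(self, tmp_path):
        params = tiny_params(seed=9)
        path = tmp_path / "model.npz"
        save_checkpoint(path, params, seed=9)
        back = load_checkpoint(path)
        assert back.n_unrolls == params.n_unrolls
        assert back.lam == pytest.approx(params.lam)
        for a, b in zip(back.resnet.params, params.resnet.params):
            assert np.array_equal(a, b)

    def test_backward_matches_finite_differences_through_unrolls(self):
        """End-to-end gradient of a scalar loss through 2 unrolls (float64,
        converged inner CG so the implicit gradient is exact)."""
        maps = np.ones((1, 8, 8), complex)  # unitary E: CG converges exactly
        op = EncodingOperator(maps, None)
        rng = np.random.default_rng(4)
        y = (rng.standard_normal((1, 8, 8)) + 1j * rng.standard_normal((1, 8, 8)))
        net = ResNetRegularizer(ResNetConfig(1, 4), seed=2, dtype=np.float64)
        params = UnrolledParams(net, n_unrolls=2, dc_iters=12)
        w = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))

        def loss():
            x, _ = unrolled_forward_cached(y, op, params)
            return float(np.real(np.vdot(w, x)))

        x, steps = unrolled_forward_cached(y, op, params)
        grads, g_log_lam = unrolled_backward(w.copy(), op, params, steps)
        eps = 1e-6
        p = net.params[0]
        for idx in [tuple(rng.integers(0, s) for s in p.shape) for _ in range(3)]:
            orig = p[idx]
            p[idx] = orig + eps
            fp = loss()
            p[idx] = orig - eps
            fm = loss()
            p[idx] = orig
            fd = (fp - fm) / (2 * eps)
            if abs(fd) > 1e-9:
                assert abs(fd - grads[0][idx]) / abs(fd) < 1e-3
        orig = params.log_lam[0]
        params.log_lam[0] = orig + eps
        fp = loss()
        params.log_lam[0] = orig - eps
        fm = loss()
        params.log_lam[0] = orig
        fd = (fp - fm) / (2 * eps)
        assert abs(fd - g_log_lam) / max(abs(fd), 1e-12) < 1e-3


class TestAdamOptimizer:
    def test_descends_quadratic(self):
        target = np.array([3.0, -2.0])
        p = [np.zeros(2)]
        opt = Adam(p, lr=0.05)
        for _ in range(500):
            opt.step(p, [2 * (p[0] - target)])
        assert np.allclose(p[0], target, atol=1e-2)
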
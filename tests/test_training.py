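"""SSDU splitting, the l1-l2 k-space loss, references, and training loops."""

import numpy as np
import pytest

from mrcprecon import (
    EncodingOperator,
    apply_mask,
    loss_l1l2_kspace,
    make_duct_phantom,
    make_equidistant_mask,
    make_supervised_reference,
    retrospective_undersample,
    simulate_acquisition,
    simulate_coil_maps,
    ssdu_split,
    train_ssdu,
    train_supervised,
)
from mrcprecon.fourier import fft2c, ifft2c
from mrcprecon.masks import SamplingMask
from mrcprecon.nn import ResNetConfig, ResNetRegularizer
from mrcprecon.training import SplitConfig, TrainConfig, TrainingPair
from mrcprecon.unrolled import UnrolledParams, unrolled_reconstruct


@pytest.fixture()
def r6_mask():
    return make_equidistant_mask(480, 6, 24)


class TestSSDUSplit:
    def test_partition_contract_over_seeds(self, r6_mask):
        for seed in range(30):
            split = ssdu_split(r6_mask, rho=0.4, sigma_pe=None, seed=seed)
            union = np.union1d(split.theta_mask.sampled, split.lambda_mask.sampled)
            inter = np.intersect1d(split.theta_mask.sampled, split.lambda_mask.sampled)
            assert np.array_equal(union, r6_mask.sampled)
            assert inter.size == 0
            assert np.isin(r6_mask.acs, split.theta_mask.sampled).all()

    def test_lambda_size_matches_rho(self):
        # R=6 mask on 100 sampled lines: 76 non-ACS candidates
        mask = make_equidistant_mask(480, 6, 24)
        split = ssdu_split(mask, rho=0.4, sigma_pe=None, seed=0)
        assert split.lambda_mask.n_sampled == round(0.4 * 76) == 30

    def test_seed_determinism_and_variation(self, r6_mask):
        a = ssdu_split(r6_mask, 0.4, None, seed=5)
        b = ssdu_split(r6_mask, 0.4, None, seed=5)
        assert np.array_equal(a.lambda_mask.sampled, b.lambda_mask.sampled)
        distinct = {
            tuple(ssdu_split(r6_mask, 0.4, None, seed=s).lambda_mask.sampled)
            for s in range(100)
        }
        assert len(distinct) > 90  # different seeds give different splits

    def test_gaussian_center_preference(self, r6_mask):
        """Held-out lines concentrate near k-space center (Gaussian draw)."""
        center = r6_mask.n_pe // 2
        cands = np.array([k for k in r6_mask.sampled if k not in set(r6_mask.acs)])
        lam_dist = []
        for seed in range(200):
            split = ssdu_split(r6_mask, 0.3, r6_mask.n_pe / 4, seed)
            lam_dist.append(np.abs(split.lambda_mask.sampled - center).mean())
        assert np.mean(lam_dist) < np.abs(cands - center).mean()

    def test_invalid_rho(self, r6_mask):
        for rho in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                ssdu_split(r6_mask, rho, None, seed=0)

    def test_no_candidates_rejected(self):
        mask = SamplingMask(32, np.arange(12, 20), 12, 20, accel=1)  # ACS only
        with pytest.raises(ValueError):
            ssdu_split(mask, 0.4, None, seed=0)


class TestLoss:
    def test_zero_iff_equal(self):
        rng = np.random.default_rng(0)
        u = rng.standard_normal(10) + 1j * rng.standard_normal(10)
        assert loss_l1l2_kspace(u, u)[0] == 0.0
        assert loss_l1l2_kspace(u, u + 0.1)[0] > 0

    def test_forced_value(self):
        value, _ = loss_l1l2_kspace(np.array([1.0, 0.0]), np.array([0.0, 0.0]))
        assert value == pytest.approx(2.0)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(1)
        u = rng.standard_normal(40) + 1j * rng.standard_normal(40)
        v = rng.standard_normal(40) + 1j * rng.standard_normal(40)
        value, _ = loss_l1l2_kspace(u, v)
        l2 = np.sqrt(sum(abs(ui - vi) ** 2 for ui, vi in zip(u, v)))
        l1 = sum(abs(ui - vi) for ui, vi in zip(u, v))
        expected = l2 / np.sqrt(sum(abs(x) ** 2 for x in u)) + l1 / sum(
            abs(x) for x in u
        )
        assert value == pytest.approx(expected, rel=1e-12)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        u = rng.standard_normal(12) + 1j * rng.standard_normal(12)
        v = rng.standard_normal(12) + 1j * rng.standard_normal(12)
        _, grad = loss_l1l2_kspace(u, v)
        eps = 1e-7
        for i in (0, 5, 11):
            vp = v.copy()
            vp[i] += eps
            fd_re = (loss_l1l2_kspace(u, vp)[0] - loss_l1l2_kspace(u, v)[0]) / eps
            vp = v.copy()
            vp[i] += 1j * eps
            fd_im = (loss_l1l2_kspace(u, vp)[0] - loss_l1l2_kspace(u, v)[0]) / eps
            assert fd_re == pytest.approx(grad[i].real, rel=1e-4, abs=1e-6)
            assert fd_im == pytest.approx(grad[i].imag, rel=1e-4, abs=1e-6)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            loss_l1l2_kspace(np.zeros(4), np.ones(4))


class TestSupervisedReference:
    def test_fully_sampled_is_plain_recon(self, maps8, phantom64):
        acq = simulate_acquisition(phantom64, maps8, None, 0.0, seed=0)
        from mrcprecon import coil_combine
        from mrcprecon.masks import make_full_mask

        ref = make_supervised_reference(acq.kspace, make_full_mask(64), maps8)
        direct = coil_combine(maps8, ifft2c(acq.kspace))
        assert np.allclose(ref, direct, atol=1e-12)

    def test_phantom_reference_accuracy(self, r2_acq, phantom64, maps8):
        acq, mask2 = r2_acq
        ref = make_supervised_reference(acq.kspace, mask2, maps8)
        err = np.linalg.norm(ref - phantom64.pixels) / np.linalg.norm(phantom64.pixels)
        assert err < 0.02


def _tiny_pairs(n=2, with_ref=True, seed0=0):
    maps = simulate_coil_maps(32, 32, 4, seed=11)
    mask2 = make_equidistant_mask(32, 2, 16)
    mask4 = retrospective_undersample(mask2, 2)
    pairs = []
    for i in range(n):
        ph = make_duct_phantom(32, 32, 2, seed=seed0 + i)
        acq = simulate_acquisition(ph, maps, mask2, 0.01, seed=100 + i)
        ref = make_supervised_reference(acq.kspace, mask2, maps) if with_ref else None
        pairs.append(
            TrainingPair(
                y_input=apply_mask(acq.kspace, mask4),
                mask_input=mask4,
                maps=maps.maps,
                x_ref=ref,
            )
        )
    return pairs, maps, mask4


def _tiny_model(seed=0):
    return UnrolledParams(
        ResNetRegularizer(ResNetConfig(n_blocks=1, channels=8), seed=seed),
        n_unrolls=2,
        dc_iters=4,
    )


class TestTrainingLoops:
    def test_supervised_deterministic(self):
        pairs, _, _ = _tiny_pairs()
        cfg = TrainConfig(epochs=1, seed=3)
        a = train_supervised(pairs, cfg, _tiny_model()).loss_history
        b = train_supervised(pairs, cfg, _tiny_model()).loss_history
        assert a == b

    def test_supervised_loss_decreases(self):
        pairs, _, _ = _tiny_pairs(n=3)
        state = train_supervised(pairs, TrainConfig(epochs=12, seed=0), _tiny_model())
        assert state.loss_history[-1] < state.loss_history[0]

    def test_supervised_requires_reference(self):
        pairs, _, _ = _tiny_pairs(with_ref=False)
        with pytest.raises(ValueError):
            train_supervised(pairs, TrainConfig(epochs=1), _tiny_model())

    def test_ssdu_deterministic(self):
        pairs, _, _ = _tiny_pairs(with_ref=False)
        cfg = TrainConfig(epochs=1, seed=4)
        split = SplitConfig(rho=0.4)
        a = train_ssdu(pairs, split, cfg, _tiny_model()).loss_history
        b = train_ssdu(pairs, split, cfg, _tiny_model()).loss_history
        assert a == b

    def test_ssdu_loss_decreases(self):
        pairs, _, _ = _tiny_pairs(n=3, with_ref=False)
        state = train_ssdu(
            pairs, SplitConfig(rho=0.4), TrainConfig(epochs=12, seed=0), _tiny_model()
        )
        assert state.loss_history[-1] < state.loss_history[0]

    def test_ssdu_degenerate_rho_rejected(self):
        pairs, _, _ = _tiny_pairs(with_ref=False)
        with pytest.raises(ValueError):
            train_ssdu(
                pairs, SplitConfig(rho=1e-6), TrainConfig(epochs=1), _tiny_model()
            )

    def test_no_lambda_leakage(self):
        """Zeroing the held-out Lambda samples leaves the Theta-reconstruction
        bit-identical: the loss set is never read by the network input path."""
        pairs, maps, mask4 = _tiny_pairs(n=1, with_ref=False)
        y = pairs[0].y_input
        split = ssdu_split(mask4, 0.4, None, seed=7)
        params = _tiny_model(seed=2)
        op = EncodingOperator(maps.maps.astype(np.complex64), split.theta_mask)
        y_theta = apply_mask(y, split.theta_mask).astype(np.complex64)
        out_full = unrolled_reconstruct(y_theta, op, params).image
        y_zeroed = y.copy()
        y_zeroed[:, split.lambda_mask.sampled, :] = 0
        out_zeroed = unrolled_reconstruct(
            apply_mask(y_zeroed, split.theta_mask).astype(np.complex64), op, params
        ).image
        assert np.array_equal(out_full, out_zeroed)

    @pytest.mark.parametrize("strategy", ["supervised", "ssdu"])
    def test_training_improves_heldout_reconstruction(self, strategy):
        """Direction invariant: on noiseless, mildly undersampled data a
        briefly trained model beats the zero-filled adjoint on held-out slices
        (direction, not magnitude)."""
        maps = simulate_coil_maps(32, 32, 4, seed=11)
        mask2 = make_equidistant_mask(32, 2, 8)
        pairs = []
        for i in range(6):
            ph = make_duct_phantom(32, 32, 2, seed=20 + i)
            acq = simulate_acquisition(ph, maps, mask2, 0.0, seed=0)
            pairs.append(
                TrainingPair(
                    acq.kspace,
                    mask2,
                    maps.maps,
                    x_ref=ph.pixels if strategy == "supervised" else None,
                )
            )
        cfg = TrainConfig(epochs=25, seed=1)
        if strategy == "supervised":
            state = train_supervised(pairs, cfg, _tiny_model(seed=1))
        else:
            state = train_ssdu(pairs, SplitConfig(rho=0.4), cfg, _tiny_model(seed=2))
        ph = make_duct_phantom(32, 32, 2, seed=99)
        acq = simulate_acquisition(ph, maps, mask2, 0.0, seed=0)
        op = EncodingOperator(maps.maps.astype(np.complex64), mask2)
        y = acq.kspace.astype(np.complex64)
        err0 = np.linalg.norm(np.abs(op.adjoint(y)) - np.abs(ph.pixels))
        xt = unrolled_reconstruct(y, op, state.params).image
        errt = np.linalg.norm(np.abs(xt) - np.abs(ph.pixels))
        assert errt < err0


class TestManifestHygiene:
    def test_disjoint_manifest_accepted(self):
        from mrcprecon.training import check_manifest_disjoint

        check_manifest_disjoint(
            {"train": ["a.h5", "b.h5"], "val": ["c.h5"], "test": ["d.h5"]}
        )

    def test_overlapping_manifest_rejected(self):
        from mrcprecon.training import check_manifest_disjoint

        with pytest.raises(ValueError, match="overlap"):
            check_manifest_disjoint({"train": ["a.h5"], "test": ["a.h5"]})
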
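"""Scaled-down end-to-end benchmark on synthetic duct phantoms.

Mirrors the full study design at desk scale: simulate moderately accelerated
(R=2) multicoil acquisitions of duct phantoms, build GRAPPA references from
them, retrospectively undersample to the high acceleration, train the
unrolled reconstruction both supervised (against the GRAPPA references) and
self-supervised (SSDU), and compare zero-filled, CG-SENSE, wavelet-CS,
GRAPPA, and both trained models on held-out phantoms with PSNR/SSIM against
the known ground truth.

Default problem sizes (64x64 grid, 8 coils, 200 slices of which 20 are held
out, R=2 -> R=4 retrospective undersampling with 16 ACS lines, reduced
architecture of 4 unrolls / 2 residual blocks / 32 channels, 10 epochs) keep
a full run on one CPU core in the fifteen-minute range while preserving every
stage of the pipeline.  Everything derives deterministically from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import espirit_maps
from .classical import cg_sense, cs_wavelet
from .encoding import EncodingOperator, coil_combine
from .fourier import ifft2c
from .io import normalize_volume
from .masks import apply_mask, make_equidistant_mask, retrospective_undersample
from .metrics import MetricsReport, psnr_volume, ssim_volume, wilcoxon_one_sided
from .nn import ResNetConfig, ResNetRegularizer
from .phantom import (
    NOISE_SIGMA_HIGH_FIELD,
    make_duct_phantom,
    simulate_acquisition,
    simulate_coil_maps,
)
from .training import (
    SplitConfig,
    TrainConfig,
    TrainingPair,
    make_supervised_reference,
    train_ssdu,
    train_supervised,
)
from .unrolled import UnrolledParams, unrolled_reconstruct

__all__ = ["BenchmarkConfig", "run_benchmark"]


@dataclass
class BenchmarkConfig:
    """Study conditions of the synthetic end-to-end experiment."""

    ny: int = 64
    nx: int = 64
    n_coils: int = 8
    n_slices: int = 200          # total phantoms; the last n_test are held out
    n_test: int = 20
    n_ducts: int = 4
    accel_ref: int = 2           # measured acceleration (reference regime)
    extra: int = 2               # retrospective factor -> input acceleration R=4
    n_acs: int = 16
    noise_sigma: float = NOISE_SIGMA_HIGH_FIELD
    n_unrolls: int = 4
    n_blocks: int = 2
    channels: int = 32
    dc_iters: int = 6
    epochs: int = 10
    lr: float = 3e-4
    rho: float = 0.4
    cg_lambda: float = 0.01
    cs_lambda: float = 0.008
    cg_iters: int = 30
    cs_iters: int = 60
    espirit_calib: int = 16
    methods: tuple = ("zero-filled", "cg-sense", "cs", "grappa-r2", "dl-sv", "dl-ssdu")


def _seed_int(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1)[0] % (2**31))


def run_benchmark(seed: int, config: BenchmarkConfig | None = None,
                  verbose: bool = False) -> dict:
    """Run the full synthetic training-and-evaluation experiment.

    Returns a dictionary of mean held-out metrics per method, PSNR gains of
    the trained models over the zero-filled baseline, Wilcoxon p-values of
    the supervised model against the baselines, the training loss histories,
    and the problem sizes used.
    """
    cfg = config or BenchmarkConfig()
    master = np.random.SeedSequence(seed)
    s_maps, s_phantom, s_noise, s_init_sv, s_init_ssdu, s_train_sv, s_train_ssdu = (
        master.spawn(7)
    )

    coil_maps = simulate_coil_maps(cfg.ny, cfg.nx, cfg.n_coils, _seed_int(s_maps))
    mask2 = make_equidistant_mask(cfg.ny, cfg.accel_ref, cfg.n_acs)
    mask_hi = retrospective_undersample(mask2, cfg.extra)

    phantom_seeds = s_phantom.spawn(cfg.n_slices)
    noise_seeds = s_noise.spawn(cfg.n_slices)
    truths = []
    y2_stack = np.empty(
        (cfg.n_slices, cfg.n_coils, cfg.ny, cfg.nx), dtype=np.complex128
    )
    for i in range(cfg.n_slices):
        ph = make_duct_phantom(cfg.ny, cfg.nx, cfg.n_ducts, _seed_int(phantom_seeds[i]))
        truths.append(np.abs(ph.pixels))
        acq = simulate_acquisition(
            ph, coil_maps, mask2, cfg.noise_sigma, _seed_int(noise_seeds[i])
        )
        y2_stack[i] = acq.kspace

    # volume-wise normalization (one factor for the whole stack)
    y2_stack, norm_factor = normalize_volume(y2_stack)
    truths = np.asarray(truths) / norm_factor

    # one set of sensitivity maps per dataset, estimated from the ACS region
    maps_est = espirit_maps(y2_stack[0], calib_size=cfg.espirit_calib, kernel_size=5)

    refs = np.empty((cfg.n_slices, cfg.ny, cfg.nx), dtype=complex)
    y_hi = np.empty_like(y2_stack)
    for i in range(cfg.n_slices):
        refs[i] = make_supervised_reference(y2_stack[i], mask2, maps_est)
        y_hi[i] = apply_mask(y2_stack[i], mask_hi)

    n_train = cfg.n_slices - cfg.n_test
    train_idx = np.arange(n_train)
    test_idx = np.arange(n_train, cfg.n_slices)

    def make_pairs(with_ref: bool):
        return [
            TrainingPair(
                y_input=y_hi[i],
                mask_input=mask_hi,
                maps=maps_est.maps,
                x_ref=refs[i] if with_ref else None,
            )
            for i in train_idx
        ]

    arch = ResNetConfig(n_blocks=cfg.n_blocks, channels=cfg.channels)

    def fresh_params(init_seed: int) -> UnrolledParams:
        return UnrolledParams(
            ResNetRegularizer(arch, seed=init_seed),
            n_unrolls=cfg.n_unrolls,
            dc_iters=cfg.dc_iters,
        )

    states = {}
    if "dl-sv" in cfg.methods:
        states["dl-sv"] = train_supervised(
            make_pairs(True),
            TrainConfig(epochs=cfg.epochs, lr=cfg.lr, seed=_seed_int(s_train_sv)),
            fresh_params(_seed_int(s_init_sv)),
        )
        if verbose:
            print(f"supervised loss: {states['dl-sv'].loss_history[0]:.4f} -> "
                  f"{states['dl-sv'].loss_history[-1]:.4f}")
    if "dl-ssdu" in cfg.methods:
        states["dl-ssdu"] = train_ssdu(
            make_pairs(False),
            SplitConfig(rho=cfg.rho, sigma_pe=cfg.ny / 4),
            TrainConfig(epochs=cfg.epochs, lr=cfg.lr, seed=_seed_int(s_train_ssdu)),
            fresh_params(_seed_int(s_init_ssdu)),
        )
        if verbose:
            print(f"ssdu loss: {states['dl-ssdu'].loss_history[0]:.4f} -> "
                  f"{states['dl-ssdu'].loss_history[-1]:.4f}")

    # held-out evaluation against the known ground truth
    op_hi = EncodingOperator(maps_est.maps, mask_hi)
    report = MetricsReport(reference="ground-truth phantom")
    for method in cfg.methods:
        report.psnr[method] = []
        report.ssim[method] = []
    for i in test_idx:
        y = y_hi[i]
        truth = truths[i]
        recons = {}
        if "zero-filled" in cfg.methods:
            recons["zero-filled"] = op_hi.adjoint(y)
        if "cg-sense" in cfg.methods:
            recons["cg-sense"] = cg_sense(
                y, op_hi, cfg.cg_lambda, n_iters=cfg.cg_iters
            ).image
        if "cs" in cfg.methods:
            recons["cs"] = cs_wavelet(y, op_hi, cfg.cs_lambda, n_iters=cfg.cs_iters).image
        if "grappa-r2" in cfg.methods:
            recons["grappa-r2"] = refs[i]
        for name in ("dl-sv", "dl-ssdu"):
            if name in states:
                op32 = EncodingOperator(maps_est.maps.astype(np.complex64), mask_hi)
                recons[name] = unrolled_reconstruct(
                    y.astype(np.complex64), op32, states[name].params
                ).image
        for method, img in recons.items():
            mag = np.abs(img)
            report.psnr[method].append(psnr_volume(mag, truth))
            report.ssim[method].append(ssim_volume(mag, truth))

    results: dict = {
        "n_train": int(n_train),
        "n_test": int(cfg.n_test),
        "norm_factor": float(norm_factor),
        "report": report,
        "loss_history": {k: v.loss_history for k, v in states.items()},
        "lambda_learned": {k: v.params.lam for k, v in states.items()},
    }
    means = {m: float(np.mean(v)) for m, v in report.psnr.items() if v}
    results["psnr_mean_db"] = means
    results["ssim_mean"] = {
        m: float(np.mean(v)) for m, v in report.ssim.items() if v
    }
    if "zero-filled" in means:
        for name in ("dl-sv", "dl-ssdu"):
            if name in means:
                results[f"gain_{name}_db"] = means[name] - means["zero-filled"]
    for name in ("dl-sv", "dl-ssdu"):
        for base in ("cg-sense", "cs", "zero-filled"):
            if name in report.psnr and base in report.psnr and report.psnr[name]:
                report.p_values[f"{name}>{base}"] = wilcoxon_one_sided(
                    report.psnr[name], report.psnr[base]
                )
    return results
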
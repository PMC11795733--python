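"""Training strategies for the unrolled reconstruction.

Two strategies are provided:

Supervised (SV)
    Pairs a highly undersampled input with a reference image reconstructed by
    GRAPPA from a moderately (R=2) accelerated scan of the same anatomy.  The
    loss compares the k-space of the reference against the k-space of the
    network output (both taken over the full grid, per coil through the
    sensitivity maps).

Self-supervised (SSDU)
    Needs no reference: the measured lines Omega of each example are split
    into two disjoint sets, Theta (fed to the reconstruction for data
    consistency) and Lambda (held out for the loss).  Lambda is drawn from
    the non-ACS measured lines with 1-D Gaussian probability centered on
    k-space center, so the held-out set mimics the aliasing distribution of
    the measurement; the ACS block always stays in Theta.  A fresh split is
    drawn every epoch (seeded).

Both minimize the normalized l1-l2 k-space loss

    L(u, v) = ||u - v||_2 / ||u||_2 + ||u - v||_1 / ||u||_1

with Adam (default learning rate 3e-4), batch size one slice, and global
gradient-norm clipping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import acs_phase_of, grappa_fit_kernel, grappa_reconstruct
from .encoding import EncodingOperator, coil_combine
from .fourier import fft2c, ifft2c
from .masks import SamplingMask, apply_mask
from .nn import Adam, ResNetRegularizer, clip_grad_norm
from .phantom import CoilMaps
from .unrolled import UnrolledParams, unrolled_backward, unrolled_forward_cached

__all__ = [
    "TrainingPair",
    "SSDUSplit",
    "TrainConfig",
    "SplitConfig",
    "TrainState",
    "ssdu_split",
    "loss_l1l2_kspace",
    "make_supervised_reference",
    "train_supervised",
    "train_ssdu",
    "check_manifest_disjoint",
]


def check_manifest_disjoint(manifest: dict) -> None:
    """Validate dataset-split hygiene: train/val/test share no identities.

    ``manifest`` maps role (``train``/``val``/``test``) to a list of dataset
    identities (file paths or subject labels).  Overlap between roles leaks
    evaluation data into training and is rejected.
    """
    roles = [r for r in ("train", "val", "test") if manifest.get(r)]
    for i, a in enumerate(roles):
        for b in roles[i + 1 :]:
            overlap = set(map(str, manifest[a])) & set(map(str, manifest[b]))
            if overlap:
                raise ValueError(
                    f"manifest roles {a!r} and {b!r} overlap: {sorted(overlap)}"
                )


@dataclass
class TrainingPair:
    """One training example: undersampled k-space plus optional reference."""

    y_input: np.ndarray
    mask_input: SamplingMask
    maps: np.ndarray
    x_ref: np.ndarray | None = None


@dataclass
class SSDUSplit:
    """Disjoint partition of the measured lines: Theta (DC) and Lambda (loss)."""

    theta_mask: SamplingMask
    lambda_mask: SamplingMask
    rho: float
    seed: int


@dataclass
class TrainConfig:
    """Optimization settings shared by both strategies."""

    epochs: int = 100
    lr: float = 3e-4
    clip: float = 1.0
    seed: int = 0
    shuffle: bool = True


@dataclass
class SplitConfig:
    """SSDU split settings: held-out fraction and Gaussian line-draw width."""

    rho: float = 0.4
    sigma_pe: float | None = None  # defaults to n_pe / 4


@dataclass
class TrainState:
    """Result of a training run (reproducible from seed + config + data)."""

    params: UnrolledParams
    optimizer: Adam
    epoch: int
    loss_history: list = field(default_factory=list)
    seed: int = 0


def ssdu_split(
    mask: SamplingMask, rho: float, sigma_pe: float | None, seed: int
) -> SSDUSplit:
    """Split the measured lines Omega into disjoint Theta and Lambda sets.

    Lambda is drawn without replacement from the non-ACS measured lines with
    probability proportional to ``exp(-(k - k_center)^2 / (2 sigma^2))``;
    Theta is the complement within Omega and always contains the ACS block.
    """
    if not 0 < rho < 1:
        raise ValueError("rho must lie strictly between 0 and 1")
    if sigma_pe is None:
        sigma_pe = mask.n_pe / 4
    acs = set(mask.acs.tolist())
    candidates = np.array([k for k in mask.sampled if k not in acs])
    if candidates.size == 0:
        raise ValueError("mask has no non-ACS lines to hold out")
    n_lambda = int(round(rho * candidates.size))
    if n_lambda < 1 or n_lambda >= candidates.size:
        raise ValueError("rho leaves an empty Theta or Lambda set")
    center = mask.n_pe // 2
    w = np.exp(-((candidates - center) ** 2) / (2.0 * sigma_pe**2))
    rng = np.random.default_rng(seed)
    lam_lines = rng.choice(candidates, size=n_lambda, replace=False, p=w / w.sum())
    lam_lines = np.sort(lam_lines)
    theta_lines = np.setdiff1d(mask.sampled, lam_lines)
    theta = SamplingMask(
        mask.n_pe, theta_lines, mask.acs_start, mask.acs_stop, mask.accel
    )
    lam = SamplingMask(mask.n_pe, lam_lines, 0, 0, mask.accel)
    return SSDUSplit(theta, lam, rho, seed)


def loss_l1l2_kspace(u: np.ndarray, v: np.ndarray):
    """Normalized l1-l2 loss between k-space sample sets on the same indices.

    ``||u - v||_2 / ||u||_2 + ||u - v||_1 / ||u||_1`` with complex moduli;
    zero iff u == v.  Returns ``(value, grad)`` where grad packs
    d/d(Re v) + i d/d(Im v), ready for backpropagation.
    """
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape:
        raise ValueError("u and v must cover the same index set")
    n2 = float(np.linalg.norm(u))
    n1 = float(np.abs(u).sum())
    if n2 == 0 or n1 == 0:
        raise ValueError("reference samples must not be all zero")
    d = v - u
    d2 = float(np.linalg.norm(d))
    d1 = float(np.abs(d).sum())
    value = d2 / n2 + d1 / n1
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(np.abs(d) > 0, d / np.maximum(np.abs(d), 1e-300), 0.0)
    grad = (d / d2 / n2 if d2 > 0 else np.zeros_like(d)) + unit / n1
    return value, grad


def make_supervised_reference(
    y2: np.ndarray, mask2: SamplingMask, maps: CoilMaps | np.ndarray
) -> np.ndarray:
    """GRAPPA-based coil-combined reference image from an R=2 acquisition."""
    if mask2.is_full():
        filled = np.asarray(y2, dtype=complex)
    else:
        acs = np.asarray(y2)[:, mask2.acs_start : mask2.acs_stop, :]
        kernel = grappa_fit_kernel(acs, mask2.accel, acs_phase=acs_phase_of(mask2))
        filled = grappa_reconstruct(y2, mask2, kernel)
    return coil_combine(maps, ifft2c(filled))


def _maps_array(maps) -> np.ndarray:
    return maps.maps if isinstance(maps, CoilMaps) else np.asarray(maps)


def _run_training(
    pairs,
    params: UnrolledParams,
    config: TrainConfig,
    split_cfg: SplitConfig | None,
) -> TrainState:
    supervised = split_cfg is None
    trainable = params.trainable()
    opt = Adam(trainable, lr=config.lr)
    master = np.random.SeedSequence(config.seed)
    order_rng = np.random.default_rng(master.spawn(1)[0])
    split_root = master.spawn(1)[0]
    loss_history: list[float] = []

    for epoch in range(config.epochs):
        order = np.arange(len(pairs))
        if config.shuffle:
            order_rng.shuffle(order)
        epoch_split_seeds = None
        if not supervised:
            epoch_seq = np.random.SeedSequence(
                entropy=split_root.entropy,
                spawn_key=tuple(split_root.spawn_key) + (epoch,),
            )
            epoch_split_seeds = [
                int(s.generate_state(1)[0] % (2**31)) for s in epoch_seq.spawn(len(pairs))
            ]
        epoch_loss = 0.0
        for j in order:
            pair = pairs[j]
            maps = _maps_array(pair.maps).astype(np.complex64)
            if supervised:
                if pair.x_ref is None:
                    raise ValueError("supervised training requires x_ref on every pair")
                op = EncodingOperator(maps, pair.mask_input)
                y_in = pair.y_input.astype(np.complex64)
                target = fft2c(maps * np.asarray(pair.x_ref, dtype=np.complex64)[None])
                x, steps = unrolled_forward_cached(y_in, op, params)
                v = fft2c(maps * x[None])
                value, gv = loss_l1l2_kspace(target, v)
                gc = (np.conj(maps) * ifft2c(gv)).sum(axis=0)
            else:
                split = ssdu_split(
                    pair.mask_input,
                    split_cfg.rho,
                    split_cfg.sigma_pe,
                    epoch_split_seeds[j],
                )
                op = EncodingOperator(maps, split.theta_mask)
                y_in = apply_mask(pair.y_input, split.theta_mask).astype(np.complex64)
                lam_lines = split.lambda_mask.sampled
                u = pair.y_input[:, lam_lines, :].astype(np.complex64)
                x, steps = unrolled_forward_cached(y_in, op, params)
                v_full = fft2c(maps * x[None])
                value, gv_lines = loss_l1l2_kspace(u, v_full[:, lam_lines, :])
                gv = np.zeros_like(v_full)
                gv[:, lam_lines, :] = gv_lines
                gc = (np.conj(maps) * ifft2c(gv)).sum(axis=0)
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, example {j}"
                )
            grads, g_log_lam = unrolled_backward(gc, op, params, steps)
            all_grads = [*grads, np.array([g_log_lam])]
            clip_grad_norm(all_grads, config.clip)
            opt.step(trainable, all_grads)
            epoch_loss += value
        loss_history.append(epoch_loss / max(len(pairs), 1))
    return TrainState(params, opt, config.epochs, loss_history, config.seed)


def train_supervised(
    pairs, config: TrainConfig, params: UnrolledParams
) -> TrainState:
    """Train against GRAPPA-derived references (every pair needs ``x_ref``)."""
    for pair in pairs:
        if pair.x_ref is None:
            raise ValueError("supervised training requires x_ref on every pair")
    return _run_training(pairs, params, config, None)


def train_ssdu(
    pairs, split_cfg: SplitConfig, config: TrainConfig, params: UnrolledParams
) -> TrainState:
    """Self-supervised training via per-epoch Theta/Lambda k-space splits."""
    return _run_training(pairs, params, config, split_cfg)
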
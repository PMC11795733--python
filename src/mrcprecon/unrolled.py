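"""Unrolled model-based reconstruction: learned denoising + data consistency.

The reconstruction alternates a learned residual-CNN regularizer with a
conjugate-gradient data-consistency solve for a fixed number of unrolls,

    x_0 = Eh y            (zero-filled adjoint)
    z_i = N_theta(x_i)    (regularizer)
    x_{i+1} = argmin_x ||y - Ex||^2 + lam ||x - z_i||^2
            = (EhE + lam I)^(-1) (Eh y + lam z_i),

with the SAME network weights theta at every unroll and a single trainable
data-consistency weight lam >= 0 (stored as its logarithm so positivity is
structural).  The physics stays in native complex arithmetic; the network
sees a 2-channel real representation.

Training support: `unrolled_forward_cached` / `unrolled_backward` give exact
gradients through the network and implicit gradients through each
data-consistency solve (differentiating the normal-equation solution, reusing
CG on the adjoint system — the standard approach for unrolled networks with
CG blocks; it is exact in the limit of converged inner CG).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .classical import ReconResult, cg_solve
from .encoding import EncodingOperator
from .nn import ResNetConfig, ResNetRegularizer

__all__ = [
    "UnrolledParams",
    "regularizer_denoise",
    "data_consistency_step",
    "unrolled_reconstruct",
    "save_checkpoint",
    "load_checkpoint",
]

_CHECKPOINT_VERSION = 1


@dataclass
class UnrolledParams:
    """Weights and structure of the unrolled reconstruction.

    ``log_lam`` is a 1-element float64 array so the optimizer can update it
    in place alongside the network weights; ``lam = exp(log_lam)`` is always
    positive.  The regularizer weights are shared by all unrolls, so the
    trainable parameter count does not depend on ``n_unrolls``.
    """

    resnet: ResNetRegularizer
    log_lam: np.ndarray = field(
        default_factory=lambda: np.array([np.log(0.05)], dtype=np.float64)
    )
    n_unrolls: int = 12
    dc_iters: int = 10

    def __post_init__(self) -> None:
        self.log_lam = np.atleast_1d(np.asarray(self.log_lam, dtype=np.float64))
        if self.n_unrolls < 0:
            raise ValueError("n_unrolls must be non-negative")

    @property
    def lam(self) -> float:
        return float(np.exp(self.log_lam[0]))

    def trainable(self) -> list[np.ndarray]:
        """All trainable arrays: network weights plus log-lambda."""
        return [*self.resnet.params, self.log_lam]

    def n_parameters(self) -> int:
        return self.resnet.n_parameters() + 1


def regularizer_denoise(params: UnrolledParams, x: np.ndarray) -> np.ndarray:
    """Apply the residual CNN to a complex image (shape preserved)."""
    x = np.asarray(x)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite input to the regularizer")
    out = params.resnet.forward(np.stack([x.real, x.imag]))
    return out[0] + 1j * out[1]


def data_consistency_step(
    y: np.ndarray,
    op: EncodingOperator,
    z: np.ndarray,
    lam: float,
    dc_iters: int = 10,
) -> np.ndarray:
    """Solve ``(EhE + lam I) x = Eh y + lam z`` by CG, warm-started at z."""
    if lam < 0:
        raise ValueError("lam must be non-negative")
    if lam == 0 and op.mask is not None and not op.mask.is_full():
        warnings.warn(
            "lam=0 with an undersampled mask: the inner problem is ill-posed; "
            "truncated CG acts as the only regularization",
            RuntimeWarning,
            stacklevel=2,
        )
    b = op.adjoint(y) + lam * z
    return cg_solve(lambda v: op.normal(v) + lam * v, b, x0=z, n_iters=dc_iters, tol=0.0)


def unrolled_reconstruct(
    y: np.ndarray, op: EncodingOperator, params: UnrolledParams
) -> ReconResult:
    """Run the unrolled reconstruction from the zero-filled adjoint."""
    x = op.adjoint(y)
    lam = params.lam
    for _ in range(params.n_unrolls):
        z = regularizer_denoise(params, x)
        x = data_consistency_step(y, op, z, lam, params.dc_iters)
    return ReconResult(x, "unrolled", lam, params.n_unrolls)


# --------------------------------------------------------------------------
# Training-time forward/backward
# --------------------------------------------------------------------------


def unrolled_forward_cached(y, op: EncodingOperator, params: UnrolledParams):
    """Forward pass retaining everything the backward pass needs."""
    x = op.adjoint(y)
    lam = params.lam
    steps = []
    for _ in range(params.n_unrolls):
        x2 = np.stack([x.real, x.imag])
        z2, net_cache = params.resnet.forward(x2, want_cache=True)
        z = (z2[0] + 1j * z2[1]).astype(x.dtype)
        x_new = data_consistency_step(y, op, z, lam, params.dc_iters)
        steps.append((net_cache, z, x_new))
        x = x_new
    return x, steps


def unrolled_backward(gc, op: EncodingOperator, params: UnrolledParams, steps):
    """Backpropagate a complex image gradient through the unrolled network.

    ``gc`` holds d(loss)/d(real part) + i * d(loss)/d(imag part) of the final
    image.  Returns (grads, g_log_lam) with grads aligned to
    ``params.resnet.params``.
    """
    lam = params.lam
    grads = [np.zeros_like(p) for p in params.resnet.params]
    g_lam = 0.0
    for net_cache, z, x_out in reversed(steps):
        # implicit gradient of x = (EhE + lam I)^(-1) (Eh y + lam z)
        s = cg_solve(
            lambda v: op.normal(v) + lam * v,
            np.ascontiguousarray(gc),
            n_iters=params.dc_iters,
            tol=0.0,
        )
        g_lam += float(np.real(np.vdot(s, z - x_out)))
        gz = lam * s
        gx2, step_grads = params.resnet.backward(
            np.stack([gz.real, gz.imag]), net_cache
        )
        for acc, g in zip(grads, step_grads):
            acc += g
        gc = (gx2[0] + 1j * gx2[1]).astype(gc.dtype)
    g_log_lam = g_lam * lam  # chain rule through lam = exp(log_lam)
    return grads, g_log_lam


# --------------------------------------------------------------------------
# Checkpoints
# --------------------------------------------------------------------------


def save_checkpoint(path, params: UnrolledParams, seed: int | None = None) -> None:
    """Persist weights, lambda, and architecture to a single .npz archive."""
    cfg = params.resnet.config
    arrays = {f"w{i}": p for i, p in enumerate(params.resnet.params)}
    np.savez(
        path,
        version=_CHECKPOINT_VERSION,
        log_lam=params.log_lam,
        n_unrolls=params.n_unrolls,
        dc_iters=params.dc_iters,
        n_blocks=cfg.n_blocks,
        channels=cfg.channels,
        kernel_extent=cfg.kernel_extent,
        residual_scale=cfg.residual_scale,
        dtype=str(params.resnet.dtype),
        seed=-1 if seed is None else seed,
        n_params=len(params.resnet.params),
        **arrays,
    )


def load_checkpoint(path) -> UnrolledParams:
    with np.load(path, allow_pickle=False) as data:
        if int(data["version"]) != _CHECKPOINT_VERSION:
            raise ValueError("unsupported checkpoint version")
        cfg = ResNetConfig(
            n_blocks=int(data["n_blocks"]),
            channels=int(data["channels"]),
            kernel_extent=int(data["kernel_extent"]),
            residual_scale=float(data["residual_scale"]),
        )
        net = ResNetRegularizer(cfg, dtype=np.dtype(str(data["dtype"])), zero_init=True)
        stored = [data[f"w{i}"] for i in range(int(data["n_params"]))]
        for p, s in zip(net.params, stored):
            p[...] = s
        return UnrolledParams(
            resnet=net,
            log_lam=data["log_lam"],
            n_unrolls=int(data["n_unrolls"]),
            dc_iters=int(data["dc_iters"]),
        )
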
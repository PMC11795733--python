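"""The linear multicoil encoding operator E and its adjoint/normal forms.

``E x = mask . F (S_c x)`` per coil c, with S the coil sensitivity maps and F
the centered orthonormal 2-D FFT.  The mask is applied symmetrically on the
forward and adjoint sides (projection form), so the normal operator EhE
depends only on the sampled lines — the form required by regularized
least-squares data-consistency solves.

With RSS-normalized maps and the orthonormal transform, ||E|| <= 1, which
keeps conjugate-gradient solves and unrolled training well conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fourier import fft2c, ifft2c
from .masks import SamplingMask, apply_mask
from .phantom import CoilMaps

__all__ = [
    "EncodingOperator",
    "encode_forward",
    "encode_adjoint",
    "coil_combine",
    "operator_norm",
]

_EPS = 1e-12


@dataclass
class EncodingOperator:
    """Multicoil Cartesian encoding operator for one 2-D slice.

    Parameters
    ----------
    maps:
        Complex coil sensitivities, shape ``(n_coils, ny, nx)``.
    mask:
        Phase-encode sampling mask, or ``None`` for full sampling.
    """

    maps: np.ndarray
    mask: SamplingMask | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps)
        if self.maps.ndim != 3:
            raise ValueError("maps must have shape (n_coils, ny, nx)")
        if self.mask is not None and self.mask.n_pe != self.maps.shape[1]:
            raise ValueError("mask length and map PE dimension differ")
        # hot-path caches (the normal operator runs inside CG loops)
        self._conj_maps = np.conj(self.maps)
        if self.mask is None or self.mask.is_full():
            self._line_weight = None
        else:
            real_dtype = np.zeros(1, dtype=self.maps.dtype).real.dtype
            self._line_weight = self.mask.bool_array().astype(real_dtype)[
                None, :, None
            ]

    @property
    def shape(self) -> tuple[int, int]:
        return self.maps.shape[1:]

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    def forward(self, image: np.ndarray) -> np.ndarray:
        return encode_forward(self, image)

    def adjoint(self, kspace: np.ndarray) -> np.ndarray:
        return encode_adjoint(self, kspace)

    def normal(self, image: np.ndarray) -> np.ndarray:
        """EhE applied to an image (one forward + adjoint pass).

        Equivalent to ``adjoint(forward(image))`` but skips per-call shape
        checks and redundant mask projections (mask . mask = mask).
        """
        kspace = fft2c(self.maps * image[None])
        if self._line_weight is not None:
            kspace *= self._line_weight
        return (self._conj_maps * ifft2c(kspace)).sum(axis=0)

    def with_mask(self, mask: SamplingMask | None) -> "EncodingOperator":
        """Same maps, different sampling pattern (maps are shared, not copied)."""
        return EncodingOperator(self.maps, mask)


def encode_forward(op: EncodingOperator, image: np.ndarray) -> np.ndarray:
    """y = mask . F(S x): image -> multicoil k-space."""
    image = np.asarray(image)
    if image.shape != op.shape:
        raise ValueError(f"image shape {image.shape} != operator shape {op.shape}")
    kspace = fft2c(op.maps * image[None])
    if op.mask is not None:
        kspace = apply_mask(kspace, op.mask)
    return kspace


def encode_adjoint(op: EncodingOperator, kspace: np.ndarray) -> np.ndarray:
    """Eh y = sum_c conj(S_c) . Finv(mask . y_c): the zero-filled reconstruction."""
    kspace = np.asarray(kspace)
    if kspace.shape != (op.n_coils, *op.shape):
        raise ValueError(
            f"kspace shape {kspace.shape} != {(op.n_coils, *op.shape)}"
        )
    if op.mask is not None:
        kspace = apply_mask(kspace, op.mask)
    return (np.conj(op.maps) * ifft2c(kspace)).sum(axis=0)


def coil_combine(
    maps: CoilMaps | np.ndarray, coil_images: np.ndarray, eps: float = _EPS
) -> np.ndarray:
    """Sensitivity-weighted coil combination.

    ``sum_c conj(S_c) img_c / max(sum_c |S_c|^2, eps)``; for RSS-normalized
    maps the denominator is 1 inside the support, and images generated as
    ``S_c x`` are recovered exactly wherever any map is nonzero.
    """
    m = maps.maps if isinstance(maps, CoilMaps) else np.asarray(maps)
    coil_images = np.asarray(coil_images)
    if coil_images.shape != m.shape:
        raise ValueError("coil_images and maps shapes differ")
    denom = np.maximum((np.abs(m) ** 2).sum(axis=0), eps)
    return (np.conj(m) * coil_images).sum(axis=0) / denom


def operator_norm(op: EncodingOperator, n_iters: int = 30, seed: int = 0) -> float:
    """Largest singular value of E, estimated by power iteration on EhE."""
    rng = np.random.default_rng(seed)
    ny, nx = op.shape
    x = rng.standard_normal((ny, nx)) + 1j * rng.standard_normal((ny, nx))
    x /= np.linalg.norm(x)
    lam = 0.0
    for _ in range(n_iters):
        y = op.normal(x)
        lam = float(np.real(np.vdot(x, y)))
        norm = np.linalg.norm(y)
        if norm == 0:
            return 0.0
        x = y / norm
    return float(np.sqrt(max(lam, 0.0)))
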
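"""Coil-sensitivity calibration (ESPIRiT) and GRAPPA k-space interpolation.

Both methods calibrate on the fully sampled central ACS block. ESPIRiT builds
the block-Hankel calibration matrix, keeps the dominant right-singular
vectors as k-space kernels, transforms them to image space, and takes the
per-pixel dominant eigenvector of the resulting operator as the sensitivity
map.  Maps are kept over the whole FOV (no background cropping), with unit
per-pixel norm, and the per-pixel phase referenced to the first coil so
repeated runs are bit-identical.

GRAPPA fills the missing phase-encode lines of an equidistantly undersampled
slice by coil-wise linear interpolation from sampled neighbors; the
interpolation weights are fit by least squares over all sliding windows of
the ACS block.  Measured lines always pass through unchanged, so the output
is data-consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .fourier import ifft2c
from .masks import SamplingMask
from .phantom import CoilMaps

__all__ = [
    "CalibrationError",
    "GrappaKernel",
    "espirit_maps",
    "grappa_fit_kernel",
    "grappa_reconstruct",
]


class CalibrationError(RuntimeError):
    """Raised when a kernel/map fit is degenerate or underdetermined."""


# --------------------------------------------------------------------------
# ESPIRiT
# --------------------------------------------------------------------------


def _calib_block(kspace: np.ndarray, calib_size: int) -> np.ndarray:
    nc, npe, nro = kspace.shape
    cpe, cro = min(calib_size, npe), min(calib_size, nro)
    p0 = npe // 2 - cpe // 2
    r0 = nro // 2 - cro // 2
    return kspace[:, p0 : p0 + cpe, r0 : r0 + cro]


def espirit_maps(
    kspace: np.ndarray,
    calib_size: int = 24,
    kernel_size: int = 5,
    n_maps: int = 1,
    sv_thresh: float = 0.02,
) -> CoilMaps:
    """Estimate coil sensitivity maps from the fully sampled k-space center.

    Parameters
    ----------
    kspace:
        Multicoil 2-D k-space ``(n_coils, n_pe, n_ro)``; the central
        ``calib_size`` x ``calib_size`` block must be fully sampled.
    calib_size, kernel_size:
        Calibration block edge and sliding-kernel edge (defaults 24 and 5).
    n_maps:
        Number of eigenvector sets to compute; only the dominant one is
        returned as the sensitivity map.
    sv_thresh:
        Relative singular-value cutoff for the calibration-matrix row space.

    Returns maps defined on the full grid (background is NOT cropped to
    zero), unit norm per pixel, phase referenced to the first coil.
    """
    kspace = np.asarray(kspace, dtype=complex)
    if kspace.ndim != 3:
        raise ValueError("kspace must be (n_coils, n_pe, n_ro)")
    nc, ny, nx = kspace.shape
    calib = _calib_block(kspace, calib_size)
    line_energy = (np.abs(calib) ** 2).sum(axis=(0, 2))
    if np.any(line_energy == 0):
        raise ValueError("calibration region is not fully sampled")
    k = kernel_size
    if calib.shape[1] < k or calib.shape[2] < k:
        raise ValueError("calibration block smaller than the kernel")

    # block-Hankel calibration matrix: one row per kernel-sized window
    win = sliding_window_view(calib, (k, k), axis=(1, 2))  # (nc, wy, wx, k, k)
    hankel = win.transpose(1, 2, 0, 3, 4).reshape(-1, nc * k * k)
    _, svals, vh = np.linalg.svd(hankel, full_matrices=False)
    if svals[0] == 0:
        raise CalibrationError("all-zero calibration data")
    kernels = vh[svals >= sv_thresh * svals[0]].reshape(-1, nc, k, k)

    # kernels to image space: centered zero-padding + inverse FFT.  The
    # spatial axes are conjugate-flipped so the per-pixel operator acts on
    # the sensitivity vector itself rather than its mirror image.
    padded = np.zeros((kernels.shape[0], nc, ny, nx), dtype=complex)
    p0, r0 = ny // 2 - k // 2, nx // 2 - k // 2
    padded[:, :, p0 : p0 + k, r0 : r0 + k] = np.conj(kernels[:, :, ::-1, ::-1])
    gimg = ifft2c(padded)

    # per-pixel nc x nc operator; dominant eigenvectors are the maps
    m = np.einsum("rcyx,rdyx->yxcd", np.conj(gimg), gimg)
    eigvals, eigvecs = np.linalg.eigh(m)
    sel = eigvecs[..., -1 : -(n_maps + 1) : -1]  # (ny, nx, nc, n_maps) dominant first
    maps = np.moveaxis(sel[..., 0], -1, 0)

    # per-pixel phase convention: first coil real-nonnegative
    ref = maps[0]
    phase = np.where(np.abs(ref) > 0, ref / np.maximum(np.abs(ref), 1e-30), 1.0)
    maps = maps * np.conj(phase)[None]
    return CoilMaps(maps, nc, normalized=True)


# --------------------------------------------------------------------------
# GRAPPA
# --------------------------------------------------------------------------

_RO_OFF = np.arange(-2, 3)  # 5 readout columns


@dataclass
class GrappaKernel:
    """GRAPPA interpolation weights for one equidistant acceleration.

    ``weights[d]`` maps the flattened source neighborhood (coil x source-line
    x readout-offset, C-order) to all target coils for the missing line at
    offset ``d`` above the nearest sampled grid line.
    """

    weights: dict[int, np.ndarray]
    accel: int
    n_src_pe: int = 4
    n_src_ro: int = 5

    def __post_init__(self) -> None:
        for w in self.weights.values():
            if not np.all(np.isfinite(w)):
                raise ValueError("kernel weights must be finite")


def acs_phase_of(mask: SamplingMask) -> int:
    """Grid alignment of a mask's ACS block for `grappa_fit_kernel`."""
    return int((mask.acs_start - mask.n_pe // 2) % mask.accel)


def _src_offsets(d: int, accel: int, n_src_pe: int) -> np.ndarray:
    """Sampled-line offsets relative to a target missing line at offset d."""
    jbs = np.arange(n_src_pe) - (n_src_pe // 2 - 1)
    return -d + accel * jbs


def grappa_fit_kernel(
    acs_block: np.ndarray,
    accel: int,
    n_src_pe: int = 4,
    n_src_ro: int = 5,
    tikhonov: float = 1e-12,
    acs_phase: int | None = None,
) -> GrappaKernel:
    """Least-squares fit of GRAPPA weights over ACS sliding windows.

    For each missing-line offset ``d`` in ``1..accel-1``, targets are taken at
    ACS positions whose full source neighborhood lies inside the block, and
    the weights solve ``min ||S w - t||^2 + tau ||w||^2`` with
    ``tau = tikhonov * trace(S^H S) / n_features``.

    ``acs_phase`` aligns the calibration windows with the equidistant grid:
    it is the value of ``(absolute_pe_index - n_pe//2) mod accel`` for the
    first ACS row, and restricts the fit of offset ``d`` to targets whose
    sources sit exactly on grid lines (the geometry actually used when
    filling).  With ``None`` every sliding position is used (the classic
    shift-invariant calibration), which is equivalent for smooth coil
    correlations but not exact for pattern-aligned data.
    """
    acs = np.asarray(acs_block, dtype=complex)
    if acs.ndim != 3:
        raise ValueError("acs_block must be (n_coils, n_acs, n_ro)")
    if accel < 2:
        raise ValueError("accel must be >= 2 for interpolation")
    if not np.any(acs):
        raise CalibrationError("all-zero ACS block")
    nc, na, nro = acs.shape
    if n_src_ro != _RO_OFF.size:
        raise ValueError("only 5 readout source columns are supported")
    rs = np.arange(2, nro - 2)
    weights: dict[int, np.ndarray] = {}
    for d in range(1, accel):
        off = _src_offsets(d, accel, n_src_pe)
        t_lo, t_hi = -off.min(), na - off.max()
        ts = np.arange(t_lo, t_hi)
        if acs_phase is not None:
            ts = ts[(acs_phase + ts) % accel == d]
        n_feat = nc * n_src_pe * n_src_ro
        if ts.size * rs.size < n_feat:
            raise CalibrationError(
                f"too few ACS windows ({ts.size * rs.size}) for {n_feat} weights"
            )
        # sources: (nc, T, n_src_pe, R, n_src_ro) -> rows (T*R, features)
        src = acs[:, ts[:, None] + off, :][..., rs[:, None] + _RO_OFF]
        s_mat = src.transpose(1, 3, 0, 2, 4).reshape(ts.size * rs.size, n_feat)
        t_mat = acs[:, ts, :][:, :, rs].transpose(1, 2, 0).reshape(-1, nc)
        shs = s_mat.conj().T @ s_mat
        tau = tikhonov * np.real(np.trace(shs)) / n_feat
        w = np.linalg.solve(
            shs + tau * np.eye(n_feat), s_mat.conj().T @ t_mat
        )
        weights[d] = w
    return GrappaKernel(weights, accel, n_src_pe, n_src_ro)


def grappa_reconstruct(
    kslice: np.ndarray, mask: SamplingMask, kernel: GrappaKernel
) -> np.ndarray:
    """Fill the missing PE lines of an undersampled slice with GRAPPA.

    Measured lines (including ACS) are copied through unchanged.  Source
    positions outside the grid contribute zero (zero-padded boundaries in
    both PE and readout).
    """
    data = np.asarray(kslice, dtype=complex)
    if data.ndim != 3 or data.shape[1] != mask.n_pe:
        raise ValueError("kslice must be (n_coils, n_pe, n_ro) matching the mask")
    if kernel.accel != mask.accel:
        raise ValueError(
            f"kernel accel {kernel.accel} does not match mask accel {mask.accel}"
        )
    nc, npe, nro = data.shape
    accel = kernel.accel
    center = npe // 2
    out = data.copy()
    sampled = set(mask.sampled.tolist())

    pad_pe = 2 * accel + accel  # covers all source offsets
    padded = np.zeros((nc, npe + 2 * pad_pe, nro + 4), dtype=complex)
    padded[:, pad_pe : pad_pe + npe, 2 : 2 + nro] = data

    for t in range(npe):
        if t in sampled:
            continue
        d = int((t - center) % accel)
        if d == 0:
            # on the equidistant grid but unmeasured: no kernel for it
            raise ValueError("mask is not consistent with the kernel geometry")
        off = _src_offsets(d, accel, kernel.n_src_pe)
        feat = np.empty((nc, kernel.n_src_pe, 5, nro), dtype=complex)
        for j, o in enumerate(off):
            row = padded[:, pad_pe + t + o, :]
            for r, ro in enumerate(_RO_OFF):
                feat[:, j, r, :] = row[:, 2 + ro : 2 + ro + nro]
        s_line = feat.reshape(-1, nro)
        out[:, t, :] = kernel.weights[d].T @ s_line  # (nc, nro)
    return out
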
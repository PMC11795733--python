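"""Synthetic MRCP-like phantoms, coil sensitivities, and noisy acquisitions.

MRCP contrast is heavily T2-weighted: fluid-filled bile and pancreatic ducts
appear as bright, thin, curvilinear structures on a strongly suppressed soft
tissue background.  The phantom emulates exactly that geometry — random-walk
duct centerlines with a Gaussian cross-section laid over a dim elliptical
"body" — plus a smooth random phase, so every reconstruction stage can be
exercised without measured data.  Coil sensitivities are smooth complex
Gaussian lobes centered on a ring around the FOV (body/spine array class
hardware), normalized to unit root-sum-of-squares.  Acquisition follows the
forward model y = Ex + n with i.i.d. complex Gaussian noise applied on the
sampled lines only; the low-field (0.55 T) regime is emulated purely by a
larger noise level.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .fourier import fft2c
from .masks import SamplingMask, apply_mask, make_full_mask

__all__ = [
    "PhantomImage",
    "CoilMaps",
    "AcquisitionSim",
    "make_duct_phantom",
    "simulate_coil_maps",
    "simulate_acquisition",
    "NOISE_SIGMA_HIGH_FIELD",
    "NOISE_SIGMA_LOW_FIELD",
]

# Noise std (per real/imag component, k-space units of an orthonormal FFT of a
# unit-intensity duct) for the two emulated field-strength regimes.  0.02
# corresponds to a duct-to-noise ratio of ~50 in the coil-combined image
# (a clean 3 T-like scan); the low-field value is 4x noisier.
NOISE_SIGMA_HIGH_FIELD = 0.02
NOISE_SIGMA_LOW_FIELD = 0.08


@dataclass
class PhantomImage:
    """Complex ground-truth image with duct/background bookkeeping masks."""

    pixels: np.ndarray
    ny: int
    nx: int
    seed: int
    duct_mask: np.ndarray = field(repr=False, default=None)
    body_mask: np.ndarray = field(repr=False, default=None)


@dataclass
class CoilMaps:
    """Per-coil complex sensitivity profiles, shape ``(n_coils, ny, nx)``."""

    maps: np.ndarray
    n_coils: int
    normalized: bool = True


@dataclass
class AcquisitionSim:
    """Simulated noisy undersampled multicoil k-space of one slice."""

    kspace: np.ndarray
    noise_sigma: float
    mask: SamplingMask
    seed: int


def _random_walk_duct(rng: np.random.Generator, ny: int, nx: int) -> np.ndarray:
    """Centerline indicator of one duct: a smooth random walk across the grid."""
    line = np.zeros((ny, nx))
    # start somewhere in the central body region, heading in a random direction
    y = rng.uniform(0.25 * ny, 0.75 * ny)
    x = rng.uniform(0.25 * nx, 0.75 * nx)
    angle = rng.uniform(0, 2 * np.pi)
    n_steps = int(1.5 * max(ny, nx))
    for _ in range(n_steps):
        iy, ix = int(round(y)), int(round(x))
        if 0 <= iy < ny and 0 <= ix < nx:
            line[iy, ix] = 1.0
        angle += rng.normal(0.0, 0.18)  # gentle curvature
        y += np.sin(angle)
        x += np.cos(angle)
        if not (-0.1 * ny < y < 1.1 * ny and -0.1 * nx < x < 1.1 * nx):
            break
    return line


def make_duct_phantom(ny: int, nx: int, n_ducts: int, seed: int) -> PhantomImage:
    """Generate a duct phantom: bright curvilinear tubes on a dim body ellipse.

    Ducts are random-walk centerlines smoothed to a Gaussian cross-section
    (~1.2 px sigma) with per-duct peak intensity in [0.85, 1.15]; the
    background ellipse sits at intensity 0.08 with a soft edge, giving a
    duct-to-background contrast of roughly 10:1 at the centerlines (>= 5x
    averaged over the duct mask).  A smooth random phase
    (low-pass-filtered noise) makes the image genuinely complex.
    """
    if ny < 16 or nx < 16:
        raise ValueError("grid must be at least 16x16")
    if n_ducts < 0:
        raise ValueError("n_ducts must be non-negative")
    rng = np.random.default_rng(seed)

    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    r2 = ((yy - cy) / (0.42 * ny)) ** 2 + ((xx - cx) / (0.46 * nx)) ** 2
    body = 1.0 / (1.0 + np.exp((r2 - 1.0) * 12.0))  # soft-edged ellipse
    body_mask = r2 <= 1.0

    ducts = np.zeros((ny, nx))
    for _ in range(n_ducts):
        center = _random_walk_duct(rng, ny, nx)
        tube = gaussian_filter(center, sigma=1.2)
        peak = tube.max()
        if peak > 0:
            ducts = np.maximum(ducts, tube / peak * rng.uniform(0.85, 1.15))
    # bookkeeping mask covers the rendered-bright duct region only (ducts
    # fade with the body edge, so wandering segments outside it don't count)
    duct_mask = (ducts > 0.35) & (body > 0.5)

    magnitude = 0.08 * body + ducts * body  # ducts fade with the body edge
    phase = gaussian_filter(rng.standard_normal((ny, nx)), sigma=max(ny, nx) / 8)
    peak_phase = np.abs(phase).max()
    if peak_phase > 0:
        phase = phase / peak_phase * 0.5  # +-0.5 rad, smooth
    pixels = magnitude * np.exp(1j * phase)
    return PhantomImage(pixels, ny, nx, seed, duct_mask, body_mask & ~duct_mask)


def simulate_coil_maps(ny: int, nx: int, n_coils: int, seed: int) -> CoilMaps:
    """Smooth complex coil sensitivities, unit root-sum-of-squares per pixel.

    Each coil is a broad Gaussian lobe centered on a ring around the grid with
    a random low-order polynomial phase; RSS normalization makes the profiles
    directly usable as ideal sensitivity maps.
    """
    if ny < 1 or nx < 1:
        raise ValueError("grid dimensions must be positive")
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    radius = 0.55 * min(ny, nx)
    sigma = 0.6 * min(ny, nx)
    maps = np.empty((n_coils, ny, nx), dtype=complex)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils + rng.normal(0, 0.1)
        my = cy + radius * np.sin(ang)
        mx = cx + radius * np.cos(ang)
        mag = np.exp(-(((yy - my) ** 2 + (xx - mx) ** 2) / (2 * sigma**2)))
        u, v = (yy - cy) / ny, (xx - cx) / nx
        phase = (
            rng.uniform(-np.pi, np.pi)
            + rng.normal(0, 1.5) * u
            + rng.normal(0, 1.5) * v
            + rng.normal(0, 1.0) * u * v
        )
        maps[c] = mag * np.exp(1j * phase)
    rss = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    maps /= np.maximum(rss, 1e-30)
    return CoilMaps(maps, n_coils, normalized=True)


def simulate_acquisition(
    phantom: PhantomImage,
    maps: CoilMaps,
    mask: SamplingMask | None,
    noise_sigma: float,
    seed: int,
) -> AcquisitionSim:
    """Simulate y = Ex + n for one slice.

    The forward model multiplies the phantom by each coil map, applies the
    centered orthonormal 2-D FFT, masks unsampled PE lines to exactly zero,
    and adds i.i.d. complex Gaussian noise (std ``noise_sigma`` per real and
    imaginary component) on the sampled lines only.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    ny, nx = phantom.pixels.shape
    if maps.maps.shape[1:] != (ny, nx):
        raise ValueError("coil maps and phantom shapes differ")
    if mask is None:
        mask = make_full_mask(ny)
    if mask.n_pe != ny:
        raise ValueError("mask length and phantom PE dimension differ")
    kspace = fft2c(maps.maps * phantom.pixels[None])
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = noise_sigma * (
            rng.standard_normal(kspace.shape) + 1j * rng.standard_normal(kspace.shape)
        )
        kspace = kspace + noise
    kspace = apply_mask(kspace, mask)
    return AcquisitionSim(kspace, noise_sigma, mask, seed)
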
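"""Centered, orthonormal FFT helpers.

One transform convention is used throughout the package: the image origin is
at the grid center, k-space DC is at the grid center, and all transforms are
orthonormal (``norm="ortho"``), so Parseval's identity holds exactly and
regularization weights are scale-stable.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as _fft

__all__ = ["fft2c", "ifft2c", "fftnc", "ifftnc"]


def fft2c(x: np.ndarray, axes: tuple[int, int] = (-2, -1)) -> np.ndarray:
    """Centered orthonormal 2-D FFT over ``axes``."""
    return _fft.fftshift(
        _fft.fft2(_fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"), axes=axes
    )


def ifft2c(x: np.ndarray, axes: tuple[int, int] = (-2, -1)) -> np.ndarray:
    """Centered orthonormal 2-D inverse FFT over ``axes``."""
    return _fft.fftshift(
        _fft.ifft2(_fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"), axes=axes
    )


def fftnc(x: np.ndarray, axis: int) -> np.ndarray:
    """Centered orthonormal 1-D FFT along ``axis``."""
    return _fft.fftshift(
        _fft.fft(_fft.ifftshift(x, axes=axis), axis=axis, norm="ortho"), axes=axis
    )


def ifftnc(x: np.ndarray, axis: int) -> np.ndarray:
    """Centered orthonormal 1-D inverse FFT along ``axis``."""
    return _fft.fftshift(
        _fft.ifft(_fft.ifftshift(x, axes=axis), axis=axis, norm="ortho"), axes=axis
    )
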
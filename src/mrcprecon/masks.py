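"""Cartesian phase-encode sampling masks.

Masks select phase-encode (PE) lines of a 2-D k-space slice.  The scanner
protocol emulated here uses regular equidistant undersampling along PE with a
fully sampled, centered block of autocalibration (ACS) lines; higher nominal
accelerations are obtained retrospectively by dropping lines from a measured
equidistant acquisition while keeping the ACS block intact, so the
high-acceleration sampled set nests inside the low-acceleration one.

Conventions: 0-based PE indices; the ACS block is the half-open, centered
range ``[n_pe//2 - n_acs//2, n_pe//2 + n_acs//2)``; the equidistant grid is
anchored so the central line ``n_pe//2`` (DC after centered FFT) is sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SamplingMask",
    "make_equidistant_mask",
    "make_full_mask",
    "retrospective_undersample",
    "apply_mask",
]


@dataclass(frozen=True)
class SamplingMask:
    """Set of sampled phase-encode line indices with ACS annotation.

    Parameters
    ----------
    n_pe:
        Number of phase-encode lines of the grid.
    sampled:
        Sorted array of sampled 0-based PE indices.
    acs_start, acs_stop:
        Half-open range of the fully sampled ACS block (``acs_start ==
        acs_stop`` means no ACS annotation).
    accel:
        Nominal acceleration factor R (bookkeeping only).
    """

    n_pe: int
    sampled: np.ndarray
    acs_start: int = 0
    acs_stop: int = 0
    accel: int = 1

    def __post_init__(self) -> None:
        sampled = np.unique(np.asarray(self.sampled, dtype=np.intp))
        object.__setattr__(self, "sampled", sampled)
        if self.n_pe < 1:
            raise ValueError("n_pe must be positive")
        if sampled.size and (sampled[0] < 0 or sampled[-1] >= self.n_pe):
            raise ValueError("sampled indices out of range [0, n_pe)")
        if not 0 <= self.acs_start <= self.acs_stop <= self.n_pe:
            raise ValueError("invalid ACS range")
        acs = np.arange(self.acs_start, self.acs_stop)
        if acs.size and not np.isin(acs, sampled).all():
            raise ValueError("ACS block must be a subset of sampled lines")

    @property
    def acs(self) -> np.ndarray:
        """Indices of the ACS block."""
        return np.arange(self.acs_start, self.acs_stop, dtype=np.intp)

    @property
    def n_acs(self) -> int:
        return self.acs_stop - self.acs_start

    @property
    def n_sampled(self) -> int:
        return int(self.sampled.size)

    def bool_array(self) -> np.ndarray:
        """Dense boolean PE-line indicator of length ``n_pe``."""
        out = np.zeros(self.n_pe, dtype=bool)
        out[self.sampled] = True
        return out

    def is_full(self) -> bool:
        return self.n_sampled == self.n_pe

    def same_lines(self, other: "SamplingMask") -> bool:
        return self.n_pe == other.n_pe and np.array_equal(self.sampled, other.sampled)


def make_full_mask(n_pe: int) -> SamplingMask:
    """Fully sampled mask (R = 1, no ACS annotation)."""
    return SamplingMask(n_pe, np.arange(n_pe), 0, n_pe, accel=1)


def make_equidistant_mask(n_pe: int, accel: int, n_acs: int) -> SamplingMask:
    """Equidistant PE undersampling with a centered ACS block.

    The equidistant grid contains every ``accel``-th line with the offset
    chosen so the central line ``n_pe//2`` lies on the grid; the ACS block
    ``[n_pe//2 - n_acs//2, n_pe//2 + n_acs//2)`` is added on top.
    """
    if n_pe < 1:
        raise ValueError("n_pe must be positive")
    if accel < 1:
        raise ValueError("accel must be >= 1")
    if accel > n_pe:
        raise ValueError("accel exceeds the number of phase-encode lines")
    if not 0 <= n_acs <= n_pe:
        raise ValueError("n_acs must lie in [0, n_pe]")
    center = n_pe // 2
    grid = np.arange(center % accel, n_pe, accel)
    acs_start = center - n_acs // 2
    acs_stop = acs_start + n_acs
    sampled = np.union1d(grid, np.arange(acs_start, acs_stop))
    return SamplingMask(n_pe, sampled, acs_start, acs_stop, accel=accel)


def retrospective_undersample(mask2: SamplingMask, extra: int) -> SamplingMask:
    """Drop lines from an equidistant acquisition to raise R by ``extra``.

    Keeps every ``extra``-th line of the equidistant grid (phase anchored at
    the central line) plus the full ACS block, mirroring how a measured R=2
    scan is retrospectively turned into an R=6 input.  The result's sampled
    set is a subset of ``mask2.sampled``.
    """
    if extra < 1:
        raise ValueError("extra must be >= 1")
    if extra == 1:
        return mask2
    center = mask2.n_pe // 2
    new_accel = mask2.accel * extra
    keep = mask2.sampled[(mask2.sampled - center) % new_accel == 0]
    sampled = np.union1d(keep, mask2.acs)
    return SamplingMask(
        mask2.n_pe, sampled, mask2.acs_start, mask2.acs_stop, accel=new_accel
    )


def apply_mask(kspace: np.ndarray, mask: SamplingMask) -> np.ndarray:
    """Zero the unsampled PE lines of ``kspace`` (PE on axis -2).

    Sampled lines are copied through untouched; the operation is a projection
    (applying it twice equals applying it once).
    """
    kspace = np.asarray(kspace)
    if kspace.shape[-2] != mask.n_pe:
        raise ValueError(
            f"kspace has {kspace.shape[-2]} PE lines, mask expects {mask.n_pe}"
        )
    out = np.zeros_like(kspace)
    out[..., mask.sampled, :] = kspace[..., mask.sampled, :]
    return out
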
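"""Volumetric image-quality metrics and the paired significance test.

PSNR and SSIM are computed on magnitude volumes (stacks of absolute-valued
2-D reconstructions).  PSNR uses the reference volume's maximum as the peak,
so different methods compared against one reference share a scale.  SSIM is
the standard Gaussian-windowed formulation (7x7 window, sigma 1.5, K1=0.01,
K2=0.03, data range = reference maximum) averaged over slices.  Line-profile
similarity is quantified with the Pearson product-moment correlation
coefficient (PPMCC), and paired method comparisons use the exact one-sided
Wilcoxon signed-rank test (alternative: first method larger).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve
from scipy.stats import rankdata

__all__ = [
    "psnr_volume",
    "ssim_volume",
    "ssim_slice",
    "mip",
    "line_profile",
    "ppmcc",
    "wilcoxon_one_sided",
    "MetricsReport",
]


def _as_volume(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3:
        raise ValueError("expected a 2-D image or 3-D volume")
    return x


def psnr_volume(test, ref) -> float:
    """Peak signal-to-noise ratio in dB, peak taken from the reference.

    ``20 log10(max(ref) / RMSE)``; returns ``inf`` when the volumes agree
    exactly.  Note PSNR is not symmetric in its arguments.
    """
    test, ref = _as_volume(test), _as_volume(ref)
    if test.shape != ref.shape:
        raise ValueError("volumes must share a shape")
    peak = float(ref.max())
    if peak <= 0:
        raise ValueError("reference volume must not be identically zero")
    mse = float(((test - ref) ** 2).mean())
    if mse == 0:
        return float("inf")
    return 20.0 * np.log10(peak / np.sqrt(mse))


def _gaussian_window(size: int = 7, sigma: float = 1.5) -> np.ndarray:
    ax = np.arange(size) - size // 2
    g = np.exp(-(ax**2) / (2 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def ssim_slice(test: np.ndarray, ref: np.ndarray, data_range: float,
               win_size: int = 7, sigma: float = 1.5) -> float:
    """Mean SSIM of one 2-D slice pair (Gaussian window, reflective borders).

    The window-radius border is excluded from the average, mirroring the
    standard windowed formulation.
    """
    test = np.asarray(test, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if test.shape != ref.shape:
        raise ValueError("slices must share a shape")
    if min(test.shape) < win_size:
        raise ValueError("slice smaller than the SSIM window")
    w = _gaussian_window(win_size, sigma)

    def filt(x):
        return convolve(x, w, mode="reflect")

    mu_t, mu_r = filt(test), filt(ref)
    var_t = filt(test * test) - mu_t**2
    var_r = filt(ref * ref) - mu_r**2
    cov = filt(test * ref) - mu_t * mu_r
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    ssim_map = ((2 * mu_t * mu_r + c1) * (2 * cov + c2)) / (
        (mu_t**2 + mu_r**2 + c1) * (var_t + var_r + c2)
    )
    pad = win_size // 2
    core = ssim_map[pad:-pad, pad:-pad] if pad else ssim_map
    return float(core.mean())


def ssim_volume(test, ref) -> float:
    """Mean per-slice SSIM over a magnitude volume stack (fraction in [-1, 1])."""
    test, ref = _as_volume(test), _as_volume(ref)
    if test.shape != ref.shape:
        raise ValueError("volumes must share a shape")
    data_range = float(ref.max())
    if data_range == 0:
        data_range = 1.0  # stability constants then dominate; SSIM of 0 vs 0 is 1
    return float(
        np.mean([ssim_slice(t, r, data_range) for t, r in zip(test, ref)])
    )


def mip(volume, axis: int = 0) -> np.ndarray:
    """Maximum intensity projection along ``axis``."""
    return np.max(np.asarray(volume), axis=axis)


def line_profile(image, path) -> np.ndarray:
    """Sample intensities at ordered integer pixel coordinates.

    ``path`` is ``(n_points, ndim)`` matching the array's dimensionality.
    """
    image = np.asarray(image)
    path = np.atleast_2d(np.asarray(path, dtype=int))
    if path.shape[1] != image.ndim:
        raise ValueError("path coordinates do not match image dimensionality")
    for d in range(image.ndim):
        if (path[:, d] < 0).any() or (path[:, d] >= image.shape[d]).any():
            raise ValueError("path coordinate out of bounds")
    return image[tuple(path.T)]


def ppmcc(a, b) -> float:
    """Pearson product-moment correlation between two intensity profiles."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("profiles must be equal-length 1-D with >= 2 samples")
    da, db = a - a.mean(), b - b.mean()
    na, nb = np.linalg.norm(da), np.linalg.norm(db)
    if na == 0 or nb == 0:
        raise ValueError("profiles must have nonzero variance")
    return float(np.clip((da @ db) / (na * nb), -1.0, 1.0))


def wilcoxon_one_sided(a, b) -> float:
    """Exact one-sided Wilcoxon signed-rank p-value (alternative: a > b).

    Zero differences are dropped; tied absolute differences get average ranks.
    The null distribution of the positive-rank sum is enumerated exactly via
    its generating function (ranks doubled so averaged ranks stay integer),
    equivalent to enumerating all 2^n sign patterns.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n < 1:
        raise ValueError("all paired differences are zero")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    r2 = np.rint(2 * ranks).astype(int)  # doubled ranks are exact integers
    total = int(r2.sum())
    # generating function product over (1 + x^r): counts of each rank-sum
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    top = 0
    for r in r2:
        counts[r : top + r + 1] += counts[: top + 1]
        top += r
    thresh = int(np.rint(2 * w_plus))
    p = counts[thresh:].sum() / counts.sum()
    return float(min(max(p, np.finfo(float).tiny), 1.0))


@dataclass
class MetricsReport:
    """Per-volume metrics for several methods against one reference.

    ``psnr`` / ``ssim`` map method name -> list of per-volume values;
    ``ppmcc`` maps method name -> list of per-profile correlations;
    ``p_values`` maps "method_a>method_b" -> one-sided Wilcoxon p.
    """

    reference: str
    psnr: dict = field(default_factory=dict)
    ssim: dict = field(default_factory=dict)
    ppmcc: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)

    def summary(self) -> dict:
        """Mean +- SD per method (SSIM reported in percent)."""
        out: dict = {"reference": self.reference}
        for name, table in (("psnr_db", self.psnr), ("ssim_pct", self.ssim)):
            scale = 100.0 if name == "ssim_pct" else 1.0
            out[name] = {
                m: {
                    "mean": float(np.mean(v)) * scale,
                    "sd": float(np.std(v, ddof=1)) * scale if len(v) > 1 else 0.0,
                }
                for m, v in sorted(table.items())
            }
        if self.ppmcc:
            out["ppmcc"] = {m: list(map(float, v)) for m, v in sorted(self.ppmcc.items())}
        if self.p_values:
            out["p_values"] = {k: float(v) for k, v in sorted(self.p_values.items())}
        return out

    def to_json(self) -> str:
        """Deterministic JSON rendering (same inputs -> identical bytes)."""
        full = {
            "summary": self.summary(),
            "per_volume": {
                "psnr_db": {m: list(map(float, v)) for m, v in sorted(self.psnr.items())},
                "ssim": {m: list(map(float, v)) for m, v in sorted(self.ssim.items())},
            },
        }
        return json.dumps(full, indent=2, sort_keys=True)

    def to_csv(self) -> str:
        """Per-volume CSV: method, volume index, PSNR (dB), SSIM (%)."""
        lines = ["method,volume,psnr_db,ssim_pct"]
        for m in sorted(self.psnr):
            for i, (p, s) in enumerate(zip(self.psnr[m], self.ssim.get(m, []))):
                lines.append(f"{m},{i},{p:.6f},{100 * s:.6f}")
        return "\n".join(lines) + "\n"
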
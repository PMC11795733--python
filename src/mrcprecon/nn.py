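"""Minimal NumPy neural-network engine for the unrolled regularizer.

Implements exactly what the reconstruction needs — 2-D "same" convolutions
with zero padding, ReLU, a residual CNN, and Adam — with hand-derived exact
backpropagation.  Convolutions are evaluated as a single GEMM per layer via
im2col, which is the fastest route available on a plain CPU BLAS; float32 is
the default compute precision (float64 is used by the gradient-check tests).

The regularizer network maps a 2-channel (real, imaginary) image to an image
of the same shape:

    h = conv_in(x); h <- h + s * conv2(relu(conv1(h)))  [n_blocks times]
    out = x + conv_out(h)

With all weights zero the network is exactly the identity, so an untrained
(zeroed) model leaves its input untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ResNetConfig", "ResNetRegularizer", "Adam", "clip_grad_norm"]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(C, H, W) -> (C*k*k, H*W) patch matrix with zero 'same' padding."""
    c, h, w = x.shape
    p = k // 2
    xp = np.zeros((c, h + 2 * p, w + 2 * p), dtype=x.dtype)
    xp[:, p : p + h, p : p + w] = x
    v = sliding_window_view(xp, (k, k), axis=(1, 2))  # (C, H, W, k, k)
    return v.transpose(0, 3, 4, 1, 2).reshape(c * k * k, h * w)


def _conv_forward(x, w, b):
    """x (Cin,H,W), w (Cout,Cin,k,k) -> y (Cout,H,W); returns (y, cols)."""
    cout, cin, k, _ = w.shape
    h, wd = x.shape[1:]
    cols = _im2col(x, k)
    y = w.reshape(cout, -1) @ cols
    if b is not None:
        y += b[:, None]
    return y.reshape(cout, h, wd), cols


def _conv_backward(gout, x_shape, w, cols):
    """Gradients of a 'same' zero-padded convolution.

    Returns (gx, gw, gb).  gx is computed as a convolution of the output
    gradient with the spatially flipped, in/out-transposed weights, which is
    exact for zero padding.
    """
    cout, cin, k, _ = w.shape
    h, wd = x_shape[1:]
    g2 = gout.reshape(cout, -1)
    gw = (g2 @ cols.T).reshape(w.shape)
    gb = g2.sum(axis=1)
    w_flip = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Cin, Cout, k, k)
    gx, _ = _conv_forward(gout, np.ascontiguousarray(w_flip), None)
    return gx, gw, gb


@dataclass
class ResNetConfig:
    """Architecture of the learned regularizer.

    ``n_blocks`` residual blocks of two ``kernel_extent`` x ``kernel_extent``
    convolutions with ``channels`` feature maps; each block's output is scaled
    by ``residual_scale`` before the skip addition (stabilizes deep unrolled
    training).
    """

    n_blocks: int = 8
    channels: int = 64
    kernel_extent: int = 3
    residual_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.kernel_extent % 2 != 1:
            raise ValueError("kernel_extent must be odd")


class ResNetRegularizer:
    """Residual CNN denoiser on 2-channel (real, imaginary) images."""

    def __init__(
        self,
        config: ResNetConfig | None = None,
        seed: int = 0,
        dtype=np.float32,
        zero_init: bool = False,
    ):
        self.config = config or ResNetConfig()
        self.dtype = np.dtype(dtype)
        self.seed = seed
        rng = np.random.default_rng(seed)
        c, k = self.config.channels, self.config.kernel_extent
        self.params: list[np.ndarray] = []

        def conv_init(cout, cin):
            if zero_init:
                w = np.zeros((cout, cin, k, k), dtype=self.dtype)
            else:
                std = np.sqrt(2.0 / (cin * k * k))
                w = rng.normal(0, std, (cout, cin, k, k)).astype(self.dtype)
            self.params.append(w)
            self.params.append(np.zeros(cout, dtype=self.dtype))

        conv_init(c, 2)
        for _ in range(self.config.n_blocks):
            conv_init(c, c)
            conv_init(c, c)
        conv_init(2, c)

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def forward(self, x2: np.ndarray, want_cache: bool = False):
        """x2 (2, H, W) -> (2, H, W); optionally returns the backprop cache."""
        x2 = np.ascontiguousarray(x2, dtype=self.dtype)
        p = self.params
        rs = self.dtype.type(self.config.residual_scale)
        cache: list = []
        h, cols_in = _conv_forward(x2, p[0], p[1])
        cache.append((x2.shape, cols_in))
        i = 2
        for _ in range(self.config.n_blocks):
            u, cols1 = _conv_forward(h, p[i], p[i + 1])
            a = np.maximum(u, 0)
            v, cols2 = _conv_forward(a, p[i + 2], p[i + 3])
            cache.append((h.shape, cols1, u > 0, a.shape, cols2))
            h = h + rs * v
            i += 4
        out, cols_out = _conv_forward(h, p[i], p[i + 1])
        cache.append((h.shape, cols_out))
        out = x2 + out
        if want_cache:
            return out, cache
        return out

    def backward(self, gout: np.ndarray, cache: list):
        """Backpropagate; returns (gx, grads) with grads aligned to params."""
        gout = np.ascontiguousarray(gout, dtype=self.dtype)
        p = self.params
        rs = self.dtype.type(self.config.residual_scale)
        grads: list[np.ndarray | None] = [None] * len(p)
        i = len(p) - 2
        h_shape, cols_out = cache[-1]
        gh, grads[i], grads[i + 1] = _conv_backward(gout, h_shape, p[i], cols_out)
        gx = gout  # global skip
        i -= 4
        for blk in range(self.config.n_blocks - 1, -1, -1):
            h_shape, cols1, relu_mask, a_shape, cols2 = cache[1 + blk]
            gv = rs * gh
            ga, grads[i + 2], grads[i + 3] = _conv_backward(gv, a_shape, p[i + 2], cols2)
            gu = ga * relu_mask
            gh1, grads[i], grads[i + 1] = _conv_backward(gu, h_shape, p[i], cols1)
            gh = gh + gh1
            i -= 4
        x_shape, cols_in = cache[0]
        gx_in, grads[0], grads[1] = _conv_backward(gh, x_shape, p[0], cols_in)
        return gx + gx_in, grads

    def state_dict(self) -> dict:
        return {
            "params": [p.copy() for p in self.params],
            "config": self.config,
            "seed": self.seed,
            "dtype": self.dtype.str,
        }


class Adam:
    """Adam optimizer over a list of arrays (updates in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 3e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in params]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            g64 = np.asarray(g, dtype=np.float64)
            m *= self.b1
            m += (1 - self.b1) * g64
            v *= self.b2
            v += (1 - self.b2) * g64 * g64
            p -= (self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(p.dtype)


def clip_grad_norm(grads: list[np.ndarray], max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is at most max_norm."""
    total = float(np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads)))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for g in grads:
            g *= scale
    return total
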
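"""Scikit-learn style estimator interface to the reconstructors.

Each estimator consumes a list of undersampled multicoil 2-D k-space slices
(all sharing one sampling mask) and produces complex images.  ``fit`` runs
the method's calibration/learning stage — ESPIRiT map estimation for the
classical methods, GRAPPA kernel fitting, or full network training for the
unrolled model — and sets trailing-underscore attributes; ``predict``
reconstructs.  All classes follow the sklearn estimator contract
(``get_params``/``set_params``, clonable, no mutation of constructor args),
so they compose with sklearn model selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .calibration import acs_phase_of, espirit_maps, grappa_fit_kernel, grappa_reconstruct
from .classical import cg_sense, cs_wavelet
from .encoding import EncodingOperator, coil_combine
from .fourier import ifft2c
from .masks import SamplingMask
from .nn import ResNetConfig, ResNetRegularizer
from .training import (
    SplitConfig,
    TrainConfig,
    TrainingPair,
    train_ssdu,
    train_supervised,
)
from .unrolled import UnrolledParams, unrolled_reconstruct

__all__ = [
    "ZeroFilledReconstructor",
    "CGSenseReconstructor",
    "WaveletCSReconstructor",
    "GrappaReconstructor",
    "UnrolledReconstructor",
]


class _CalibratedReconstructor(BaseEstimator):
    """Shared fit logic: estimate (or accept) coil maps, build the operator."""

    def __init__(self, mask=None, maps=None, espirit_calib=24, espirit_kernel=5):
        self.mask = mask
        self.maps = maps
        self.espirit_calib = espirit_calib
        self.espirit_kernel = espirit_kernel

    def fit(self, X, y=None):
        X = self._check_x(X)
        if self.maps is not None:
            self.maps_ = np.asarray(self.maps)
        else:
            self.maps_ = espirit_maps(
                X[0], self.espirit_calib, self.espirit_kernel
            ).maps
        self.operator_ = EncodingOperator(self.maps_, self.mask)
        return self

    def _check_x(self, X):
        X = [np.asarray(x) for x in X]
        if not X:
            raise ValueError("X must hold at least one k-space slice")
        for x in X:
            if x.ndim != 3:
                raise ValueError("each element must be (n_coils, n_pe, n_ro)")
        return X

    def _recon_one(self, y):  # pragma: no cover - abstract
        raise NotImplementedError

    def predict(self, X):
        """Reconstruct each slice; returns an array of complex images."""
        if not hasattr(self, "operator_"):
            raise RuntimeError("estimator is not fitted")
        return np.stack([self._recon_one(np.asarray(y)) for y in X])


class ZeroFilledReconstructor(_CalibratedReconstructor):
    """Adjoint (zero-filled) reconstruction; the x0 of the unrolled model."""

    def _recon_one(self, y):
        return self.operator_.adjoint(y)


class CGSenseReconstructor(_CalibratedReconstructor):
    """Iterative parallel imaging (CG-SENSE), lambda = 0.01 by default."""

    def __init__(self, mask=None, maps=None, reg_lambda=0.01, n_iters=30,
                 tol=1e-6, espirit_calib=24, espirit_kernel=5):
        super().__init__(mask, maps, espirit_calib, espirit_kernel)
        self.reg_lambda = reg_lambda
        self.n_iters = n_iters
        self.tol = tol

    def _recon_one(self, y):
        return cg_sense(y, self.operator_, self.reg_lambda, self.n_iters, self.tol).image


class WaveletCSReconstructor(_CalibratedReconstructor):
    """Wavelet-regularized compressed sensing, lambda = 0.008 by default."""

    def __init__(self, mask=None, maps=None, reg_lambda=0.008, n_iters=60,
                 penalty="l1", espirit_calib=24, espirit_kernel=5):
        super().__init__(mask, maps, espirit_calib, espirit_kernel)
        self.reg_lambda = reg_lambda
        self.n_iters = n_iters
        self.penalty = penalty

    def _recon_one(self, y):
        return cs_wavelet(
            y, self.operator_, self.reg_lambda, self.n_iters, self.penalty
        ).image


class GrappaReconstructor(_CalibratedReconstructor):
    """GRAPPA interpolation followed by sensitivity-weighted coil combination."""

    def fit(self, X, y=None):
        super().fit(X, y)
        if self.mask is None:
            raise ValueError("GRAPPA requires an undersampling mask")
        acs = X[0][:, self.mask.acs_start : self.mask.acs_stop, :]
        self.kernel_ = grappa_fit_kernel(
            np.asarray(acs), self.mask.accel, acs_phase=acs_phase_of(self.mask)
        )
        return self

    def _recon_one(self, y):
        filled = grappa_reconstruct(y, self.mask, self.kernel_)
        return coil_combine(self.maps_, ifft2c(filled))


class UnrolledReconstructor(_CalibratedReconstructor):
    """Trainable unrolled model-based reconstruction (supervised or SSDU).

    ``fit(X, y)`` trains the network: ``X`` is the list of undersampled
    k-space slices and ``y`` the matching reference images for
    ``strategy="supervised"`` (ignored for ``strategy="ssdu"``).

    Fitted attributes: ``params_`` (trained weights), ``lambda_`` (learned
    data-consistency weight), ``loss_history_``.
    """

    def __init__(self, mask=None, maps=None, strategy="supervised", n_unrolls=12,
                 n_blocks=8, channels=64, dc_iters=10, epochs=100, lr=3e-4,
                 rho=0.4, sigma_pe=None, random_state=0,
                 espirit_calib=24, espirit_kernel=5):
        super().__init__(mask, maps, espirit_calib, espirit_kernel)
        self.strategy = strategy
        self.n_unrolls = n_unrolls
        self.n_blocks = n_blocks
        self.channels = channels
        self.dc_iters = dc_iters
        self.epochs = epochs
        self.lr = lr
        self.rho = rho
        self.sigma_pe = sigma_pe
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.strategy not in ("supervised", "ssdu"):
            raise ValueError("strategy must be 'supervised' or 'ssdu'")
        super().fit(X)
        X = self._check_x(X)
        if self.mask is None:
            raise ValueError("training requires the undersampling mask")
        params = UnrolledParams(
            ResNetRegularizer(
                ResNetConfig(n_blocks=self.n_blocks, channels=self.channels),
                seed=self.random_state,
            ),
            n_unrolls=self.n_unrolls,
            dc_iters=self.dc_iters,
        )
        cfg = TrainConfig(epochs=self.epochs, lr=self.lr, seed=self.random_state)
        if self.strategy == "supervised":
            if y is None:
                raise ValueError("supervised training requires reference images y")
            pairs = [
                TrainingPair(x, self.mask, self.maps_, x_ref=np.asarray(r))
                for x, r in zip(X, y)
            ]
            state = train_supervised(pairs, cfg, params)
        else:
            pairs = [TrainingPair(x, self.mask, self.maps_) for x in X]
            state = train_ssdu(
                pairs, SplitConfig(rho=self.rho, sigma_pe=self.sigma_pe), cfg, params
            )
        self.params_ = state.params
        self.lambda_ = state.params.lam
        self.loss_history_ = state.loss_history
        self.operator32_ = EncodingOperator(
            self.maps_.astype(np.complex64), self.mask
        )
        return self

    def _recon_one(self, y):
        return unrolled_reconstruct(
            y.astype(np.complex64), self.operator32_, self.params_
        ).image
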
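"""scikit-learn style estimators wrapping the denoising methods.

Each denoiser is a transformer over epoch arrays of shape
(n_epochs, n_channels, epoch_len): ``fit(X, y)`` learns from noisy inputs
``X`` and clean targets ``y`` (the baselines need little or no fitting),
``transform(X)`` returns denoised epochs of the same shape, and ``score``
reports the mean output SNR in dB against the clean reference. Because
they follow the fit/transform/get_params contract they compose with
sklearn pipelines and model selection.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .baselines import (
    WaveletConfig,
    WienerConfig,
    wavelet_denoise_epochs,
    wiener_denoise_epochs,
)
from .exceptions import ShapeError, UsageError
from .metrics import snr_db
from .models import DiscriminatorConfig
from .synthetic import NoiseSpec, PairedEpochSet
from .training import TrainingConfig, denoise_epochs, train

__all__ = ["AdversarialEEGDenoiser", "WaveletDenoiser", "WienerDenoiser"]


def _check_epochs(X, name="X"):
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ShapeError(f"{name} must be (n_epochs, n_channels, epoch_len), got {X.shape}")
    if not np.all(np.isfinite(X)):
        raise UsageError(f"{name} contains non-finite values")
    return X


def _mean_snr(clean, den) -> float:
    vals = [
        snr_db(clean[i, c], den[i, c])
        for i in range(clean.shape[0])
        for c in range(clean.shape[1])
    ]
    finite = [v for v in vals if np.isfinite(v)]
    return float(np.mean(finite)) if finite else np.inf


class AdversarialEEGDenoiser(TransformerMixin, BaseEstimator):
    """GAN-based EEG denoiser (LSGAN, WGAN-GP or WGAN without penalty).

    Parameters
    ----------
    generator : {"lstm", "resnet"}
        Reconstruction network: a recurrent sequence model or a 1-D
        residual CNN. Both end in a sigmoid so outputs live in [0, 1].
    loss_mode : {"lsgan", "wgan_gp", "wgan_nogp"}
        Adversarial regime. ``lsgan`` pairs squared-error adversarial
        labels with an MSE content term; the wgan modes train a linear
        critic with (or without) the gradient penalty.
    lr_g, lr_d, betas, batch_size, epochs, n_critic, lambda_gp, adv_weight
        Optimization settings; ``None`` selects the per-mode published
        defaults (see :class:`~eegadvdenoise.training.TrainingConfig`).
    hidden_size : int
        LSTM hidden width (ignored for the resnet generator).
    base_filters, n_blocks : int
        Residual generator width/depth (ignored for the lstm generator).
    disc_base_filters, disc_n_layers, disc_proj_filters, disc_norm
        Discriminator/critic architecture; the defaults are the full
        8-layer, 1024-feature network. Smaller values give the reduced
        discriminator used for short epochs.
    early_stop_patience : int or None
        Early stopping patience (epochs) on a 90/10 held-out content loss.
    random_state : int
        Seed for init, shuffling and interpolation draws.

    Attributes
    ----------
    generator_ : the trained generator network
    discriminator_ : the trained discriminator/critic
    trace_ : :class:`~eegadvdenoise.training.TrainingTrace`

    Examples
    --------
    >>> den = AdversarialEEGDenoiser(generator="lstm", loss_mode="lsgan",
    ...                              epochs=2, random_state=0)
    >>> den.fit(noisy_epochs, clean_epochs).transform(noisy_epochs).shape
    (n, C, L)
    """

    def __init__(
        self,
        generator: str = "lstm",
        loss_mode: str = "lsgan",
        lr_g: Optional[float] = None,
        lr_d: Optional[float] = None,
        betas=(0.5, 0.999),
        batch_size: Optional[int] = None,
        epochs: Optional[int] = None,
        n_critic: int = 5,
        lambda_gp: float = 10.0,
        adv_weight: float = 1.0,
        hidden_size: int = 64,
        base_filters: int = 64,
        n_blocks: int = 16,
        disc_base_filters: int = 64,
        disc_n_layers: int = 8,
        disc_proj_filters: int = 1024,
        disc_norm: str = "batch",
        early_stop_patience: Optional[int] = None,
        random_state: int = 0,
    ):
        self.generator = generator
        self.loss_mode = loss_mode
        self.lr_g = lr_g
        self.lr_d = lr_d
        self.betas = betas
        self.batch_size = batch_size
        self.epochs = epochs
        self.n_critic = n_critic
        self.lambda_gp = lambda_gp
        self.adv_weight = adv_weight
        self.hidden_size = hidden_size
        self.base_filters = base_filters
        self.n_blocks = n_blocks
        self.disc_base_filters = disc_base_filters
        self.disc_n_layers = disc_n_layers
        self.disc_proj_filters = disc_proj_filters
        self.disc_norm = disc_norm
        self.early_stop_patience = early_stop_patience
        self.random_state = random_state

    def _training_config(self) -> TrainingConfig:
        factory = {
            "lsgan": TrainingConfig.lsgan,
            "wgan_gp": TrainingConfig.wgan_gp,
            "wgan_nogp": TrainingConfig.wgan_nogp,
        }[self.loss_mode]
        kw = dict(
            betas=tuple(self.betas),
            n_critic=self.n_critic,
            lambda_gp=self.lambda_gp,
            adv_weight=self.adv_weight,
            seed=self.random_state,
            early_stop_patience=self.early_stop_patience,
        )
        for name in ("lr_g", "lr_d", "batch_size", "epochs"):
            v = getattr(self, name)
            if v is not None:
                kw[name] = v
        return factory(**kw)

    def fit(self, X, y):
        """Train on noisy epochs ``X`` against clean targets ``y``."""
        X = _check_epochs(X, "X")
        y = _check_epochs(y, "y")
        if X.shape != y.shape:
            raise ShapeError(f"X {X.shape} and y {y.shape} must match")
        pairs = PairedEpochSet(
            clean=y,
            noisy=X,
            specs=[NoiseSpec("white", 0.0, 0)] * X.shape[0],
            epoch_len=X.shape[2],
        )
        gen_kwargs = (
            {"hidden_size": self.hidden_size}
            if self.generator == "lstm"
            else {"base_filters": self.base_filters, "n_blocks": self.n_blocks}
        )
        head = "sigmoid" if self.loss_mode == "lsgan" else "linear"
        disc_cfg = DiscriminatorConfig(
            in_channels=X.shape[1],
            base_filters=self.disc_base_filters,
            n_layers=self.disc_n_layers,
            proj_filters=self.disc_proj_filters,
            head=head,
            norm=self.disc_norm,
        )
        self.generator_, self.discriminator_, self.trace_ = train(
            pairs,
            g_arch=self.generator,
            cfg=self._training_config(),
            generator_kwargs=gen_kwargs,
            discriminator_config=disc_cfg,
        )
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "generator_"):
            raise UsageError("fit the denoiser before calling transform")
        X = _check_epochs(X, "X")
        return denoise_epochs(self.generator_, X)

    def score(self, X, y) -> float:
        """Mean output SNR (dB) of ``transform(X)`` against clean ``y``."""
        return _mean_snr(_check_epochs(y, "y"), self.transform(X))


class WaveletDenoiser(TransformerMixin, BaseEstimator):
    """Universal-threshold wavelet shrinkage as a stateless transformer."""

    def __init__(self, wavelet_name: str = "db4", levels: int = 4,
                 threshold_mode: str = "soft"):
        self.wavelet_name = wavelet_name
        self.levels = levels
        self.threshold_mode = threshold_mode

    def _config(self) -> WaveletConfig:
        return WaveletConfig(
            wavelet_name=self.wavelet_name,
            levels=self.levels,
            threshold_mode=self.threshold_mode,
        )

    def fit(self, X, y=None):
        _check_epochs(X, "X")
        self._config()  # validate parameters eagerly
        return self

    def transform(self, X) -> np.ndarray:
        return wavelet_denoise_epochs(_check_epochs(X, "X"), self._config())

    def score(self, X, y) -> float:
        return _mean_snr(_check_epochs(y, "y"), self.transform(X))


class WienerDenoiser(TransformerMixin, BaseEstimator):
    """Short-time spectral Wiener filter.

    ``fit(X, y)`` with clean targets measures the true noise power from
    the residual ``X - y`` (exact for semi-synthetic pairs); without
    targets the filter falls back to a high-band noise estimate at
    transform time.
    """

    def __init__(self, window_len: int = 256):
        self.window_len = window_len

    def _config(self) -> WienerConfig:
        est = "from_clean_ref" if getattr(self, "noise_power_", None) is not None else "high_band"
        return WienerConfig(window_len=self.window_len, noise_psd_estimate=est)

    def fit(self, X, y=None):
        X = _check_epochs(X, "X")
        if y is not None:
            y = _check_epochs(y, "y")
            if X.shape != y.shape:
                raise ShapeError("X and y must match")
            self.noise_power_ = float(np.mean((X - y) ** 2))
        else:
            self.noise_power_ = None
        return self

    def transform(self, X) -> np.ndarray:
        X = _check_epochs(X, "X")
        return wiener_denoise_epochs(
            X, self._config(), noise_powers=getattr(self, "noise_power_", None)
        )

    def score(self, X, y) -> float:
        return _mean_snr(_check_epochs(y, "y"), self.transform(X))
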
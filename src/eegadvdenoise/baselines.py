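"""Classical denoising comparators: wavelet thresholding and Wiener
filtering.

Both are deterministic, length-preserving, single-signal operations; the
``*_epochs`` helpers map them over a (n, C, L) epoch array so they produce
the same denoised-epoch arrays the evaluator consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pywt

from .exceptions import ShapeError, UsageError

__all__ = [
    "WaveletConfig",
    "WienerConfig",
    "wavelet_denoise",
    "wiener_denoise",
    "wavelet_denoise_epochs",
    "wiener_denoise_epochs",
]


@dataclass
class WaveletConfig:
    """Multilevel wavelet shrinkage settings.

    Defaults (sym8, 4 levels, soft universal threshold) are common EEG
    practice: the near-symmetric sym8 filters keep band leakage between
    detail scales low, which matters for rhythmic 8-30 Hz content. The
    threshold is sigma * sqrt(2 ln N) with sigma estimated from the
    finest detail band.
    """

    wavelet_name: str = "sym8"
    levels: int = 4
    threshold_rule: str = "universal"
    threshold_mode: str = "soft"

    def __post_init__(self):
        if self.levels < 1:
            raise UsageError("levels must be >= 1")
        if self.wavelet_name not in pywt.wavelist():
            raise UsageError(f"unknown wavelet {self.wavelet_name!r}")
        if self.threshold_rule != "universal":
            raise UsageError("only the universal threshold rule is implemented")
        if self.threshold_mode not in ("soft", "hard"):
            raise UsageError("threshold_mode must be 'soft' or 'hard'")


@dataclass
class WienerConfig:
    """Short-time spectral Wiener filter settings.

    ``window_len`` must be a power of two; the noise spectrum comes either
    from a known noise power (semi-synthetic pairs make it exact) or from
    the upper quarter of the spectrum where EEG content is negligible.
    """

    window_len: int = 256
    noise_psd_estimate: str = "from_clean_ref"

    def __post_init__(self):
        w = self.window_len
        if w < 4 or (w & (w - 1)) != 0:
            raise UsageError("window_len must be a power of two >= 4")
        if self.noise_psd_estimate not in ("from_clean_ref", "high_band"):
            raise UsageError("noise_psd_estimate must be from_clean_ref|high_band")


def wavelet_denoise(noisy, cfg: WaveletConfig = None) -> np.ndarray:
    """Universal-threshold wavelet shrinkage of one signal.

    Decomposes to ``cfg.levels`` scales and shrinks every detail band with
    the universal threshold ``sigma * sqrt(2 ln N)``. The noise scale
    ``sigma`` is the MAD/0.6745 estimate from the *finest* detail band —
    the standard white-noise estimator: coarser bands carry the rhythmic
    EEG content itself, so estimating sigma per band would shrink the
    signal away along with the noise. The approximation band is left
    untouched (it carries the slow waveform).
    """
    if cfg is None:
        cfg = WaveletConfig()
    x = np.asarray(noisy, dtype=float).ravel()
    if x.size < 2**cfg.levels:
        raise ShapeError(
            f"signal of {x.size} samples too short for {cfg.levels} wavelet levels"
        )
    # clamp depth so short epochs do not push coefficients into pure
    # boundary effects
    max_level = pywt.dwt_max_level(x.size, pywt.Wavelet(cfg.wavelet_name).dec_len)
    level = max(1, min(cfg.levels, max_level))
    coeffs = pywt.wavedec(x, cfg.wavelet_name, level=level)
    n = x.size
    finest = coeffs[-1]
    sigma = float(np.median(np.abs(finest)) / 0.6745) if finest.size else 0.0
    thr = sigma * np.sqrt(2.0 * np.log(n))
    out = [coeffs[0]]
    for detail in coeffs[1:]:
        if thr == 0.0:
            out.append(detail)
        else:
            out.append(pywt.threshold(detail, thr, mode=cfg.threshold_mode))
    rec = pywt.waverec(out, cfg.wavelet_name)
    return rec[: x.size]


def _stft_frames(x, win, hop):
    n = x.size
    starts = range(0, n - win.size + 1, hop)
    return np.array([x[s : s + win.size] * win for s in starts]), list(starts)


def wiener_denoise(
    noisy, cfg: WienerConfig = None, noise_power: Optional[float] = None
) -> np.ndarray:
    """Short-time spectral Wiener filter of one signal.

    Hann windows with 50% overlap satisfy the constant-overlap-add
    condition, so unit gain reconstructs the input exactly (up to the
    frame-coverage edges). The per-bin gain is
    ``H = max(0, 1 - P_n / P_x)`` with ``P_x`` the frame periodogram and
    ``P_n`` the (flat) noise spectrum from ``noise_power``, or estimated
    from the top quarter of the spectrum when no noise power is supplied.
    """
    if cfg is None:
        cfg = WienerConfig()
    x = np.asarray(noisy, dtype=float).ravel()
    W = cfg.window_len
    if x.size < W:
        raise ShapeError(f"signal of {x.size} samples shorter than window {W}")
    hop = W // 2
    win = np.hanning(W)

    # reflect-pad half a window on each side so every original sample has
    # full frame coverage (otherwise the OLA normalization is tiny at the
    # edges and the division amplifies the modified edge frames)
    lp = hop
    tail_pad = (-(x.size + lp - W)) % hop + lp
    xp = np.concatenate([x[:lp][::-1], x, np.zeros(tail_pad)])
    frames, starts = _stft_frames(xp, win, hop)
    spec = np.fft.rfft(frames, axis=1)
    psd = np.abs(spec) ** 2

    if noise_power is not None:
        # flat noise PSD: per-bin expected periodogram of white noise of
        # that power through the analysis window
        p_noise = noise_power * np.sum(win**2)
        noise_psd = np.full(psd.shape[1], p_noise)
        noise_psd[0] /= 1.0
    else:
        hi = psd[:, 3 * psd.shape[1] // 4 :]
        noise_psd = np.full(psd.shape[1], float(np.median(hi)))

    gain = np.clip(1.0 - noise_psd[None, :] / np.maximum(psd, 1e-300), 0.0, None)
    den = np.fft.irfft(spec * gain, n=W, axis=1)

    out = np.zeros(xp.size)
    norm = np.zeros(xp.size)
    for f, s in zip(den, starts):
        out[s : s + W] += f * win
        norm[s : s + W] += win**2
    norm = np.maximum(norm, 1e-8)
    return (out / norm)[lp : lp + x.size]


def wavelet_denoise_epochs(epochs, cfg: WaveletConfig = None) -> np.ndarray:
    epochs = np.asarray(epochs, dtype=float)
    out = np.empty_like(epochs)
    for i in range(epochs.shape[0]):
        for c in range(epochs.shape[1]):
            out[i, c] = wavelet_denoise(epochs[i, c], cfg)
    return out


def wiener_denoise_epochs(
    epochs, cfg: WienerConfig = None, noise_powers=None
) -> np.ndarray:
    """Apply the Wiener filter per epoch; ``noise_powers`` may be a scalar
    or one value per epoch (known exactly for semi-synthetic pairs)."""
    epochs = np.asarray(epochs, dtype=float)
    out = np.empty_like(epochs)
    for i in range(epochs.shape[0]):
        np_i = None
        if noise_powers is not None:
            np_i = float(np.ravel(noise_powers)[i] if np.ndim(noise_powers) else noise_powers)
        for c in range(epochs.shape[1]):
            out[i, c] = wiener_denoise(epochs[i, c], cfg, noise_power=np_i)
    return out
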
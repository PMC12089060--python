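"""Signal conditioning: band-pass filtering, min-max scaling, shape
enforcement and epoching.

The default chain mirrors standard motor-imagery practice: an 8-30 Hz
zero-phase FIR band-pass (covering the alpha and beta rhythms) applied per
channel, followed by per-channel min-max normalization onto [0, 1] - the
domain the sigmoid-headed generators produce. Epoching cuts the continuous
recording into fixed-length windows (default 512 samples = 4 s at 128 Hz,
non-overlapping), the unit the adversarial models train on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from mne.filter import filter_data

from .exceptions import EEGDenoiseError, ShapeError, UsageError
from .io import EEGRecording

__all__ = [
    "NormalizationState",
    "EpochSet",
    "bandpass",
    "minmax_normalize",
    "denormalize",
    "ensure_min_shape",
    "epoch_signal",
    "DEFAULT_EPOCH_LEN",
]

logger = logging.getLogger(__name__)

#: 4 s at 128 Hz; divisible by 16 as the full discriminator requires.
DEFAULT_EPOCH_LEN = 512


@dataclass
class NormalizationState:
    """Per-channel extrema recorded by :func:`minmax_normalize`.

    Keeping the extrema makes the scaling exactly invertible via
    :func:`denormalize`.
    """

    per_channel_min: np.ndarray
    per_channel_max: np.ndarray

    def __post_init__(self):
        self.per_channel_min = np.asarray(self.per_channel_min, dtype=float)
        self.per_channel_max = np.asarray(self.per_channel_max, dtype=float)
        if np.any(self.per_channel_max < self.per_channel_min):
            raise UsageError("per-channel max below min")


@dataclass
class EpochSet:
    """Fixed-length windows cut from one recording.

    ``epochs`` has shape (n_epochs, n_channels, epoch_len);
    ``source_offsets`` records where each window starts in the source.
    """

    epochs: np.ndarray
    source_offsets: np.ndarray
    epoch_len: int

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.source_offsets = np.asarray(self.source_offsets, dtype=int)
        if self.epochs.ndim != 3:
            raise ShapeError("epochs must be 3-D (n_epochs, n_channels, epoch_len)")
        if self.epoch_len <= 0 or self.epochs.shape[2] != self.epoch_len:
            raise ShapeError("epoch_len does not match epoch array")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def bandpass(
    rec: EEGRecording,
    low_hz: float = 8.0,
    high_hz: float = 30.0,
    transition_hz: float = 2.0,
) -> EEGRecording:
    """Zero-phase FIR band-pass, applied independently per channel.

    A windowed-sinc FIR (designed and applied forward-backward by MNE) keeps
    the passband phase linear with zero net delay, so time-alignment metrics
    (CC, DTW) downstream are not corrupted by filter phase. Transition width
    defaults to 2 Hz on both edges.

    Raises
    ------
    UsageError
        If the band is empty or reaches the Nyquist frequency.
    ShapeError
        If the recording is shorter than the filter.
    """
    nyq = rec.sample_rate / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise UsageError(
            f"need 0 < low ({low_hz}) < high ({high_hz}) < Nyquist ({nyq})"
        )
    # MNE's 'auto' FIR length for a given transition bandwidth: 3.3 cycles.
    approx_len = int(round(3.3 * rec.sample_rate / transition_hz))
    if rec.n_samples <= approx_len:
        raise ShapeError(
            f"recording of {rec.n_samples} samples is shorter than the "
            f"~{approx_len}-tap filter; lengthen the signal or widen transition_hz"
        )
    filtered = filter_data(
        rec.data,
        sfreq=rec.sample_rate,
        l_freq=low_hz,
        h_freq=high_hz,
        l_trans_bandwidth=transition_hz,
        h_trans_bandwidth=transition_hz,
        method="fir",
        fir_design="firwin",
        phase="zero",
        verbose=False,
    )
    logger.info(
        "bandpass %.1f-%.1f Hz (transition %.1f Hz) on %d ch x %d samples",
        low_hz, high_hz, transition_hz, rec.n_channels, rec.n_samples,
    )
    return EEGRecording(
        channel_names=list(rec.channel_names),
        sample_rate=rec.sample_rate,
        data=filtered,
        labels=None if rec.labels is None else list(rec.labels),
    )


def minmax_normalize(rec: EEGRecording):
    """Scale each channel onto [0, 1]; returns (recording, state).

    ``y = (x - min) / (max - min)`` per channel. A constant channel has no
    range; it maps to 0.5 (midpoint) with a warning rather than raising, so
    flat fixtures keep flowing through pipelines. The returned
    :class:`NormalizationState` inverts the transform exactly.
    """
    mn = rec.data.min(axis=1)
    mx = rec.data.max(axis=1)
    span = mx - mn
    flat = span == 0
    if np.any(flat):
        logger.warning(
            "constant channel(s) %s mapped to 0.5",
            [rec.channel_names[i] for i in np.where(flat)[0]],
        )
    safe_span = np.where(flat, 1.0, span)
    scaled = (rec.data - mn[:, None]) / safe_span[:, None]
    scaled[flat] = 0.5
    out = EEGRecording(
        channel_names=list(rec.channel_names),
        sample_rate=rec.sample_rate,
        data=scaled,
        labels=None if rec.labels is None else list(rec.labels),
    )
    return out, NormalizationState(per_channel_min=mn, per_channel_max=mx)


def denormalize(rec: EEGRecording, state: NormalizationState) -> EEGRecording:
    """Invert :func:`minmax_normalize` using the stored extrema."""
    mn = state.per_channel_min
    mx = state.per_channel_max
    if mn.shape[0] != rec.n_channels:
        raise UsageError(
            f"state holds {mn.shape[0]} channels, recording has {rec.n_channels}"
        )
    span = mx - mn
    flat = span == 0
    data = rec.data * np.where(flat, 0.0, span)[:, None] + mn[:, None]
    return EEGRecording(
        channel_names=list(rec.channel_names),
        sample_rate=rec.sample_rate,
        data=data,
        labels=None if rec.labels is None else list(rec.labels),
    )


def ensure_min_shape(
    rec: EEGRecording,
    min_channels: int,
    min_samples: int,
    mode: str = "crop",
) -> EEGRecording:
    """Force the recording to exactly (min_channels, min_samples).

    ``crop`` keeps the first channels/samples of oversize input; ``pad``
    extends undersized input by edge replication (repeating the last sample
    rather than zero-filling, which would inject a step discontinuity into
    any later filtering). Exact-size input passes through unchanged.
    """
    if mode not in ("crop", "pad"):
        raise UsageError(f"mode must be 'crop' or 'pad', got {mode!r}")
    data = rec.data
    names = list(rec.channel_names)
    labels = None if rec.labels is None else list(rec.labels)

    if data.shape[0] > min_channels:
        logger.info("cropping channels %d -> %d", data.shape[0], min_channels)
        data = data[:min_channels]
        names = names[:min_channels]
    elif data.shape[0] < min_channels:
        if mode == "crop":
            raise EEGDenoiseError(
                f"cannot crop {data.shape[0]} channels up to {min_channels}"
            )
        logger.info("padding channels %d -> %d by replication", data.shape[0], min_channels)
        reps = [data[i % data.shape[0]] for i in range(min_channels)]
        names = names + [f"{names[i % len(names)]}_pad{i}" for i in range(data.shape[0], min_channels)]
        data = np.stack(reps)

    if data.shape[1] > min_samples:
        logger.info("cropping samples %d -> %d", data.shape[1], min_samples)
        data = data[:, :min_samples]
        if labels is not None:
            labels = labels[:min_samples]
    elif data.shape[1] < min_samples:
        if mode == "crop":
            raise EEGDenoiseError(
                f"cannot crop {data.shape[1]} samples up to {min_samples}"
            )
        pad = min_samples - data.shape[1]
        logger.info("padding samples %d -> %d by edge replication", data.shape[1], min_samples)
        data = np.concatenate([data, np.repeat(data[:, -1:], pad, axis=1)], axis=1)
        if labels is not None:
            labels = labels + [labels[-1]] * pad

    return EEGRecording(
        channel_names=names, sample_rate=rec.sample_rate, data=data, labels=labels
    )


def epoch_signal(rec: EEGRecording, epoch_len: int = DEFAULT_EPOCH_LEN, stride: int = None) -> EpochSet:
    """Cut the recording into fixed-length windows.

    With the default ``stride = epoch_len`` the windows tile the signal
    without overlap; the number of epochs is
    ``floor((n_samples - epoch_len) / stride) + 1``.
    """
    if stride is None:
        stride = epoch_len
    if epoch_len <= 0 or stride < 1:
        raise UsageError("epoch_len and stride must be positive")
    if epoch_len > rec.n_samples:
        raise ShapeError(
            f"epoch_len {epoch_len} exceeds recording length {rec.n_samples}"
        )
    n = (rec.n_samples - epoch_len) // stride + 1
    offsets = np.arange(n) * stride
    epochs = np.stack([rec.data[:, o : o + epoch_len] for o in offsets])
    return EpochSet(epochs=epochs, source_offsets=offsets, epoch_len=epoch_len)
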
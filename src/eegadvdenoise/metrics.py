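"""Eight-metric signal-quality evaluation: SNR, PSNR, RRMSE, MAE, MI, SD,
CC and DTW, computed per channel and aggregated as mean ± SD.

Definitions are the field-standard ones on a reference/estimate pair:

SNR    10*log10(sum(ref^2) / sum((est-ref)^2))         [dB]
PSNR   10*log10(peak^2 / MSE(ref, est)), peak = 1      [dB]
RRMSE  RMS(est - ref) / RMS(ref)
MAE    mean |est - ref|
SD     population standard deviation of (est - ref)
MI     joint-histogram mutual information               [bits]
CC     Pearson correlation coefficient
DTW    unconstrained dynamic-time-warping distance with
       absolute-difference local cost

Perfect reconstruction drives SNR and PSNR to +infinity; the sentinel is
kept as ``inf`` in memory and serialized as the string ``"Infinity"``,
never silently as a large float.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .exceptions import ShapeError, UsageError
from .synthetic import PairedEpochSet

__all__ = [
    "METRIC_NAMES",
    "snr_db",
    "psnr_db",
    "rrmse",
    "mae",
    "residual_sd",
    "mutual_information",
    "pearson_cc",
    "dtw_distance",
    "MetricsReport",
    "evaluate",
]

METRIC_NAMES = ("SNR", "PSNR", "RRMSE", "MAE", "MI", "SD", "CC", "DTW")

INF_TOKEN = "Infinity"


def _pair(ref, est):
    ref = np.asarray(ref, dtype=float).ravel()
    est = np.asarray(est, dtype=float).ravel()
    if ref.shape != est.shape:
        raise ShapeError(f"length mismatch {ref.shape} vs {est.shape}")
    return ref, est


def snr_db(ref, est) -> float:
    """Residual-referenced signal-to-noise ratio in dB; +inf when est == ref."""
    ref, est = _pair(ref, est)
    p_ref = float(np.sum(ref**2))
    if p_ref == 0:
        raise UsageError("reference has zero power; SNR undefined")
    p_res = float(np.sum((est - ref) ** 2))
    if p_res == 0:
        return np.inf
    return 10.0 * np.log10(p_ref / p_res)


def psnr_db(ref, est, peak: float = 1.0) -> float:
    """Peak-referenced SNR in dB; peak defaults to 1 for [0, 1] signals."""
    ref, est = _pair(ref, est)
    mse = float(np.mean((est - ref) ** 2))
    if mse == 0:
        return np.inf
    return 10.0 * np.log10(peak**2 / mse)


def rrmse(ref, est) -> float:
    """Root-mean-squared error relative to the reference RMS."""
    ref, est = _pair(ref, est)
    rms_ref = float(np.sqrt(np.mean(ref**2)))
    if rms_ref == 0:
        raise UsageError("reference has zero RMS; RRMSE undefined")
    return float(np.sqrt(np.mean((est - ref) ** 2))) / rms_ref


def mae(ref, est) -> float:
    """Mean absolute error."""
    ref, est = _pair(ref, est)
    return float(np.mean(np.abs(est - ref)))


def residual_sd(ref, est) -> float:
    """Population standard deviation of the residual (est - ref)."""
    ref, est = _pair(ref, est)
    return float(np.std(est - ref))


def signal_sd(ref, est) -> float:
    """Standard deviation of the estimate itself (alternative SD reading)."""
    _, est = _pair(ref, est)
    return float(np.std(est))


def mutual_information(ref, est, bins: int = 64) -> float:
    """Joint-histogram mutual information in bits.

    Equal-width bins span each signal's own range; degenerate (constant)
    signals collapse to a single bin and yield MI = 0. Symmetric in its
    arguments by construction.
    """
    ref, est = _pair(ref, est)
    if ref.size < bins:
        raise UsageError(f"need at least {bins} samples for {bins}-bin MI")

    def _edges(x):
        lo, hi = float(x.min()), float(x.max())
        if lo == hi:  # constant signal: single effective bin
            return np.array([lo - 0.5, hi + 0.5])
        return np.linspace(lo, hi, bins + 1)

    joint, _, _ = np.histogram2d(ref, est, bins=[_edges(ref), _edges(est)])
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / (px @ py)[mask])))


def pearson_cc(ref, est) -> float:
    """Pearson correlation coefficient; raises on constant input."""
    ref, est = _pair(ref, est)
    if np.std(ref) == 0 or np.std(est) == 0:
        raise UsageError("correlation undefined for constant signals")
    return float(np.corrcoef(ref, est)[0, 1])


# ---------------------------------------------------------------------------
# dynamic time warping
# ---------------------------------------------------------------------------

try:  # numba accelerates the O(n*m) table; pure NumPy/Python fallback below
    from numba import njit

    @njit(cache=False)
    def _dtw_table(a, b):  # pragma: no cover - exercised through dtw_distance
        n, m = a.shape[0], b.shape[0]
        big = 1e300
        prev = np.empty(m + 1)
        cur = np.empty(m + 1)
        for j in range(m + 1):
            prev[j] = big
        prev[0] = 0.0
        for i in range(1, n + 1):
            cur[0] = big
            for j in range(1, m + 1):
                c = abs(a[i - 1] - b[j - 1])
                best = prev[j - 1]
                if prev[j] < best:
                    best = prev[j]
                if cur[j - 1] < best:
                    best = cur[j - 1]
                cur[j] = c + best
            for j in range(m + 1):
                prev[j] = cur[j]
        return prev[m]

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _dtw_py(a, b):
    n, m = len(a), len(b)
    prev = np.full(m + 1, np.inf)
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur = np.full(m + 1, np.inf)
        cost = np.abs(a[i - 1] - b)
        for j in range(1, m + 1):
            cur[j] = cost[j - 1] + min(prev[j - 1], prev[j], cur[j - 1])
        prev = cur
    return float(prev[m])


def dtw_distance(a, b) -> float:
    """Minimal cumulative |a_i - b_j| over monotone warping paths.

    Classic dynamic program with steps (1,0), (0,1), (1,1), endpoints
    matched, no window constraint and no path-length normalization.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise UsageError("DTW undefined for empty sequences")
    if _HAVE_NUMBA:
        return float(_dtw_table(a, b))
    return _dtw_py(a, b)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Per-channel metric table plus mean ± SD aggregates.

    ``per_channel`` is a channel x metric DataFrame; ``aggregate_mean`` and
    ``aggregate_sd`` are its column mean and (population) SD. ``metadata``
    records the method name, dataset tag and epoch count.
    """

    per_channel: pd.DataFrame
    aggregate_mean: pd.Series
    aggregate_sd: pd.Series
    metadata: Dict[str, object] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def enc(v):
            if isinstance(v, float) and np.isinf(v):
                return INF_TOKEN
            return v

        return {
            "metadata": self.metadata,
            "per_channel": {
                str(ch): {m: enc(float(v)) for m, v in row.items()}
                for ch, row in self.per_channel.iterrows()
            },
            "aggregate_mean": {m: enc(float(v)) for m, v in self.aggregate_mean.items()},
            "aggregate_sd": {m: enc(float(v)) for m, v in self.aggregate_sd.items()},
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def evaluate(
    pairs: PairedEpochSet,
    denoised: np.ndarray,
    tag: str = "",
    mi_bins: int = 64,
    sd_mode: str = "residual",
) -> MetricsReport:
    """Score denoised epochs against their clean references.

    Each metric is computed per (channel, epoch) pair, averaged over
    epochs to give one value per channel, then summarized across channels
    as mean ± SD — mirroring per-channel reporting with channel-mean
    aggregation. ``sd_mode`` chooses between the residual SD (default) and
    the SD of the denoised signal itself.
    """
    denoised = np.asarray(denoised, dtype=float)
    if denoised.shape != pairs.clean.shape:
        raise ShapeError(
            f"denoised shape {denoised.shape} does not match pairs {pairs.clean.shape}"
        )
    if sd_mode not in ("residual", "signal"):
        raise UsageError("sd_mode must be 'residual' or 'signal'")
    sd_fn = residual_sd if sd_mode == "residual" else signal_sd

    n, C, L = pairs.clean.shape
    rows = []
    for ch in range(C):
        vals = {m: [] for m in METRIC_NAMES}
        for ep in range(n):
            ref = pairs.clean[ep, ch]
            est = denoised[ep, ch]
            vals["SNR"].append(snr_db(ref, est))
            vals["PSNR"].append(psnr_db(ref, est))
            vals["RRMSE"].append(rrmse(ref, est))
            vals["MAE"].append(mae(ref, est))
            vals["MI"].append(mutual_information(ref, est, bins=min(mi_bins, L)))
            vals["SD"].append(sd_fn(ref, est))
            vals["CC"].append(pearson_cc(ref, est))
            vals["DTW"].append(dtw_distance(ref, est))
        rows.append({m: float(np.mean(v)) for m, v in vals.items()})

    per_channel = pd.DataFrame(rows, index=[f"ch{c}" for c in range(C)])
    return MetricsReport(
        per_channel=per_channel,
        aggregate_mean=per_channel.mean(axis=0),
        aggregate_sd=per_channel.std(axis=0, ddof=0),
        metadata={"method": tag, "n_epochs": int(n), "sd_mode": sd_mode},
    )
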
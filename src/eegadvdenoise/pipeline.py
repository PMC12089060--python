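"""End-to-end experiment orchestration: simulate -> pair -> train ->
denoise -> evaluate, with every method scored on the identical test pairs.

The experiment is fully described by an :class:`ExperimentConfig`; running
it twice with the same config reproduces every number bit for bit. The
output is one :class:`~eegadvdenoise.metrics.MetricsReport` per method plus
a merged methods x metrics comparison table (mean ± SD across channels),
and a manifest (config + seeds + pair-set hash) sufficient to regenerate
every artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .estimators import AdversarialEEGDenoiser, WaveletDenoiser, WienerDenoiser
from .exceptions import EEGDenoiseError, UsageError
from .metrics import METRIC_NAMES, MetricsReport, evaluate
from .preprocess import bandpass, minmax_normalize
from .synthetic import PairedEpochSet, build_paired_set, simulate_clean_eeg

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "smoke_config"]

logger = logging.getLogger(__name__)

ADVERSARIAL_METHODS = ("lsgan", "wgan_gp", "wgan_nogp")
BASELINE_METHODS = ("wavelet", "wiener")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one comparison experiment."""

    # simulation block
    channels: int = 3
    seconds: float = 120.0
    sample_rate: float = 128.0
    sim_seed: int = 0
    # preprocessing
    apply_bandpass: bool = True
    low_hz: float = 8.0
    high_hz: float = 30.0
    # pairing block
    noise_kinds: Sequence[str] = ("white",)
    snr_grid_db: Sequence[float] = (-5.0, 0.0, 5.0, 10.0)
    z_threshold: float = 3.0
    epoch_len: int = 512
    pair_seed: int = 1
    # methods and training
    methods: Sequence[str] = ("wavelet", "wiener")
    train_kwargs: Dict[str, dict] = field(default_factory=dict)
    test_fraction: float = 0.2
    split_seed: int = 2
    wiener_window: int = 256
    # output
    output_dir: Optional[str] = None

    def __post_init__(self):
        if not self.methods:
            raise UsageError("methods must be non-empty")
        for m in self.methods:
            if m not in ADVERSARIAL_METHODS + BASELINE_METHODS:
                raise UsageError(f"unknown method {m!r}")


@dataclass
class ExperimentResult:
    reports: Dict[str, MetricsReport]
    comparison: pd.DataFrame
    manifest: dict
    pairs_train: PairedEpochSet
    pairs_test: PairedEpochSet


def smoke_config(seed: int = 0, methods: Sequence[str] = None) -> ExperimentConfig:
    """The reduced single-channel profile used for quick, CPU-only runs.

    One simulated channel, 64-sample epochs, white noise at 0 dB,
    ~200 pairs, a reduced discriminator and short training schedules. The
    scaled-down learning rates are raised accordingly (a handful of Adam
    steps at the full-scale 2e-5 would leave the networks at their
    initialization).
    """
    if methods is None:
        methods = ("lsgan", "wgan_gp", "wgan_nogp", "wavelet", "wiener")
    small_net = dict(
        generator="lstm",
        hidden_size=32,
        disc_base_filters=8,
        disc_n_layers=4,
        disc_proj_filters=32,
        batch_size=32,
        epochs=8,
        random_state=seed,
    )
    return ExperimentConfig(
        channels=1,
        seconds=100.0,
        sim_seed=seed,
        noise_kinds=("white",),
        snr_grid_db=(0.0,),
        epoch_len=64,
        pair_seed=seed + 1,
        split_seed=seed + 2,
        methods=tuple(methods),
        wiener_window=32,
        train_kwargs={
            "lsgan": dict(small_net, loss_mode="lsgan", lr_g=5e-3, lr_d=1e-3),
            "wgan_gp": dict(small_net, loss_mode="wgan_gp", lr_g=1e-3, lr_d=1e-3),
            "wgan_nogp": dict(small_net, loss_mode="wgan_nogp", lr_g=1e-3, lr_d=1e-3),
        },
    )


def _pairset_hash(pairs: PairedEpochSet) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(pairs.clean).tobytes())
    h.update(np.ascontiguousarray(pairs.noisy).tobytes())
    return h.hexdigest()[:16]


def _make_estimator(method: str, cfg: ExperimentConfig):
    if method in ADVERSARIAL_METHODS:
        kw = dict(cfg.train_kwargs.get(method, {}))
        kw.setdefault("loss_mode", method)
        return AdversarialEEGDenoiser(**kw)
    if method == "wavelet":
        return WaveletDenoiser()
    if method == "wiener":
        return WienerDenoiser(window_len=cfg.wiener_window)
    raise UsageError(f"unknown method {method!r}")


def build_pairs(cfg: ExperimentConfig) -> PairedEpochSet:
    """Simulate, precondition and pair the synthetic recording."""
    rec = simulate_clean_eeg(
        n_channels=cfg.channels,
        n_samples=int(round(cfg.seconds * cfg.sample_rate)),
        sample_rate=cfg.sample_rate,
        seed=cfg.sim_seed,
    )
    if cfg.apply_bandpass:
        rec = bandpass(rec, cfg.low_hz, cfg.high_hz)
    rec, _ = minmax_normalize(rec)
    return build_paired_set(
        rec,
        z_threshold=cfg.z_threshold,
        epoch_len=cfg.epoch_len,
        noise_kinds=cfg.noise_kinds,
        snr_grid_db=cfg.snr_grid_db,
        seed=cfg.pair_seed,
    )


def split_pairs(
    pairs: PairedEpochSet, test_fraction: float, seed: int
) -> Tuple[PairedEpochSet, PairedEpochSet]:
    """Seeded pair-level train/test split (default 80/20), before training."""
    rng = np.random.default_rng(seed)
    idx = np.arange(pairs.n_pairs)
    rng.shuffle(idx)
    n_test = max(1, int(round(test_fraction * pairs.n_pairs)))
    return pairs.subset(idx[n_test:]), pairs.subset(idx[:n_test])


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run every configured method on identical pairs and merge the scores.

    Adversarial methods are fitted on the training split and applied to the
    test split; the classical baselines are fitted (where they learn
    anything: the Wiener noise power) on the same training split and
    applied to the same test epochs. All reports therefore describe the
    same data, which the manifest pins with a pair-set hash.
    """
    t0 = time.time()
    stage = "pairing"
    try:
        pairs = build_pairs(cfg)
        train_pairs, test_pairs = split_pairs(pairs, cfg.test_fraction, cfg.split_seed)
        logger.info(
            "pairs: %d train / %d test (epoch_len %d)",
            train_pairs.n_pairs, test_pairs.n_pairs, cfg.epoch_len,
        )

        reports: Dict[str, MetricsReport] = {}
        traces = {}
        for method in cfg.methods:
            stage = method
            t_m = time.time()
            est = _make_estimator(method, cfg)
            est.fit(train_pairs.noisy, train_pairs.clean)
            denoised = est.transform(test_pairs.noisy)
            reports[method] = evaluate(test_pairs, denoised, tag=method)
            if hasattr(est, "trace_"):
                traces[method] = est.trace_
            logger.info("%s done in %.1f s", method, time.time() - t_m)

        stage = "reporting"
        mean_tbl = pd.DataFrame(
            {m: reports[m].aggregate_mean for m in cfg.methods}
        ).T[list(METRIC_NAMES)]
        sd_tbl = pd.DataFrame(
            {m: reports[m].aggregate_sd for m in cfg.methods}
        ).T[list(METRIC_NAMES)]
        comparison = mean_tbl.copy()

        noisy_report = evaluate(test_pairs, test_pairs.noisy, tag="noisy-input")

        manifest = {
            "config": _jsonable(asdict(cfg)),
            "pairset_hash": _pairset_hash(pairs),
            "n_train_pairs": train_pairs.n_pairs,
            "n_test_pairs": test_pairs.n_pairs,
            "runtime_s": round(time.time() - t0, 2),
        }
        result = ExperimentResult(
            reports={**reports, "noisy-input": noisy_report},
            comparison=comparison,
            manifest=manifest,
            pairs_train=train_pairs,
            pairs_test=test_pairs,
        )
        if cfg.output_dir:
            _persist(result, sd_tbl, traces, Path(cfg.output_dir))
        return result
    except EEGDenoiseError as e:
        raise EEGDenoiseError(f"experiment failed during stage {stage!r}: {e}") from e


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _persist(result: ExperimentResult, sd_tbl: pd.DataFrame, traces, out_dir: Path):
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(
        json.dumps(
            {name: rep.to_dict() for name, rep in result.reports.items()},
            indent=2,
        )
    )
    # comparison.csv: methods x metrics, "mean±sd" cells
    pretty = result.comparison.copy().astype(object)
    for m in pretty.index:
        for c in pretty.columns:
            pretty.loc[m, c] = f"{result.comparison.loc[m, c]:.4g}±{sd_tbl.loc[m, c]:.3g}"
    pretty.to_csv(out_dir / "comparison.csv")
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    trace_dir = out_dir / "trace"
    trace_dir.mkdir(exist_ok=True)
    for method, trace in traces.items():
        pd.DataFrame(
            {k: pd.Series(v) for k, v in trace.as_arrays().items() if k != "epoch_boundaries"}
        ).to_csv(trace_dir / f"{method}.csv", index=False)
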
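"""Loss functions and training loops for the three adversarial regimes.

Three loss modes share the same generator/discriminator building blocks:

``lsgan``
    Least-squares GAN: the discriminator regresses its scores toward the
    labels y_real = 1, y_fake = 0 under squared error, and the generator
    combines a least-squares adversarial term with an MSE content
    (reconstruction) term. One discriminator and one generator update per
    minibatch.
``wgan_gp``
    Wasserstein GAN with gradient penalty: a linear-head critic estimates
    the Wasserstein distance; its loss is E[D(fake)] - E[D(real)] plus
    lambda * E[(||grad_x D(x~)||_2 - 1)^2] evaluated at random interpolates
    x~ = eps*real + (1-eps)*fake, eps ~ U(0,1). The critic takes n_critic
    steps per generator step; the generator minimizes -E[D(fake)].
``wgan_nogp``
    The same schedule with the penalty term removed (and no weight
    clipping), isolating what the penalty itself contributes.

The printed Wasserstein objective is a quantity the critic *maximizes*;
here the critic loss is its negation plus the penalty so that one standard
minimizer (Adam) drives every mode.

All randomness — parameter init, batch shuffling, interpolation draws —
flows from named child generators spawned from ``TrainingConfig.seed``, so
a run is bit-reproducible and the epsilon stream does not perturb the
shuffle stream (wgan_gp with lambda_gp = 0 walks the same trajectory as
wgan_nogp).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .exceptions import DivergenceError, ShapeError, UsageError
from .io import EEGRecording
from .models import (
    Discriminator,
    DiscriminatorConfig,
    LSTMGenerator,
    LSTMGeneratorConfig,
    ResNetGenerator,
    ResNetGeneratorConfig,
)
from .preprocess import NormalizationState, denormalize as _denorm_rec, epoch_signal
from .synthetic import PairedEpochSet

__all__ = [
    "TrainingConfig",
    "TrainingTrace",
    "content_loss",
    "lsgan_discriminator_loss",
    "lsgan_generator_loss",
    "gradient_penalty",
    "wgan_critic_loss",
    "wgan_generator_loss",
    "Adam",
    "train",
    "denoise",
]


@dataclass
class TrainingConfig:
    """Optimizer and schedule settings for one adversarial run.

    Defaults follow the published settings of each regime: for ``lsgan``
    lr_g = 2e-5, lr_d = 2e-3 (a deliberate 100x asymmetry), batch 32,
    15 epochs; for the wgan modes both learning rates 2e-5, batch 64,
    25 epochs, lambda_gp = 10 and n_critic = 5. ``factory`` methods apply
    the per-mode defaults; the generic constructor leaves everything
    explicit.
    """

    loss_mode: str = "lsgan"
    lr_g: float = 2e-5
    lr_d: float = 2e-3
    betas: Tuple[float, float] = (0.5, 0.999)
    batch_size: int = 32
    epochs: int = 15
    n_critic: int = 5
    lambda_gp: float = 10.0
    adv_weight: float = 1.0
    seed: int = 0
    early_stop_patience: Optional[int] = None

    def __post_init__(self):
        if self.loss_mode not in ("lsgan", "wgan_gp", "wgan_nogp"):
            raise UsageError(f"unknown loss_mode {self.loss_mode!r}")
        if self.lr_g <= 0 or self.lr_d <= 0:
            raise UsageError("learning rates must be positive")
        if self.n_critic < 1:
            raise UsageError("n_critic must be >= 1")
        if self.lambda_gp < 0:
            raise UsageError("lambda_gp must be >= 0")

    @classmethod
    def lsgan(cls, **kw) -> "TrainingConfig":
        kw.setdefault("loss_mode", "lsgan")
        kw.setdefault("lr_g", 2e-5)
        kw.setdefault("lr_d", 2e-3)
        kw.setdefault("batch_size", 32)
        kw.setdefault("epochs", 15)
        return cls(**kw)

    @classmethod
    def wgan_gp(cls, **kw) -> "TrainingConfig":
        kw.setdefault("loss_mode", "wgan_gp")
        kw.setdefault("lr_g", 2e-5)
        kw.setdefault("lr_d", 2e-5)
        kw.setdefault("batch_size", 64)
        kw.setdefault("epochs", 25)
        return cls(**kw)

    @classmethod
    def wgan_nogp(cls, **kw) -> "TrainingConfig":
        kw.setdefault("loss_mode", "wgan_nogp")
        return cls.wgan_gp(**kw)


@dataclass
class TrainingTrace:
    """Per-iteration loss history (all values finite on successful runs)."""

    g_loss: List[float] = field(default_factory=list)
    d_loss: List[float] = field(default_factory=list)
    gp: List[float] = field(default_factory=list)
    epoch_boundaries: List[int] = field(default_factory=list)
    val_content: List[float] = field(default_factory=list)

    def as_arrays(self) -> Dict[str, np.ndarray]:
        return {
            "g_loss": np.array(self.g_loss),
            "d_loss": np.array(self.d_loss),
            "gp": np.array(self.gp),
            "epoch_boundaries": np.array(self.epoch_boundaries, dtype=int),
            "val_content": np.array(self.val_content),
        }


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def _mse(a: Tensor, b) -> Tensor:
    return ((a - b) ** 2).mean()


def content_loss(gen_out, clean) -> Tensor:
    """Mean squared error between the generator output and the clean target."""
    gen_out, clean = ad._ensure(gen_out), ad._ensure(clean)
    if gen_out.shape != clean.shape:
        raise ShapeError(f"shape mismatch {gen_out.shape} vs {clean.shape}")
    return _mse(gen_out, clean)


def lsgan_discriminator_loss(d_real, d_fake) -> Tensor:
    """0.5 * [MSE(D(real), 1) + MSE(D(fake), 0)]."""
    d_real, d_fake = ad._ensure(d_real), ad._ensure(d_fake)
    return 0.5 * (_mse(d_real, 1.0) + _mse(d_fake, 0.0))


def lsgan_generator_loss(d_fake, gen_out, clean, adv_weight: float = 1.0) -> Tensor:
    """adv_weight * MSE(D(fake), 1) + content MSE.

    ``adv_weight = 0`` recovers the pure reconstruction objective; the
    default 1.0 keeps both goals — fooling the discriminator and matching
    the clean reference — active.
    """
    d_fake = ad._ensure(d_fake)
    return adv_weight * _mse(d_fake, 1.0) + content_loss(gen_out, clean)


def gradient_penalty(
    critic: Discriminator,
    x_real: np.ndarray,
    x_fake: np.ndarray,
    lambda_gp: float = 10.0,
    rng=None,
    seed: Optional[int] = None,
    training: bool = True,
) -> Tensor:
    """lambda * E[(||grad_x D(x~)||_2 - 1)^2] at x~ = eps*real + (1-eps)*fake.

    eps is drawn uniform per batch item; the returned tensor is part of the
    computation graph, so minimizing it propagates second-order information
    into the critic weights (double backprop). The interpolates are an
    auxiliary evaluation, not data: any batch-norm running statistics the
    critic keeps are restored afterwards so the penalty pass is
    side-effect-free.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    x_real = np.asarray(x_real, dtype=float)
    x_fake = np.asarray(x_fake, dtype=float)
    if x_real.shape != x_fake.shape:
        raise ShapeError("real and fake batches must share a shape")
    B = x_real.shape[0]
    eps = rng.uniform(0.0, 1.0, size=(B,) + (1,) * (x_real.ndim - 1))
    x_hat = Tensor(eps * x_real + (1.0 - eps) * x_fake, requires_grad=True)
    saved = {}
    for key, norm in getattr(critic, "norms", {}).items():
        if hasattr(norm, "running_mean"):
            saved[key] = (norm.running_mean.copy(), norm.running_var.copy())
    try:
        scores = critic.forward(x_hat, training=training)
    finally:
        for key, (m, v) in saved.items():
            critic.norms[key].running_mean = m
            critic.norms[key].running_var = v
    (gx,) = ad.grad(scores.sum(), [x_hat])
    if not np.all(np.isfinite(gx.data)):
        raise DivergenceError("non-finite critic gradients at interpolates")
    sq = (gx * gx).sum(axis=tuple(range(1, x_real.ndim)))
    norms = (sq + 1e-12) ** 0.5
    return lambda_gp * ((norms - 1.0) ** 2).mean()


def wgan_critic_loss(d_real, d_fake, gp=0.0) -> Tensor:
    """E[D(fake)] - E[D(real)] + gp, the quantity the critic minimizes."""
    d_real, d_fake = ad._ensure(d_real), ad._ensure(d_fake)
    return d_fake.mean() - d_real.mean() + gp


def wgan_generator_loss(d_fake) -> Tensor:
    """-E[D(fake)]: the generator pushes critic scores on fakes upward."""
    return -ad._ensure(d_fake).mean()


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class Adam:
    """Adam over a fixed list of parameter tensors (updates .data in place)."""

    def __init__(self, params: List[Tensor], lr: float, betas=(0.5, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, grads: List[Tensor]):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data
            m *= self.b1
            m += (1 - self.b1) * gd
            v *= self.b2
            v += (1 - self.b2) * gd * gd
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def _make_generator(arch: str, n_channels: int, rng, generator_kwargs=None):
    generator_kwargs = dict(generator_kwargs or {})
    if arch == "lstm":
        cfg = LSTMGeneratorConfig(input_size=n_channels, **generator_kwargs)
        return LSTMGenerator(cfg, rng=rng)
    if arch == "resnet":
        cfg = ResNetGeneratorConfig(n_channels=n_channels, **generator_kwargs)
        return ResNetGenerator(cfg, rng=rng)
    raise UsageError(f"unknown generator architecture {arch!r}")


def _check_finite(trace: TrainingTrace, *values):
    for v in values:
        if not np.isfinite(v):
            raise DivergenceError("training diverged (non-finite loss)", trace=trace)


def train(
    pairs: PairedEpochSet,
    g_arch: str = "lstm",
    cfg: TrainingConfig = None,
    generator_kwargs: Optional[dict] = None,
    discriminator_config: Optional[DiscriminatorConfig] = None,
):
    """Adversarial training on noisy/clean paired epochs.

    Returns ``(generator, discriminator, trace)``. In ``lsgan`` mode each
    minibatch triggers one discriminator update (squared-error labels) and
    one generator update (adversarial + content). In the wgan modes the
    critic takes a step on every minibatch and the generator on every
    ``n_critic``-th, with the gradient penalty added only under
    ``wgan_gp``. Optimizers are Adam with the configured rates and betas.
    Optional early stopping monitors content loss on a 90/10 held-out
    split. Fully deterministic for a fixed ``cfg.seed``.
    """
    if cfg is None:
        cfg = TrainingConfig()
    if pairs.n_pairs == 0:
        raise UsageError("cannot train on an empty paired set")
    n_channels = pairs.clean.shape[1]
    L = pairs.epoch_len

    if discriminator_config is None:
        discriminator_config = DiscriminatorConfig(in_channels=n_channels)
    if L % discriminator_config.downsample != 0:
        raise ShapeError(
            f"epoch length {L} not divisible by the discriminator's "
            f"downsampling factor {discriminator_config.downsample}"
        )

    root = np.random.SeedSequence(cfg.seed)
    init_rng, shuffle_rng, eps_rng = (np.random.default_rng(s) for s in root.spawn(3))

    gen = _make_generator(g_arch, n_channels, init_rng, generator_kwargs)
    disc = Discriminator(discriminator_config, rng=init_rng).build(L, rng=init_rng)

    opt_g = Adam(gen.parameters(), lr=cfg.lr_g, betas=cfg.betas)
    opt_d = Adam(disc.parameters(), lr=cfg.lr_d, betas=cfg.betas)

    # optional held-out split for early stopping
    idx = np.arange(pairs.n_pairs)
    if cfg.early_stop_patience is not None and pairs.n_pairs >= 10:
        shuffle_rng.shuffle(idx)
        n_val = max(1, pairs.n_pairs // 10)
        val_idx, train_idx = idx[:n_val], idx[n_val:]
    else:
        val_idx, train_idx = np.array([], dtype=int), idx

    noisy = pairs.noisy[train_idx]
    clean = pairs.clean[train_idx]
    val_noisy = pairs.noisy[val_idx]
    val_clean = pairs.clean[val_idx]

    trace = TrainingTrace()
    best_val = np.inf
    stale = 0

    for epoch in range(cfg.epochs):
        order = np.arange(noisy.shape[0])
        shuffle_rng.shuffle(order)
        batches = [
            order[s : s + cfg.batch_size]
            for s in range(0, len(order), cfg.batch_size)
        ]
        for it, batch in enumerate(batches):
            xb = Tensor(noisy[batch])
            yb = Tensor(clean[batch])

            if cfg.loss_mode == "lsgan":
                # --- discriminator step
                fake = gen.forward_epochs(xb, training=True)
                d_real = disc.forward(yb, training=True)
                d_fake = disc.forward(Tensor(fake.data), training=True)
                d_loss = lsgan_discriminator_loss(d_real, d_fake)
                opt_d.step(ad.grad(d_loss, disc.parameters()))
                # --- generator step
                fake = gen.forward_epochs(xb, training=True)
                d_fake_g = disc.forward(fake, training=True)
                g_loss = lsgan_generator_loss(d_fake_g, fake, yb, cfg.adv_weight)
                opt_g.step(ad.grad(g_loss, gen.parameters()))
                gp_val = 0.0
            else:
                # --- critic step (every minibatch)
                fake = gen.forward_epochs(xb, training=True)
                fake_const = Tensor(fake.data)
                d_real = disc.forward(yb, training=True)
                d_fake = disc.forward(fake_const, training=True)
                if cfg.loss_mode == "wgan_gp":
                    gp = gradient_penalty(
                        disc, yb.data, fake_const.data, cfg.lambda_gp, rng=eps_rng
                    )
                    gp_val = float(gp.data)
                else:
                    gp = 0.0
                    gp_val = 0.0
                d_loss = wgan_critic_loss(d_real, d_fake, gp)
                opt_d.step(ad.grad(d_loss, disc.parameters()))
                # --- generator step every n_critic minibatches
                if (it + 1) % cfg.n_critic == 0:
                    fake = gen.forward_epochs(xb, training=True)
                    d_fake_g = disc.forward(fake, training=True)
                    g_loss = wgan_generator_loss(d_fake_g)
                    opt_g.step(ad.grad(g_loss, gen.parameters()))
                else:
                    g_loss = Tensor(np.nan)

            d_val = float(d_loss.data)
            g_val = float(g_loss.data)
            if np.isnan(g_val) and cfg.loss_mode != "lsgan":
                g_val = trace.g_loss[-1] if trace.g_loss else 0.0
            trace.d_loss.append(d_val)
            trace.g_loss.append(g_val)
            trace.gp.append(gp_val)
            _check_finite(trace, d_val, g_val, gp_val)

        trace.epoch_boundaries.append(len(trace.d_loss))

        if len(val_idx) > 0:
            out = gen.forward_epochs(Tensor(val_noisy), training=False)
            vloss = float(content_loss(out, Tensor(val_clean)).data)
            trace.val_content.append(vloss)
            if vloss < best_val - 1e-12:
                best_val = vloss
                stale = 0
            else:
                stale += 1
                if cfg.early_stop_patience is not None and stale >= cfg.early_stop_patience:
                    break

    return gen, disc, trace


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def denoise_epochs(gen, epochs: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Run the generator over (n, C, L) epochs in inference mode."""
    epochs = np.asarray(epochs, dtype=float)
    outs = []
    for s in range(0, epochs.shape[0], batch_size):
        out = gen.forward_epochs(Tensor(epochs[s : s + batch_size]), training=False)
        outs.append(out.data)
    return np.concatenate(outs, axis=0)


def denoise(
    gen,
    rec: EEGRecording,
    norm: Optional[NormalizationState] = None,
    epoch_len: int = 512,
    tolerance: float = 0.05,
) -> EEGRecording:
    """Denoise a whole recording with a trained generator.

    The recording must already be min-max normalized (values in [0, 1] up
    to ``tolerance``); it is cut into non-overlapping epochs (the tail is
    edge-padded to a full epoch and trimmed after), each epoch is mapped
    through the generator, and the stream is stitched back. When ``norm``
    is given the inverse scaling is applied to the output.
    """
    lo, hi = rec.data.min(), rec.data.max()
    if lo < -tolerance or hi > 1.0 + tolerance:
        raise UsageError(
            f"input range [{lo:.3g}, {hi:.3g}] is not min-max normalized; "
            "run minmax_normalize first"
        )
    n = rec.n_samples
    pad = (-n) % epoch_len
    data = rec.data
    if pad:
        data = np.concatenate([data, np.repeat(data[:, -1:], pad, axis=1)], axis=1)
    epochs = data.reshape(rec.n_channels, -1, epoch_len).transpose(1, 0, 2)
    den = denoise_epochs(gen, epochs)
    stitched = den.transpose(1, 0, 2).reshape(rec.n_channels, -1)[:, :n]
    out = EEGRecording(
        channel_names=list(rec.channel_names),
        sample_rate=rec.sample_rate,
        data=stitched,
        labels=None if rec.labels is None else list(rec.labels),
    )
    if norm is not None:
        out = _denorm_rec(out, norm)
    return out
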
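"""The three network architectures: LSTM generator, residual-CNN generator,
and the 8-layer CNN discriminator/critic.

All three operate on min-max-normalized epochs. The generators map a noisy
epoch to a denoised one of identical shape, squashed through a sigmoid so
outputs live in [0, 1] like the normalized targets; the discriminator maps
an epoch to one scalar — a probability under the sigmoid head (standard
GAN) or an unbounded "realness" score under the linear head (WGAN critic).

Construction with ``rng=None`` yields all-zero weights (and identity batch
norm), which pins the forward passes to known constants — sigmoid heads
output exactly 0.5, linear heads exactly 0 — a property the test-suite uses
to detect architecture drift.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .exceptions import ShapeError, UsageError

__all__ = [
    "BatchNorm1d",
    "LSTMGeneratorConfig",
    "LSTMGenerator",
    "ResNetGeneratorConfig",
    "ResNetGenerator",
    "DiscriminatorConfig",
    "Discriminator",
    "save_model",
    "load_model",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


class BatchNorm1d:
    """Batch normalization over (batch, time) for (B, C, L) tensors.

    Training mode normalizes with batch statistics (differentiable);
    inference mode uses the running averages, making forward passes
    deterministic functions of (params, input).
    """

    def __init__(self, n_channels: int):
        self.gamma = Tensor(np.ones(n_channels), requires_grad=True)
        self.beta = Tensor(np.zeros(n_channels), requires_grad=True)
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        C = x.shape[1]
        if training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2), keepdims=True)
            m = _BN_MOMENTUM
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(C)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(C)
        else:
            mu = Tensor(self.running_mean.reshape(1, C, 1))
            var = Tensor(self.running_var.reshape(1, C, 1))
        xn = (x - mu) * ((var + _BN_EPS) ** -0.5)
        return xn * self.gamma.reshape(1, C, 1) + self.beta.reshape(1, C, 1)

    def parameters(self):
        return [self.gamma, self.beta]

    def state(self) -> Dict[str, np.ndarray]:
        return {
            "gamma": self.gamma.data,
            "beta": self.beta.data,
            "running_mean": self.running_mean,
            "running_var": self.running_var,
        }

    def load_state(self, st):
        self.gamma.data = np.asarray(st["gamma"], dtype=float)
        self.beta.data = np.asarray(st["beta"], dtype=float)
        self.running_mean = np.asarray(st["running_mean"], dtype=float)
        self.running_var = np.asarray(st["running_var"], dtype=float)


class LayerNorm1d:
    """Per-sample normalization over (channel, time); WGAN-friendly."""

    def __init__(self, n_channels: int):
        self.gamma = Tensor(np.ones(n_channels), requires_grad=True)
        self.beta = Tensor(np.zeros(n_channels), requires_grad=True)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        C = x.shape[1]
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = ((x - mu) ** 2).mean(axis=(1, 2), keepdims=True)
        xn = (x - mu) * ((var + _BN_EPS) ** -0.5)
        return xn * self.gamma.reshape(1, C, 1) + self.beta.reshape(1, C, 1)

    def parameters(self):
        return [self.gamma, self.beta]

    def state(self):
        return {"gamma": self.gamma.data, "beta": self.beta.data}

    def load_state(self, st):
        self.gamma.data = np.asarray(st["gamma"], dtype=float)
        self.beta.data = np.asarray(st["beta"], dtype=float)


class _Identity:
    def __call__(self, x, training):
        return x

    def parameters(self):
        return []

    def state(self):
        return {}

    def load_state(self, st):
        pass


def _init(rng, shape, fan_in):
    """He-style Gaussian init, or zeros when no generator is supplied."""
    if rng is None:
        return np.zeros(shape)
    return rng.standard_normal(shape) * np.sqrt(1.0 / max(fan_in, 1))


# ---------------------------------------------------------------------------
# LSTM generator
# ---------------------------------------------------------------------------


@dataclass
class LSTMGeneratorConfig:
    """Shape/behavior of the recurrent generator.

    ``input_size`` is the number of EEG channels treated as per-timestep
    features; ``output_activation`` constrains the reconstruction range —
    ``sigmoid`` matches [0, 1]-normalized signals (the default), ``tanh``
    and ``none`` are selectable.
    """

    input_size: int = 1
    hidden_size: int = 64
    output_size: Optional[int] = None
    output_activation: str = "sigmoid"

    def __post_init__(self):
        if self.output_size is None:
            self.output_size = self.input_size
        if self.output_activation not in ("sigmoid", "tanh", "none"):
            raise UsageError(f"unknown output_activation {self.output_activation!r}")


class LSTMGenerator:
    """Single-layer LSTM followed by a per-timestep linear map.

    Implements the classic gated recurrence — forget/input/output gates and
    a candidate cell state:

        f_t = sigma(W_f x_t + U_f h_{t-1} + b_f)
        i_t = sigma(W_i x_t + U_i h_{t-1} + b_i)
        c~_t = tanh(W_c x_t + U_c h_{t-1} + b_c)
        c_t = f_t * c_{t-1} + i_t * c~_t
        o_t = sigma(W_o x_t + U_o h_{t-1} + b_o)
        h_t = o_t * tanh(c_t)
        y_t = act(W_fc h_t + b_fc)

    with h_0 = c_0 = 0. Output length always equals input length.
    """

    arch = "lstm"

    def __init__(self, config: LSTMGeneratorConfig, rng=None):
        self.config = config
        H, F, O = config.hidden_size, config.input_size, config.output_size
        self.params: Dict[str, Tensor] = {}
        for gate in "fico":
            self.params[f"W_{gate}"] = Tensor(_init(rng, (H, F), F), requires_grad=True)
            self.params[f"U_{gate}"] = Tensor(_init(rng, (H, H), H), requires_grad=True)
            self.params[f"b_{gate}"] = Tensor(np.zeros(H), requires_grad=True)
        self.params["W_fc"] = Tensor(_init(rng, (O, H), H), requires_grad=True)
        self.params["b_fc"] = Tensor(np.zeros(O), requires_grad=True)

    def parameters(self):
        return list(self.params.values())

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        """Map (B, L, F) to (B, L, output_size)."""
        B, L, F = x.shape
        if F != self.config.input_size:
            raise ShapeError(f"expected {self.config.input_size} features, got {F}")
        H = self.config.hidden_size
        p = self.params
        WT = {g: ad.transpose(p[f"W_{g}"], (1, 0)) for g in "fico"}
        UT = {g: ad.transpose(p[f"U_{g}"], (1, 0)) for g in "fico"}
        W_fcT = ad.transpose(p["W_fc"], (1, 0))

        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outs = []
        for t in range(L):
            x_t = x[:, t, :]
            f = ad.sigmoid(x_t @ WT["f"] + h @ UT["f"] + p["b_f"])
            i = ad.sigmoid(x_t @ WT["i"] + h @ UT["i"] + p["b_i"])
            c_tilde = ad.tanh(x_t @ WT["c"] + h @ UT["c"] + p["b_c"])
            c = f * c + i * c_tilde
            o = ad.sigmoid(x_t @ WT["o"] + h @ UT["o"] + p["b_o"])
            h = o * ad.tanh(c)
            y_t = h @ W_fcT + p["b_fc"]
            outs.append(y_t.reshape(B, 1, self.config.output_size))
        y = ad.concat(outs, axis=1)
        if self.config.output_activation == "sigmoid":
            y = ad.sigmoid(y)
        elif self.config.output_activation == "tanh":
            y = ad.tanh(y)
        return y

    def forward_epochs(self, x: Tensor, training: bool = False) -> Tensor:
        """Epoch layout (B, C, L): channels become per-timestep features."""
        y = self.forward(ad.transpose(x, (0, 2, 1)), training=training)
        return ad.transpose(y, (0, 2, 1))

    # -- persistence -----------------------------------------------------
    def state(self):
        return {f"param.{k}": v.data for k, v in self.params.items()}

    def load_state(self, st):
        for k in self.params:
            self.params[k].data = np.asarray(st[f"param.{k}"], dtype=float)


# ---------------------------------------------------------------------------
# residual CNN generator
# ---------------------------------------------------------------------------


@dataclass
class ResNetGeneratorConfig:
    """Shape of the residual generator.

    The initial stride-2 convolution halves the sequence, the stride-2
    transposed convolution at the end restores it, so input and output
    lengths match (even lengths only). ``n_blocks`` defaults to 16 residual
    blocks of two conv+batch-norm pairs each, all with kernel size 3.
    """

    n_channels: int = 1
    base_filters: int = 64
    n_blocks: int = 16
    kernel_size: int = 3


class ResNetGenerator:
    """Conv → 16 residual blocks → transposed conv → sigmoid output conv."""

    arch = "resnet"

    def __init__(self, config: ResNetGeneratorConfig, rng=None):
        self.config = config
        C, Fb, K = config.n_channels, config.base_filters, config.kernel_size
        self.params: Dict[str, Tensor] = {}
        self.bns: Dict[str, BatchNorm1d] = {}

        def conv(name, c_out, c_in):
            self.params[f"{name}.w"] = Tensor(
                _init(rng, (c_out, c_in, K), c_in * K), requires_grad=True
            )
            self.params[f"{name}.b"] = Tensor(np.zeros(c_out), requires_grad=True)

        conv("conv0", Fb, C)
        self.bns["bn0"] = BatchNorm1d(Fb)
        for k in range(config.n_blocks):
            conv(f"block{k}.conv_a", Fb, Fb)
            self.bns[f"block{k}.bn_a"] = BatchNorm1d(Fb)
            conv(f"block{k}.conv_b", Fb, Fb)
            self.bns[f"block{k}.bn_b"] = BatchNorm1d(Fb)
        # transposed conv weight layout: (C_in, C_out, K)
        self.params["deconv.w"] = Tensor(
            _init(rng, (Fb, Fb, K), Fb * K), requires_grad=True
        )
        self.params["deconv.b"] = Tensor(np.zeros(Fb), requires_grad=True)
        self.bns["bn_up"] = BatchNorm1d(Fb)
        conv("conv_out", C, Fb)

    def parameters(self):
        ps = list(self.params.values())
        for bn in self.bns.values():
            ps.extend(bn.parameters())
        return ps

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def forward_epochs(self, x: Tensor, training: bool = False) -> Tensor:
        """Map (B, C, L) to (B, C, L); L must be even."""
        B, C, L = x.shape
        if C != self.config.n_channels:
            raise ShapeError(f"expected {self.config.n_channels} channels, got {C}")
        if L % 2 != 0:
            raise ShapeError(
                f"sequence length {L} must be divisible by 2: the stride-2 "
                "down/up-sampling pair restores even lengths only"
            )
        p, bn = self.params, self.bns
        pad = self.config.kernel_size // 2
        y = ad.conv1d(x, p["conv0.w"], p["conv0.b"], stride=2, padding=pad)
        y = ad.relu(bn["bn0"](y, training))
        for k in range(self.config.n_blocks):
            r = ad.conv1d(y, p[f"block{k}.conv_a.w"], p[f"block{k}.conv_a.b"], stride=1, padding=pad)
            r = ad.relu(bn[f"block{k}.bn_a"](r, training))
            r = ad.conv1d(r, p[f"block{k}.conv_b.w"], p[f"block{k}.conv_b.b"], stride=1, padding=pad)
            r = bn[f"block{k}.bn_b"](r, training)
            y = ad.relu(y + r)
        y = ad.conv_transpose1d(
            y, p["deconv.w"], p["deconv.b"], stride=2, padding=pad, output_padding=1
        )
        y = ad.relu(bn["bn_up"](y, training))
        y = ad.conv1d(y, p["conv_out.w"], p["conv_out.b"], stride=1, padding=pad)
        return ad.sigmoid(y)

    def state(self):
        st = {f"param.{k}": v.data for k, v in self.params.items()}
        for name, bn in self.bns.items():
            for k, v in bn.state().items():
                st[f"bn.{name}.{k}"] = v
        return st

    def load_state(self, st):
        for k in self.params:
            self.params[k].data = np.asarray(st[f"param.{k}"], dtype=float)
        for name, bn in self.bns.items():
            bn.load_state({key: st[f"bn.{name}.{key}"] for key in bn.state()})


# ---------------------------------------------------------------------------
# discriminator / critic
# ---------------------------------------------------------------------------


@dataclass
class DiscriminatorConfig:
    """The convolutional discriminator/critic.

    ``n_layers`` conv layers, kernel 3, strides alternating 1, 2; the filter
    count starts at ``base_filters`` and doubles every two layers
    (64, 64, 128, 128, 256, 256, 512, 512 at the defaults), then a
    projection conv widens to ``proj_filters`` features before flattening,
    so the flattened width is ``proj_filters * seq_len / 2**(n_layers/2)``
    (1024 * L / 16 at the defaults). ``head`` selects the sigmoid
    (probability) or linear (Wasserstein critic) output; ``norm`` selects
    batch norm (the printed architecture), layer norm, or none.
    """

    in_channels: int = 1
    base_filters: int = 64
    n_layers: int = 8
    proj_filters: int = 1024
    kernel_size: int = 3
    leaky_slope: float = 0.2
    head: str = "sigmoid"
    norm: str = "batch"

    def __post_init__(self):
        if self.head not in ("sigmoid", "linear"):
            raise UsageError(f"head must be 'sigmoid' or 'linear', got {self.head!r}")
        if self.norm not in ("batch", "layer", "none"):
            raise UsageError(f"norm must be batch|layer|none, got {self.norm!r}")
        if self.n_layers % 2 != 0:
            raise UsageError("n_layers must be even (stride pattern 1,2 repeated)")

    @property
    def filters(self):
        return [self.base_filters * 2 ** (i // 2) for i in range(self.n_layers)]

    @property
    def strides(self):
        return [1 if i % 2 == 0 else 2 for i in range(self.n_layers)]

    @property
    def downsample(self) -> int:
        """Total temporal downsampling factor (16 at the defaults)."""
        return 2 ** (self.n_layers // 2)


class Discriminator:
    """Eight-layer (by default) 1-D CNN scoring epochs as real vs generated."""

    def __init__(self, config: DiscriminatorConfig, rng=None):
        self.config = config
        K = config.kernel_size
        self.params: Dict[str, Tensor] = {}
        self.norms: Dict[str, object] = {}
        c_in = config.in_channels
        for i, (f, s) in enumerate(zip(config.filters, config.strides)):
            self.params[f"conv{i}.w"] = Tensor(
                _init(rng, (f, c_in, K), c_in * K), requires_grad=True
            )
            self.params[f"conv{i}.b"] = Tensor(np.zeros(f), requires_grad=True)
            if i > 0:  # no normalization after the first layer, as printed
                self.norms[f"norm{i}"] = self._make_norm(f)
            c_in = f
        self.params["proj.w"] = Tensor(
            _init(rng, (config.proj_filters, c_in, K), c_in * K), requires_grad=True
        )
        self.params["proj.b"] = Tensor(np.zeros(config.proj_filters), requires_grad=True)
        self.norms["norm_proj"] = self._make_norm(config.proj_filters)
        # dense layer is created lazily once the sequence length is known
        self._dense_in: Optional[int] = None

    def _make_norm(self, n_feat):
        if self.config.norm == "batch":
            return BatchNorm1d(n_feat)
        if self.config.norm == "layer":
            return LayerNorm1d(n_feat)
        return _Identity()

    def _ensure_dense(self, flat_width: int, rng=None):
        if self._dense_in is None:
            self._dense_in = flat_width
            self.params["dense.w"] = Tensor(
                _init(rng, (1, flat_width), flat_width), requires_grad=True
            )
            self.params["dense.b"] = Tensor(np.zeros(1), requires_grad=True)
        elif self._dense_in != flat_width:
            raise ShapeError(
                f"dense layer built for flattened width {self._dense_in}, got {flat_width}"
            )

    def flattened_width(self, seq_len: int) -> int:
        return self.config.proj_filters * seq_len // self.config.downsample

    def build(self, seq_len: int, rng=None):
        """Materialize the dense head for a fixed epoch length."""
        ds = self.config.downsample
        if seq_len % ds != 0:
            raise ShapeError(
                f"sequence length {seq_len} must be divisible by the "
                f"downsampling factor {ds} ({self.config.n_layers} layers, "
                "strides alternating 1 and 2)"
            )
        self._ensure_dense(self.flattened_width(seq_len), rng)
        return self

    def parameters(self):
        ps = list(self.params.values())
        for n in self.norms.values():
            ps.extend(n.parameters())
        return ps

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        """Score a batch of epochs (B, C, L) -> (B,)."""
        B, C, L = x.shape
        cfg = self.config
        if C != cfg.in_channels:
            raise ShapeError(f"expected {cfg.in_channels} channels, got {C}")
        if L % cfg.downsample != 0:
            raise ShapeError(
                f"sequence length {L} must be divisible by {cfg.downsample}"
            )
        self._ensure_dense(self.flattened_width(L))
        pad = cfg.kernel_size // 2
        y = x
        for i, s in enumerate(cfg.strides):
            y = ad.conv1d(y, self.params[f"conv{i}.w"], self.params[f"conv{i}.b"],
                          stride=s, padding=pad)
            if i > 0:
                y = self.norms[f"norm{i}"](y, training)
            y = ad.leaky_relu(y, cfg.leaky_slope)
        y = ad.conv1d(y, self.params["proj.w"], self.params["proj.b"], stride=1, padding=pad)
        y = self.norms["norm_proj"](y, training)
        y = ad.leaky_relu(y, cfg.leaky_slope)
        flat = y.reshape(B, self._dense_in)
        score = flat @ ad.transpose(self.params["dense.w"], (1, 0)) + self.params["dense.b"]
        score = score.reshape(B)
        if cfg.head == "sigmoid":
            score = ad.sigmoid(score)
        return score

    def state(self):
        st = {f"param.{k}": v.data for k, v in self.params.items()}
        for name, n in self.norms.items():
            for k, v in n.state().items():
                st[f"norm.{name}.{k}"] = v
        if self._dense_in is not None:
            st["meta.dense_in"] = np.array(self._dense_in)
        return st

    def load_state(self, st):
        if "meta.dense_in" in st:
            self._dense_in = int(st["meta.dense_in"])
            if "param.dense.w" not in {f"param.{k}" for k in self.params}:
                self.params["dense.w"] = Tensor(
                    np.zeros((1, self._dense_in)), requires_grad=True
                )
                self.params["dense.b"] = Tensor(np.zeros(1), requires_grad=True)
        for k in self.params:
            self.params[k].data = np.asarray(st[f"param.{k}"], dtype=float)
        for name, n in self.norms.items():
            sub = {}
            for key in n.state():
                sub[key] = st[f"norm.{name}.{key}"]
            n.load_state(sub)


# ---------------------------------------------------------------------------
# persistence: portable key->array archive + JSON architecture manifest
# ---------------------------------------------------------------------------

_MODEL_CLASSES = {
    "lstm": (LSTMGenerator, LSTMGeneratorConfig),
    "resnet": (ResNetGenerator, ResNetGeneratorConfig),
    "discriminator": (Discriminator, DiscriminatorConfig),
}


def _model_kind(model) -> str:
    if isinstance(model, LSTMGenerator):
        return "lstm"
    if isinstance(model, ResNetGenerator):
        return "resnet"
    if isinstance(model, Discriminator):
        return "discriminator"
    raise UsageError(f"cannot persist {type(model).__name__}")


def save_model(model, path):
    """Write weights (.npz) plus an architecture manifest (.json).

    The manifest alone suffices to rebuild the network; the archive holds
    every weight, bias and normalization statistic under stable keys.
    """
    path = Path(path)
    kind = _model_kind(model)
    np.savez(path.with_suffix(".npz"), **model.state())
    manifest = {"kind": kind, "config": asdict(model.config)}
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_model(path):
    """Rebuild a model from :func:`save_model` output."""
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    cls, cfg_cls = _MODEL_CLASSES[manifest["kind"]]
    model = cls(cfg_cls(**manifest["config"]))
    with np.load(path.with_suffix(".npz"), allow_pickle=False) as z:
        model.load_state({k: z[k] for k in z.files})
    return model
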
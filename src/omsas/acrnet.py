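"""ACRNet: an attention-condenser residual encoder–decoder for binary
tumor segmentation of 2-D MRI slices.

The network is deliberately parameter-sparse. Ordinary convolutions are
replaced by two kinds of blocks:

* **reservation block** — 1x1 convolution + channel layer-norm + ReLU;
  changes only the channel count.
* **retracting block** — depthwise 3x3 convolution (one kernel per
  channel) followed by a pointwise 1x1 convolution; extracts spatial
  features at a fraction of the parameters of a full 3x3 convolution.

Residual units stack retracting blocks with an additive skip connection.
Each encoder stage ends in an *attention condenser*: the feature map is
condensed spatially and across channels, passed through a small embedding,
expanded back, and squashed through a sigmoid to produce per-channel,
per-position gates in (0, 1) that rescale the input — selective attention
that can only attenuate, never amplify.

The channel-attention primitive (global average squeeze, two-layer
excitation, channel-wise gating) is exposed as standalone functions
`channel_squeeze`, `channel_excite`, `apply_attention` for inspection and
testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (Adam, ChannelLayerNorm, Conv1x1, DepthwiseConv3x3, MaxPool2,
                 Module, Param, ReLU, Sequential, Sigmoid, UpsampleNearest2)

__all__ = [
    "channel_squeeze", "channel_excite", "apply_attention",
    "CondenserConfig", "ACRNetConfig",
    "ReservationBlock", "RetractingBlock", "ResidualUnit", "AttentionCondenser",
    "ACRNet", "build_acrnet", "count_parameters",
    "tiny_config", "default_config",
]


# ---------------------------------------------------------------------------
# channel attention primitive (squeeze -> excite -> gate)
# ---------------------------------------------------------------------------

def channel_squeeze(feature_map: np.ndarray) -> np.ndarray:
    """Compress a (C, H, W) feature map to one scalar per channel.

    z_c is the spatial mean of channel c — the global-average-pooling
    "squeeze" step of channel attention.
    """
    m = np.asarray(feature_map, dtype=float)
    if m.ndim != 3:
        raise ValueError(f"expected a (C, H, W) feature map, got shape {m.shape}")
    return m.mean(axis=(1, 2))


def channel_excite(z: np.ndarray, w_sigma: np.ndarray,
                   w_rho: np.ndarray) -> np.ndarray:
    """Two-layer excitation: e = sigmoid(W_rho @ relu(W_sigma @ z)).

    ``w_sigma`` maps the C squeezed values to the bottleneck width and
    ``w_rho`` maps back to C. Every gate lies strictly in (0, 1).
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    w_sigma = np.atleast_2d(np.asarray(w_sigma, dtype=float))
    w_rho = np.atleast_2d(np.asarray(w_rho, dtype=float))
    if w_sigma.shape[1] != z.shape[0]:
        raise ValueError(
            f"W_sigma has {w_sigma.shape[1]} columns but z has {z.shape[0]} channels")
    if w_rho.shape[1] != w_sigma.shape[0]:
        raise ValueError(
            f"W_rho expects {w_rho.shape[1]} inputs but bottleneck is {w_sigma.shape[0]}")
    hidden = np.maximum(w_sigma @ z, 0.0)
    return 1.0 / (1.0 + np.exp(-(w_rho @ hidden)))


def apply_attention(feature_map: np.ndarray, gates: np.ndarray) -> np.ndarray:
    """Rescale each channel of a (C, H, W) map by its gate: M'[c] = e_c * M[c]."""
    m = np.asarray(feature_map, dtype=float)
    e = np.asarray(gates, dtype=float).reshape(-1)
    if e.shape[0] != m.shape[0]:
        raise ValueError(f"{e.shape[0]} gates for {m.shape[0]} channels")
    return m * e[:, None, None]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CondenserConfig:
    """Attention-condenser hyperparameters.

    ratio
        Channel bottleneck divisor: the condensed representation has
        ``max(1, c // ratio)`` channels. Larger ratio = fewer parameters.
    spatial_condense
        Spatial downsampling factor of the condensed layer (power of two;
        1 disables spatial condensing).
    """
    ratio: int = 4
    spatial_condense: int = 2

    def __post_init__(self):
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")
        if self.spatial_condense < 1 or self.spatial_condense & (self.spatial_condense - 1):
            raise ValueError("spatial_condense must be a power of two >= 1")


@dataclass(frozen=True)
class ACRNetConfig:
    """Full architecture description of an ACRNet instance."""
    input_size: tuple[int, int] = (256, 256)
    stage_widths: tuple[int, ...] = (32, 64, 128, 256)
    units_per_stage: int = 2
    condenser_ratio: int = 4
    spatial_condense: int = 2
    seed: int = 0

    def __post_init__(self):
        if len(self.stage_widths) < 2:
            raise ValueError("need at least two encoder stages")
        if any(w < 1 for w in self.stage_widths):
            raise ValueError("stage widths must be positive")
        if self.units_per_stage < 1:
            raise ValueError("units_per_stage must be >= 1")
        h, w = self.input_size
        div = 2 ** (len(self.stage_widths) - 1) * self.spatial_condense
        if h % div or w % div:
            raise ValueError(
                f"input size {h}x{w} must be divisible by {div} "
                f"(pooling across {len(self.stage_widths)} stages plus condenser)")


def default_config(seed: int = 0) -> ACRNetConfig:
    """The default 4-stage architecture (fits the lightweight budget)."""
    return ACRNetConfig(seed=seed)


def tiny_config(seed: int = 0, input_size: tuple[int, int] = (64, 64)) -> ACRNetConfig:
    """A small 3-stage variant used for probes and examples."""
    return ACRNetConfig(input_size=input_size, stage_widths=(16, 32, 64),
                        units_per_stage=1, condenser_ratio=2, seed=seed)


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

class ReservationBlock(Module):
    """1x1 conv + channel layer-norm + ReLU; changes only the channel count."""

    def __init__(self, in_channels: int, out_channels: int, rng):
        self.conv = Conv1x1(in_channels, out_channels, rng)
        self.norm = ChannelLayerNorm(out_channels)
        self.act = ReLU()
        self.body = Sequential(self.conv, self.norm, self.act)

    def forward(self, x):
        return self.body(x)

    def backward(self, grad):
        return self.body.backward(grad)

    def params(self):
        yield from self.body.params()


class RetractingBlock(Module):
    """Depthwise 3x3 followed by pointwise 1x1 — a separable feature extractor."""

    def __init__(self, in_channels: int, out_channels: int, rng):
        self.depthwise = DepthwiseConv3x3(in_channels, rng)
        self.pointwise = Conv1x1(in_channels, out_channels, rng)
        self.body = Sequential(self.depthwise, self.pointwise)

    def forward(self, x):
        return self.body(x)

    def backward(self, grad):
        return self.body.backward(grad)

    def params(self):
        yield from self.body.params()


class ResidualUnit(Module):
    """Two retracting blocks with a skip connection added before the final ReLU.

    When input and output widths differ the skip path is a 1x1 projection.
    """

    def __init__(self, in_channels: int, out_channels: int, rng):
        final_norm = ChannelLayerNorm(out_channels)
        # zero-init the residual branch's final scale: the unit starts as
        # (a ReLU of) the identity, which stabilises early optimisation
        final_norm.gamma.value[...] = 0.0
        self.f = Sequential(
            RetractingBlock(in_channels, out_channels, rng),
            ChannelLayerNorm(out_channels),
            ReLU(),
            RetractingBlock(out_channels, out_channels, rng),
            final_norm,
        )
        self.proj = (Conv1x1(in_channels, out_channels, rng)
                     if in_channels != out_channels else None)
        self.act = ReLU()

    def forward(self, x):
        skip = self.proj(x) if self.proj is not None else x
        return self.act(self.f(x) + skip)

    def backward(self, grad):
        grad = self.act.backward(grad)
        gx = self.f.backward(grad)
        gskip = self.proj.backward(grad) if self.proj is not None else grad
        return gx + gskip


class AttentionCondenser(Module):
    """Condense -> embed -> expand -> gate.

    The feature map is condensed (2x max-pool, then channel reduction to
    ``c // ratio``), embedded with one depthwise-separable convolution,
    expanded back to c channels, upsampled, and squashed through a sigmoid.
    The resulting gates in (0, 1) multiply the input elementwise, so the
    module attenuates un-attended activations and never amplifies.
    """

    def __init__(self, channels: int, cfg: CondenserConfig, rng):
        self.channels = channels
        self.cfg = cfg
        bottleneck = max(1, channels // cfg.ratio)
        condense = []
        for _ in range(cfg.spatial_condense.bit_length() - 1):
            condense.append(MaxPool2())
        condense += [Conv1x1(channels, bottleneck, rng), ReLU()]
        embed = [DepthwiseConv3x3(bottleneck, rng),
                 Conv1x1(bottleneck, bottleneck, rng), ReLU()]
        expand_conv = Conv1x1(bottleneck, channels, rng)
        # bias the gates open (sigmoid(2) ~ 0.88) so stacked condensers do
        # not attenuate the signal to nothing before training starts
        expand_conv.bias.value[...] = 2.0
        expand = [expand_conv]
        for _ in range(cfg.spatial_condense.bit_length() - 1):
            expand.append(UpsampleNearest2())
        expand.append(Sigmoid())
        self.gate_path = Sequential(*(condense + embed + expand))
        self._cache = None

    def forward(self, x):
        gates = self.gate_path(x)
        self._cache = (x, gates)
        return x * gates

    def backward(self, grad):
        x, gates = self._cache
        g_gates = self.gate_path.backward(grad * x)
        return grad * gates + g_gates

    @property
    def last_gates(self) -> np.ndarray | None:
        """Gate map (N, C, H, W) from the most recent forward pass."""
        return None if self._cache is None else self._cache[1]


# ---------------------------------------------------------------------------
# the assembled network
# ---------------------------------------------------------------------------

class ACRNet(Module):
    """Encoder–decoder over residual units with per-stage attention condensers.

    Input: (N, 1, H, W) normalized slices. Output: (N, 1, H, W) per-pixel
    tumor probabilities from a terminal 1x1 convolution + sigmoid head.
    """

    def __init__(self, config: ACRNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        widths = config.stage_widths
        ccfg = CondenserConfig(ratio=config.condenser_ratio,
                               spatial_condense=config.spatial_condense)

        self.stem = ReservationBlock(1, widths[0], rng)
        self.enc_units: list[Sequential] = []
        self.condensers: list[AttentionCondenser] = []
        self.downs: list[Sequential] = []
        for i, w in enumerate(widths):
            self.enc_units.append(Sequential(
                *[ResidualUnit(w, w, rng) for _ in range(config.units_per_stage)]))
            self.condensers.append(AttentionCondenser(w, ccfg, rng))
            if i < len(widths) - 1:
                self.downs.append(Sequential(
                    MaxPool2(), ReservationBlock(w, widths[i + 1], rng)))

        self.ups: list[UpsampleNearest2] = []
        self.merges: list[ReservationBlock] = []
        self.dec_units: list[ResidualUnit] = []
        for i in range(len(widths) - 2, -1, -1):
            self.ups.append(UpsampleNearest2())
            self.merges.append(ReservationBlock(widths[i + 1] + widths[i],
                                                widths[i], rng))
            self.dec_units.append(ResidualUnit(widths[i], widths[i], rng))

        self.head = Conv1x1(widths[0], 1, rng)
        self.out_act = Sigmoid()
        self._skip_channels = list(widths[:-1])

    # -- forward / backward -------------------------------------------------
    def forward(self, x):
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected (N, 1, H, W) input, got {x.shape}")
        h = self.stem(x)
        skips = []
        n_stage = len(self.config.stage_widths)
        for i in range(n_stage):
            h = self.enc_units[i](h)
            h = self.condensers[i](h)
            if i < n_stage - 1:
                skips.append(h)
                h = self.downs[i](h)
        for j, i in enumerate(range(n_stage - 2, -1, -1)):
            h = self.ups[j](h)
            h = np.concatenate([h, skips[i]], axis=1)
            h = self.merges[j](h)
            h = self.dec_units[j](h)
        return self.out_act(self.head(h))

    def backward(self, grad):
        grad = self.out_act.backward(grad)
        grad = self.head.backward(grad)
        n_stage = len(self.config.stage_widths)
        skip_grads: dict[int, np.ndarray] = {}
        for j in range(n_stage - 2, -1, -1):
            i = n_stage - 2 - j
            grad = self.dec_units[j].backward(grad)
            grad = self.merges[j].backward(grad)
            up_c = self.config.stage_widths[i + 1]
            grad, gskip = grad[:, :up_c], grad[:, up_c:]
            skip_grads[i] = gskip
            grad = self.ups[j].backward(grad)
        for i in range(n_stage - 1, -1, -1):
            if i < n_stage - 1:
                grad = self.downs[i].backward(grad)
                grad = grad + skip_grads[i]
            grad = self.condensers[i].backward(grad)
            grad = self.enc_units[i].backward(grad)
        return self.stem.backward(grad)

    def params(self):
        yield from self.stem.params()
        for seq in self.enc_units:
            yield from seq.params()
        for cond in self.condensers:
            yield from cond.params()
        for down in self.downs:
            yield from down.params()
        for merge in self.merges:
            yield from merge.params()
        for unit in self.dec_units:
            yield from unit.params()
        yield from self.head.params()

    # -- introspection ------------------------------------------------------
    def attention_gates(self, stage_index: int) -> np.ndarray:
        """Gates recorded by the given encoder stage's condenser (last forward)."""
        if not 0 <= stage_index < len(self.condensers):
            raise IndexError(
                f"stage_index {stage_index} out of range "
                f"[0, {len(self.condensers) - 1}]")
        gates = self.condensers[stage_index].last_gates
        if gates is None:
            raise RuntimeError("run a forward pass before requesting gates")
        return gates

    # -- serialization ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.value for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value[...] = state[f"p{i}"]

    def save(self, path) -> None:
        import json
        cfg = dict(input_size=list(self.config.input_size),
                   stage_widths=list(self.config.stage_widths),
                   units_per_stage=self.config.units_per_stage,
                   condenser_ratio=self.config.condenser_ratio,
                   spatial_condense=self.config.spatial_condense,
                   seed=self.config.seed)
        np.savez(path, __config__=json.dumps(cfg), **self.state_dict())

    @classmethod
    def load(cls, path) -> "ACRNet":
        import json
        with np.load(path, allow_pickle=False) as data:
            cfg = json.loads(str(data["__config__"]))
            model = cls(ACRNetConfig(
                input_size=tuple(cfg["input_size"]),
                stage_widths=tuple(cfg["stage_widths"]),
                units_per_stage=cfg["units_per_stage"],
                condenser_ratio=cfg["condenser_ratio"],
                spatial_condense=cfg["spatial_condense"],
                seed=cfg["seed"]))
            model.load_state_dict({k: data[k] for k in data.files
                                   if k != "__config__"})
        return model


def build_acrnet(config: ACRNetConfig | None = None) -> ACRNet:
    """Instantiate an ACRNet from a configuration (default if omitted)."""
    return ACRNet(config if config is not None else default_config())


def count_parameters(model: Module) -> int:
    """Exact count of trainable scalars in a model."""
    return model.n_params()
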
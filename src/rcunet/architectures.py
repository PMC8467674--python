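"""The three segmentation architectures: U-Net, U-Net + Res Path, RCU-Net.

RCU-Net is a U-Net whose four shortcut connections are refined by Res Paths
(chains of residual units, ``x_l = H_l(x_{l-1}) + x_{l-1}``) and which adds
a dense-block connection from the raw input straight to the last decoder
stage. The dense block runs at full input resolution (no pooling), so it
carries fine spatial detail that the encoder-decoder path loses to pooling
and up-sampling.

Default widths follow the published configuration: encoder filters
64/128/256/512/1024, Res Path unit counts 4/3/2/1 at widths 64/128/256/512,
dense block with base width F=64 and growth rate k=16 over 4 stages
(64 + 4*16 = 128 output channels), and a 128-kernel last decoder stage so
the dense output can be merged by element-wise addition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (BatchNorm2d, Conv2d, ConvTranspose2d, Identity, MaxPool2d,
                 Module, ReLU, Sequential, Sigmoid)
from .nn.init import ConfigurationError


@dataclass(frozen=True)
class BackboneConfig:
    """Shape configuration of the U-Net backbone."""

    input_extent: tuple[int, int] = (256, 256)
    input_channels: int = 1
    encoder_filters: tuple[int, ...] = (64, 128, 256, 512, 1024)
    pooling_steps: int = 4
    output_channels: int = 1

    def validate(self) -> None:
        h, w = self.input_extent
        if h <= 0 or w <= 0:
            raise ConfigurationError("input extent must be positive")
        if len(self.encoder_filters) != self.pooling_steps + 1:
            raise ConfigurationError(
                "encoder_filters must list pooling_steps + 1 widths")
        div = 2 ** self.pooling_steps
        if h % div or w % div:
            raise ConfigurationError(
                f"input extent {self.input_extent} not divisible by {div}")


@dataclass(frozen=True)
class ResPathSpec:
    """One Res Path: ``n_units`` chained residual units at ``unit_channels``."""

    level: int
    n_units: int
    unit_channels: int

    def validate(self) -> None:
        if self.n_units < 1:
            raise ConfigurationError("a Res Path needs at least one unit")
        if self.unit_channels < 1:
            raise ConfigurationError("unit_channels must be positive")


@dataclass(frozen=True)
class DenseUnitSpec:
    """Dense block: base width F, growth rate k, number of concat stages."""

    base_filters: int = 64
    growth_rate: int = 16
    stages: int = 4

    @property
    def output_channels(self) -> int:
        return self.base_filters + self.stages * self.growth_rate

    def input_channels_at(self, layer: int) -> int:
        """Channel count entering dense layer ``layer`` (1-based): F + k*(l-1)."""
        return self.base_filters + self.growth_rate * (layer - 1)

    def validate(self) -> None:
        if self.base_filters < 1 or self.stages < 0 or self.growth_rate < 0:
            raise ConfigurationError("invalid dense-unit parameters")


def default_respath_specs(cfg: BackboneConfig) -> list[ResPathSpec]:
    """4, 3, 2, 1 residual units at the encoder widths of levels 1-4."""
    n = cfg.pooling_steps
    return [ResPathSpec(level=i + 1, n_units=n - i,
                        unit_channels=cfg.encoder_filters[i])
            for i in range(n)]


def default_dense_spec(cfg: BackboneConfig) -> DenseUnitSpec:
    """Dense block scaled to the backbone: output doubles the first encoder
    width (F + stages*k = 2*F), four stages when the width allows it."""
    f0 = cfg.encoder_filters[0]
    k = f0 // 4 if f0 % 4 == 0 else 1
    return DenseUnitSpec(base_filters=f0, growth_rate=k, stages=f0 // k)


class ConvBlock(Module):
    """Two 3x3 conv + ReLU stages, the standard U-Net level block."""

    def __init__(self, in_channels: int, out_channels: int):
        super().__init__()
        self.net = Sequential(Conv2d(in_channels, out_channels), ReLU(),
                              Conv2d(out_channels, out_channels), ReLU())
        self.out_channels = out_channels

    def forward(self, x):
        return self.net(x)

    def backward(self, grad):
        return self.net.backward(grad)


class ResUnit(Module):
    """Residual unit: ReLU(H(x) + x) with H = conv-BN-ReLU-conv-BN.

    When the unit changes channel width the identity branch becomes a 1x1
    convolution projection so the addition is well-defined.
    """

    def __init__(self, in_channels: int, channels: int):
        super().__init__()
        self.body = Sequential(
            Conv2d(in_channels, channels), BatchNorm2d(channels), ReLU(),
            Conv2d(channels, channels), BatchNorm2d(channels))
        self.skip = (Identity() if in_channels == channels
                     else Conv2d(in_channels, channels, kernel_size=1))
        self.act = ReLU()

    def forward(self, x):
        return self.act(self.body(x) + self.skip(x))

    def backward(self, grad):
        g = self.act.backward(grad)
        return self.body.backward(g) + self.skip.backward(g)


class ResPath(Module):
    """A chain of residual units along one shortcut connection."""

    def __init__(self, spec: ResPathSpec, in_channels: int):
        super().__init__()
        spec.validate()
        self.spec = spec
        units = []
        ch = in_channels
        for _ in range(spec.n_units):
            units.append(ResUnit(ch, spec.unit_channels))
            ch = spec.unit_channels
        self.units = Sequential(*units)

    def forward(self, x):
        return self.units(x)

    def backward(self, grad):
        return self.units.backward(grad)


class DenseUnit(Module):
    """Dense block from the raw input: stem conv to F maps, then ``stages``
    layers each producing k maps from the concatenation of everything before
    (layer l sees F + k*(l-1) channels). Layers are BN-ReLU-conv3x3."""

    def __init__(self, spec: DenseUnitSpec, in_channels: int = 1):
        super().__init__()
        spec.validate()
        self.spec = spec
        self.stem = Conv2d(in_channels, spec.base_filters)
        layers = []
        if spec.growth_rate > 0:  # zero growth degenerates to the stem alone
            for l in range(1, spec.stages + 1):
                cin = spec.input_channels_at(l)
                layers.append(Sequential(BatchNorm2d(cin), ReLU(),
                                         Conv2d(cin, spec.growth_rate)))
        self.dense_layers = Sequential(*layers)  # container only

    def forward(self, x):
        out = self.stem(x)
        for layer in self.dense_layers.layers:
            grown = layer(out)
            out = np.concatenate([out, grown], axis=1)
        return out

    def backward(self, grad):
        k = self.spec.growth_rate
        g = grad
        for layer in reversed(self.dense_layers.layers):
            width_before = g.shape[1] - k
            g_grown = g[:, width_before:]
            g = g[:, :width_before] + layer.backward(g_grown)
        return self.stem.backward(g)


class UNetModel(Module):
    """Encoder-decoder segmentation network with optional Res Paths on the
    shortcuts and an optional dense-unit connection into the last decoder
    stage. With both disabled this is the plain U-Net; the three published
    variants are this class with different components enabled.

    Decoder stage i concatenates [shortcut features, up-sampled features]
    (in that channel order) and applies a ConvBlock. The last decoder stage
    is widened to the dense block's output width when the dense connection
    is present, so the merge is an element-wise add; a final 1x1 convolution
    and sigmoid produce the per-pixel lesion probability map.
    """

    def __init__(self, config: BackboneConfig,
                 respath_specs: list[ResPathSpec] | None = None,
                 dense_spec: DenseUnitSpec | None = None):
        super().__init__()
        config.validate()
        self.config = config
        self.respath_specs = respath_specs
        self.dense_spec = dense_spec
        f = config.encoder_filters
        n = config.pooling_steps

        if respath_specs is not None:
            if len(respath_specs) != n:
                raise ConfigurationError(
                    f"need {n} Res Path specs, got {len(respath_specs)}")
            for spec in respath_specs:
                spec.validate()

        self.last_stage_channels = f[0]
        if dense_spec is not None:
            dense_spec.validate()
            expected = 2 * f[0]
            if dense_spec.output_channels != expected:
                raise ConfigurationError(
                    f"dense output {dense_spec.output_channels} channels "
                    f"must equal the last decoder stage width {expected}")
            self.last_stage_channels = expected

        # encoder
        cin = config.input_channels
        self.encoders = Sequential(*[ConvBlock(cin if i == 0 else f[i - 1],
                                               f[i])
                                     for i in range(n + 1)])
        self.pools = Sequential(*[MaxPool2d() for _ in range(n)])

        # shortcut transforms (Res Paths or identities)
        if respath_specs is None:
            self.shortcuts = Sequential(*[Identity() for _ in range(n)])
        else:
            self.shortcuts = Sequential(
                *[ResPath(respath_specs[i], f[i]) for i in range(n)])

        # decoder, from deepest (stage n-1) to shallowest (stage 0)
        self._shortcut_channels = [
            respath_specs[i].unit_channels if respath_specs is not None
            else f[i] for i in range(n)]
        ups, decs = [], []
        deeper = f[n]
        for i in range(n - 1, -1, -1):
            ups.append(ConvTranspose2d(deeper, f[i]))
            out = self.last_stage_channels if i == 0 else f[i]
            decs.append(ConvBlock(self._shortcut_channels[i] + f[i], out))
            deeper = out
        self.ups = Sequential(*ups)
        self.decs = Sequential(*decs)

        if dense_spec is not None:
            self.dense = DenseUnit(dense_spec, config.input_channels)
        else:
            self.dense = None

        self.head = Conv2d(self.last_stage_channels, config.output_channels,
                           kernel_size=1)
        self.out_act = Sigmoid()

    @property
    def variant(self) -> str:
        if self.dense is not None:
            return "rcunet"
        return "unet_respath" if self.respath_specs is not None else "unet"

    def _check_input(self, x):
        h, w = self.config.input_extent
        if x.ndim != 4 or x.shape[1] != self.config.input_channels \
                or x.shape[2] != h or x.shape[3] != w:
            raise ValueError(
                f"expected input of shape (N, {self.config.input_channels}, "
                f"{h}, {w}), got {x.shape}")

    def forward(self, x):
        self._check_input(x)
        x = np.asarray(x, dtype=self.head.weight.data.dtype)
        n = self.config.pooling_steps
        f = self.config.encoder_filters
        enc = []
        cur = x
        for i in range(n + 1):
            if i > 0:
                cur = self.pools.layers[i - 1](cur)
            cur = self.encoders.layers[i](cur)
            enc.append(cur)
        shortcut_out = [self.shortcuts.layers[i](enc[i]) for i in range(n)]
        d = enc[n]
        for j, i in enumerate(range(n - 1, -1, -1)):
            u = self.ups.layers[j](d)
            d = self.decs.layers[j](np.concatenate([shortcut_out[i], u],
                                                   axis=1))
        if self.dense is not None:
            d = d + self.dense(x)
        return self.out_act(self.head(d))

    def backward(self, grad):
        n = self.config.pooling_steps
        f = self.config.encoder_filters
        grad = np.asarray(grad, dtype=self.head.weight.data.dtype)
        g = self.head.backward(self.out_act.backward(grad))
        gx_total = None
        if self.dense is not None:
            gx_total = self.dense.backward(g)  # add merge: grad flows to both
        enc_grad = [None] * (n + 1)
        for j, i in zip(range(n - 1, -1, -1), range(n)):
            gcat = self.decs.layers[j].backward(g)
            sc = self._shortcut_channels[i]
            g_short, g_up = gcat[:, :sc], gcat[:, sc:]
            enc_grad[i] = self.shortcuts.layers[i].backward(g_short)
            g = self.ups.layers[j].backward(g_up)
        enc_grad[n] = g
        ge = None
        for i in range(n, -1, -1):
            total = enc_grad[i] if ge is None else enc_grad[i] + ge
            gin = self.encoders.layers[i].backward(total)
            ge = self.pools.layers[i - 1].backward(gin) if i > 0 else gin
        if gx_total is not None:
            ge = ge + gx_total
        return ge

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def summary(self) -> list[dict]:
        """Per-stage extent/channel/parameter trace of the network."""
        h, w = self.config.input_extent
        f = self.config.encoder_filters
        n = self.config.pooling_steps
        rows = []

        def n_params(mod) -> int:
            return int(sum(p.data.size for p in mod.parameters()))

        for i in range(n + 1):
            rows.append({"stage": f"encoder{i + 1}",
                         "extent": (h // 2 ** i, w // 2 ** i),
                         "channels": f[i],
                         "params": n_params(self.encoders.layers[i])})
        for i in range(n):
            mod = self.shortcuts.layers[i]
            rows.append({"stage": f"shortcut{i + 1}",
                         "extent": (h // 2 ** i, w // 2 ** i),
                         "channels": f[i],
                         "params": n_params(mod),
                         "res_units": (mod.spec.n_units
                                       if isinstance(mod, ResPath) else 0)})
        for j, i in enumerate(range(n - 1, -1, -1)):
            out = self.last_stage_channels if i == 0 else f[i]
            rows.append({"stage": f"decoder{i + 1}",
                         "extent": (h // 2 ** i, w // 2 ** i),
                         "channels": out,
                         "params": (n_params(self.ups.layers[j])
                                    + n_params(self.decs.layers[j]))})
        if self.dense is not None:
            rows.append({"stage": "dense_unit", "extent": (h, w),
                         "channels": self.dense.spec.output_channels,
                         "params": n_params(self.dense)})
        rows.append({"stage": "head", "extent": (h, w),
                     "channels": self.config.output_channels,
                     "params": n_params(self.head)})
        return rows

    def save_weights(self, path) -> None:
        np.savez(path, **{k: v for k, v in self.state_dict().items()})

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})


SegModel = UNetModel

VARIANTS = ("unet", "unet_respath", "rcunet")


def build_unet(cfg: BackboneConfig | None = None) -> UNetModel:
    """Plain U-Net: raw shortcut connections, no dense unit."""
    return UNetModel(cfg or BackboneConfig())


def build_res_path(spec: ResPathSpec, in_channels: int | None = None) -> ResPath:
    """Standalone Res Path (chain of residual units) for one shortcut."""
    return ResPath(spec, in_channels if in_channels is not None
                   else spec.unit_channels)


def build_dense_unit(spec: DenseUnitSpec, in_channels: int = 1) -> DenseUnit:
    return DenseUnit(spec, in_channels)


def build_rcunet(cfg: BackboneConfig | None = None,
                 respaths: list[ResPathSpec] | None = None,
                 dense: DenseUnitSpec | None = None) -> UNetModel:
    """Full RCU-Net: Res Paths on all shortcuts + dense input connection."""
    cfg = cfg or BackboneConfig()
    return UNetModel(cfg,
                     respaths if respaths is not None
                     else default_respath_specs(cfg),
                     dense if dense is not None else default_dense_spec(cfg))


def build_variant(name: str, cfg: BackboneConfig | None = None) -> UNetModel:
    cfg = cfg or BackboneConfig()
    if name == "unet":
        return build_unet(cfg)
    if name == "unet_respath":
        return UNetModel(cfg, default_respath_specs(cfg), None)
    if name == "rcunet":
        return build_rcunet(cfg)
    raise ConfigurationError(f"unknown variant {name!r}; "
                             f"choose from {VARIANTS}")


def predict_proba(model: UNetModel, img: np.ndarray) -> np.ndarray:
    """Per-pixel lesion probability map for one image (H, W) in [0, 1]."""
    extent = model.config.input_extent
    img = np.asarray(img, dtype=np.float64)
    if img.shape != extent:
        raise ValueError(f"image extent {img.shape} does not match the "
                         f"model input extent {extent}")
    was_training = model.training
    model.eval()
    prob = model(img[None, None])[0, 0]
    if was_training:
        model.train()
    return prob


def predict_mask(model: UNetModel, img: np.ndarray,
                 threshold: float = 0.5) -> np.ndarray:
    """Binarized prediction: probability map >= threshold."""
    return predict_proba(model, img) >= threshold
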
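"""Segmentation model: encoder-decoder U-Net with skip connections.

Three presets are provided:

``resnet50-like``
    Residual encoder with 50 convolutional layers (7x7 stem + bottleneck
    stages [3, 4, 6, 3], widths 256/512/1024/2048) and a lightweight decoder
    of 8 convolutional layers distributed [2, 2, 2, 1, 1] over five bilinear
    upsampling stages, plus a 1x1 classification head. ~32M parameters.
``original-unet``
    The classic symmetric U-Net (double 3x3 convs at 64..1024 channels,
    2x2 transposed-convolution upsampling). ~31M parameters.
``small-resnet``
    A width- and depth-reduced residual variant (downsampling factor 8)
    sized for CPU desk-scale training. Same wiring, ~1e5 parameters.

The model maps a 1-channel HxW image to an HxW 3-class probability grid
(softmax over background / LV cavity / myocardium). Output spatial size
always equals input size; input sizes must be divisible by the preset's
total downsampling factor.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import nn
from .nn import (
    BasicBlock,
    BatchNorm2d,
    BilinearUp2x,
    Bottleneck,
    Conv2d,
    ConvTranspose2x2,
    Layer,
    MaxPool2x2,
    ReLU,
    Sequential,
    conv_bn_relu,
    softmax_channels,
)

ENCODER_KINDS = ("resnet50-like", "small-resnet", "original-unet")


@dataclass
class ModelConfig:
    encoder_kind: str = "resnet50-like"
    encoder_stage_widths: tuple[int, ...] | None = None
    decoder_channels: tuple[int, ...] | None = None
    input_size: tuple[int, int] = (224, 224)
    num_classes: int = 3
    in_channels: int = 1
    pretrained_encoder: str | None = None

    def __post_init__(self) -> None:
        if self.encoder_kind not in ENCODER_KINDS:
            raise ValueError(f"unknown encoder_kind {self.encoder_kind!r}")

    @property
    def downsampling_factor(self) -> int:
        return {"resnet50-like": 32, "original-unet": 16, "small-resnet": 8}[
            self.encoder_kind
        ]

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self))

    @classmethod
    def from_yaml(cls, text: str) -> "ModelConfig":
        data = yaml.safe_load(text)
        for key in ("encoder_stage_widths", "decoder_channels", "input_size"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)


class _Encoder(Layer):
    """Stage list; each stage may be preceded by a pooling op. Returns the
    feature of every stage (highest resolution first; last is the bottom)."""

    def __init__(self, stages: list[Layer], pre_ops: list[Layer | None]):
        super().__init__()
        self.stages = stages
        self.pre_ops = pre_ops

    def sublayers(self):
        subs = [(f"stage{i}", s) for i, s in enumerate(self.stages)]
        subs += [(f"pool{i}", p) for i, p in enumerate(self.pre_ops) if p is not None]
        return subs

    def forward_features(self, x: np.ndarray, train: bool = True) -> list[np.ndarray]:
        feats = []
        for pre, stage in zip(self.pre_ops, self.stages):
            if pre is not None:
                x = pre.forward(x, train)
            x = stage.forward(x, train)
            feats.append(x)
        return feats

    def backward_features(self, dfeats: list[np.ndarray]) -> np.ndarray:
        g = dfeats[-1]
        for i in range(len(self.stages) - 1, -1, -1):
            g = self.stages[i].backward(g)
            if self.pre_ops[i] is not None:
                g = self.pre_ops[i].backward(g)
            if i > 0:
                g = g + dfeats[i - 1]
        return g


class _DecoderStage(Layer):
    def __init__(self, up: Layer, convs: Sequential, has_skip: bool):
        super().__init__()
        self.up = up
        self.convs = convs
        self.has_skip = has_skip
        self._skip_channels = 0

    def sublayers(self):
        return [("up", self.up), ("convs", self.convs)]

    def forward(self, x: np.ndarray, skip: np.ndarray | None, train: bool = True):
        x = self.up.forward(x, train)
        if self.has_skip:
            self._skip_channels = skip.shape[1]
            x = np.concatenate([skip, x], axis=1)
        return self.convs.forward(x, train)

    def backward(self, dy: np.ndarray):
        d = self.convs.backward(dy)
        if self.has_skip:
            dskip = d[:, : self._skip_channels]
            d = d[:, self._skip_channels:]
        else:
            dskip = None
        return self.up.backward(d), dskip


class Segmenter(Layer):
    """U-Net: encoder features -> decoder with skip concatenation -> 1x1 head."""

    def __init__(self, config: ModelConfig, encoder: _Encoder,
                 decoder_stages: list[_DecoderStage], head: Conv2d,
                 skip_indices: list[int | None]):
        super().__init__()
        self.config = config
        self.encoder = encoder
        self.decoder_stages = decoder_stages
        self.head = head
        # encoder-feature index consumed by each decoder stage (None = no skip)
        self.skip_indices = skip_indices

    def sublayers(self):
        return (
            [("encoder", self.encoder)]
            + [(f"decoder{i}", s) for i, s in enumerate(self.decoder_stages)]
            + [("head", self.head)]
        )

    def encoder_param_names(self) -> set[str]:
        return set(self.encoder.named_params("encoder."))

    # -- passes ------------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=nn.F32)
        self._check_size(x.shape[2:])
        feats = self.encoder.forward_features(x, train)
        out = feats[-1]
        for stage, idx in zip(self.decoder_stages, self.skip_indices):
            out = stage.forward(out, feats[idx] if idx is not None else None, train)
        return self.head.forward(out, train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.head.backward(dlogits)
        n_feats = len(self.encoder.stages)
        dfeats: list[np.ndarray | None] = [None] * n_feats
        for stage, idx in zip(reversed(self.decoder_stages), reversed(self.skip_indices)):
            d, dskip = stage.backward(d)
            if idx is not None:
                dfeats[idx] = dskip if dfeats[idx] is None else dfeats[idx] + dskip
        dfeats[-1] = d if dfeats[-1] is None else dfeats[-1] + d
        for i, g in enumerate(dfeats):
            if g is None:
                dfeats[i] = 0.0  # unreachable with current presets
        return self.encoder.backward_features(dfeats)

    def predict_probs(self, images: np.ndarray) -> np.ndarray:
        """Class probabilities for a batch (or single) of 2D images, eval mode."""
        x = np.asarray(images, dtype=nn.F32)
        single = x.ndim == 2
        if single:
            x = x[None]
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[1] != self.config.in_channels:
            x = np.repeat(x[:, :1], self.config.in_channels, axis=1)
        probs = softmax_channels(self.forward(x, train=False))
        return probs[0] if single else probs

    def predict_labels(self, images: np.ndarray) -> np.ndarray:
        probs = self.predict_probs(images)
        return np.argmax(probs, axis=-3).astype(np.uint8)

    # -- utilities ---------------------------------------------------------
    def _check_size(self, hw: tuple[int, int]) -> None:
        f = self.config.downsampling_factor
        if hw[0] % f or hw[1] % f:
            raise ValueError(
                f"input size {hw} not divisible by the downsampling factor {f}"
            )

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.named_params().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_params()
        missing = set(params) - set(state)
        if missing:
            raise ValueError(f"state dict missing tensors: {sorted(missing)[:5]} ...")
        for k, p in params.items():
            if state[k].shape != p.shape:
                raise ValueError(f"shape mismatch for {k}: {state[k].shape} vs {p.shape}")
            p[...] = state[k]

    def save(self, weights_path, config_path=None) -> None:
        np.savez_compressed(weights_path, **self.named_params())
        if config_path is not None:
            with open(config_path, "w") as fh:
                fh.write(self.config.to_yaml())

    def summary(self) -> str:
        lines = [f"{self.config.encoder_kind} segmenter"]
        for name, p in self.named_params().items():
            lines.append(f"  {name:60s} {str(p.shape):20s} {p.size:>10d}")
        lines.append(f"total parameters: {self.num_params():,}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# preset builders
# ---------------------------------------------------------------------------

def _resnet_stage(cin: int, cout: int, blocks: int, stride: int,
                  rng: np.random.Generator) -> Sequential:
    mid = cout // 4
    layers = [Bottleneck(cin, mid, cout, stride, rng)]
    layers += [Bottleneck(cout, mid, cout, 1, rng) for _ in range(blocks - 1)]
    return Sequential(*layers)


def _decoder_stage(cin: int, skip: int, cout: int, n_convs: int,
                   rng: np.random.Generator) -> _DecoderStage:
    convs = [conv_bn_relu(cin + skip, cout, rng)]
    convs += [conv_bn_relu(cout, cout, rng) for _ in range(n_convs - 1)]
    return _DecoderStage(BilinearUp2x(), Sequential(*convs), has_skip=skip > 0)


def _build_resnet50(config: ModelConfig, rng: np.random.Generator) -> Segmenter:
    widths = config.encoder_stage_widths or (256, 512, 1024, 2048)
    dec = config.decoder_channels or (256, 128, 64, 32, 16)
    stem = conv_bn_relu(config.in_channels, 64, rng, k=7, stride=2)
    stages = [
        stem,                                           # /2, 64
        _resnet_stage(64, widths[0], 3, 1, rng),        # /4 (after pool)
        _resnet_stage(widths[0], widths[1], 4, 2, rng),  # /8
        _resnet_stage(widths[1], widths[2], 6, 2, rng),  # /16
        _resnet_stage(widths[2], widths[3], 3, 2, rng),  # /32
    ]
    pre_ops = [None, MaxPool2x2(), None, None, None]
    encoder = _Encoder(stages, pre_ops)
    skip_feats = [64, widths[0], widths[1], widths[2]]
    conv_counts = (2, 2, 2, 1, 1)  # 8 decoder convolutions in total
    dec_stages, skip_idx = [], []
    cin = widths[3]
    for i, (cout, n_convs) in enumerate(zip(dec, conv_counts)):
        feat_i = 3 - i if i < 4 else None
        skip_c = skip_feats[feat_i] if feat_i is not None else 0
        dec_stages.append(_decoder_stage(cin, skip_c, cout, n_convs, rng))
        skip_idx.append(feat_i)
        cin = cout
    head = Conv2d(cin, config.num_classes, k=1, rng=rng)
    return Segmenter(config, encoder, dec_stages, head, skip_idx)


def _build_small_resnet(config: ModelConfig, rng: np.random.Generator) -> Segmenter:
    widths = config.encoder_stage_widths or (8, 16, 32, 64)
    stages = [
        conv_bn_relu(config.in_channels, widths[0], rng),        # /1
        BasicBlock(widths[0], widths[1], 2, rng),                # /2
        BasicBlock(widths[1], widths[2], 2, rng),                # /4
        BasicBlock(widths[2], widths[3], 2, rng),                # /8
    ]
    encoder = _Encoder(stages, [None] * 4)
    dec = config.decoder_channels or (widths[2], widths[1], widths[0])
    dec_stages, skip_idx = [], []
    cin = widths[3]
    for i, cout in enumerate(dec):
        feat_i = 2 - i
        dec_stages.append(_decoder_stage(cin, widths[feat_i], cout, 1, rng))
        skip_idx.append(feat_i)
        cin = cout
    head = Conv2d(cin, config.num_classes, k=1, rng=rng)
    return Segmenter(config, encoder, dec_stages, head, skip_idx)


def _double_conv(cin: int, cout: int, rng: np.random.Generator) -> Sequential:
    return Sequential(
        Conv2d(cin, cout, 3, rng=rng), ReLU(),
        Conv2d(cout, cout, 3, rng=rng), ReLU(),
    )


def _build_original_unet(config: ModelConfig, rng: np.random.Generator) -> Segmenter:
    widths = config.encoder_stage_widths or (64, 128, 256, 512, 1024)
    stages = [_double_conv(config.in_channels, widths[0], rng)]
    pre_ops: list[Layer | None] = [None]
    for cin, cout in zip(widths, widths[1:]):
        stages.append(_double_conv(cin, cout, rng))
        pre_ops.append(MaxPool2x2())
    encoder = _Encoder(stages, pre_ops)
    dec_stages, skip_idx = [], []
    cin = widths[-1]
    for i in range(len(widths) - 1):
        feat_i = len(widths) - 2 - i
        cout = widths[feat_i]
        dec_stages.append(
            _DecoderStage(ConvTranspose2x2(cin, cout, rng),
                          _double_conv(2 * cout, cout, rng), has_skip=True)
        )
        skip_idx.append(feat_i)
        cin = cout
    head = Conv2d(cin, config.num_classes, k=1, rng=rng)
    return Segmenter(config, encoder, dec_stages, head, skip_idx)


_BUILDERS = {
    "resnet50-like": _build_resnet50,
    "small-resnet": _build_small_resnet,
    "original-unet": _build_original_unet,
}


def build_model(config: ModelConfig | None = None, seed: int = 0) -> Segmenter:
    """Construct a seeded Segmenter for the configured preset.

    Raises at build time if the configured input size is not divisible by the
    preset's total downsampling factor.
    """
    config = config or ModelConfig()
    f = config.downsampling_factor
    if config.input_size[0] % f or config.input_size[1] % f:
        raise ValueError(
            f"input_size {config.input_size} must be divisible by the "
            f"downsampling factor {f} of {config.encoder_kind}"
        )
    rng = np.random.default_rng(seed)
    model = _BUILDERS[config.encoder_kind](config, rng)
    if config.pretrained_encoder:
        with np.load(config.pretrained_encoder) as data:
            load_pretrained_encoder(model, dict(data))
    return model


def load_pretrained_encoder(model: Segmenter, weight_source) -> Segmenter:
    """Replace encoder weights from a prior checkpoint; decoder untouched.

    ``weight_source`` is a mapping of parameter names to arrays (or an .npz
    path); names follow :meth:`Segmenter.named_params` (``encoder.`` prefix,
    with or without it). Every encoder tensor must be present with a matching
    shape, otherwise the offending tensors are listed and nothing is changed.
    """
    if isinstance(weight_source, (str, bytes)) or hasattr(weight_source, "__fspath__"):
        with np.load(weight_source) as data:
            weight_source = dict(data)
    source = {}
    for k, v in weight_source.items():
        name = k if k.startswith("encoder.") else f"encoder.{k}"
        source[name] = v
    enc_params = {
        k: v for k, v in model.named_params().items() if k.startswith("encoder.")
    }
    problems = []
    for name, p in enc_params.items():
        if name not in source:
            problems.append(f"missing {name}")
        elif source[name].shape != p.shape:
            problems.append(
                f"shape mismatch {name}: source {source[name].shape} vs model {p.shape}"
            )
    if problems:
        raise ValueError("pretrained encoder incompatible: " + "; ".join(problems[:10]))
    for name, p in enc_params.items():
        p[...] = source[name]
    return model
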
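"""Network factories: shared encoder E, target-domain decoder DT, source
classifier CS and domain discriminator D.

The encoder is a convolutional backbone followed by a single trainable
3x3 convolution head (1024 filters by default), batch normalization, ReLU
and global average pooling, producing a feature vector whose length equals
``head_filters``.  The decoder maps that vector through a dense seed layer
(8 x 8 x 128 by default) and a stack of transposed convolutions back to an
image; the classifier and discriminator are two-layer dense heads with
dropout.  All shape arithmetic is validated at build time: a layer plan that
cannot reach the configured image side fails construction with the full
shape chain in the message.

Pretrained ImageNet backbones (ResNet152, DenseNet121/201, Xception,
InceptionV3) are recognized tags, but their weights are not bundled; the
``scratch_small`` backbone is the runnable default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

PRETRAINED_BACKBONES = ("resnet152", "densenet121", "densenet201", "xception", "inceptionv3")
BACKBONES = ("scratch_small",) + PRETRAINED_BACKBONES

#: Channel widths of the three conv/pool blocks of the scratch backbone.
SCRATCH_CHANNELS = (8, 16, 32)


class ArchitectureError(ValueError):
    pass


class PretrainedWeightsUnavailable(ArchitectureError):
    pass


@dataclass(frozen=True)
class EncoderConfig:
    backbone: str = "scratch_small"
    backbone_frozen: bool | None = None  # None -> frozen iff pretrained
    head_filters: int = 1024
    head_kernel: tuple[int, int] = (3, 3)
    head_stride: tuple[int, int] = (1, 1)
    input_side: int = 64
    input_channels: int = 3

    @property
    def frozen(self) -> bool:
        if self.backbone_frozen is None:
            return self.backbone in PRETRAINED_BACKBONES
        return self.backbone_frozen

    def validate(self) -> None:
        if self.backbone not in BACKBONES:
            raise ArchitectureError(f"unknown backbone {self.backbone!r}; choose from {BACKBONES}")
        if self.head_filters < 1:
            raise ArchitectureError("head_filters must be >= 1")
        if self.head_kernel[0] % 2 == 0:
            raise ArchitectureError("head kernel must be odd")
        if self.input_side < 16 or self.input_side % 8:
            raise ArchitectureError(
                f"input_side must be a multiple of 8 and >= 16 (three pooling "
                f"stages), got {self.input_side}"
            )


#: The reference decoder layer plan (filters, kernel, stride, padding) that
#: upsamples an 8x8 seed to a 299x299x3 image:
#: 8 -> 17 -> 35 -> 37 -> 74 -> 149 -> 299 -> 299 -> 299.
REFERENCE_DECODER_PLAN = (
    (128, 3, 2, "valid"),
    (128, 3, 2, "valid"),
    (64, 3, 1, "valid"),
    (64, 3, 2, "same"),
    (64, 3, 2, "valid"),
    (32, 3, 2, "valid"),
    (32, 3, 1, "same"),
    (3, 3, 1, "same"),
)


@dataclass(frozen=True)
class DecoderConfig:
    input_features: int = 1024
    seed_shape: tuple[int, int, int] = (8, 8, 128)
    layer_plan: tuple[tuple[int, int, int, str], ...] = REFERENCE_DECODER_PLAN
    output_side: int = 299
    output_channels: int = 3

    def shape_chain(self) -> list[int]:
        """Spatial sides from the seed through every transposed convolution."""
        side = self.seed_shape[0]
        chain = [side]
        for _filters, kernel, stride, padding in self.layer_plan:
            side = nn.conv_transpose_output_side(side, kernel, stride, padding)
            chain.append(side)
        return chain

    def validate(self) -> None:
        if self.seed_shape[0] != self.seed_shape[1]:
            raise ArchitectureError("seed shape must be spatially square")
        chain = self.shape_chain()
        if chain[-1] != self.output_side:
            raise ArchitectureError(
                f"decoder layer plan reaches side {chain[-1]}, not the target "
                f"{self.output_side}; shape chain: {'->'.join(map(str, chain))}"
            )
        if self.layer_plan[-1][0] != self.output_channels:
            raise ArchitectureError(
                f"final layer has {self.layer_plan[-1][0]} filters, expected "
                f"{self.output_channels} output channels"
            )


def auto_decoder_plan(output_side: int, base_filters: int = 32,
                      seed_side: int = 8, output_channels: int = 3,
                      ) -> tuple[tuple[int, int, int, str], ...]:
    """Derive a reduced layer plan for ``output_side = seed_side * 2**k``.

    Stride-2 'same' transposed convolutions double the side while halving the
    filter count; a final stride-1 'same' layer maps to the output channels.
    The result always satisfies ``DecoderConfig.validate``.
    """
    side, plan, filters = seed_side, [], base_filters
    while side < output_side:
        plan.append((max(filters, 4), 3, 2, "same"))
        side *= 2
        filters //= 2
    if side != output_side:
        raise ArchitectureError(
            f"auto plan needs output_side = {seed_side} * 2**k, got {output_side}"
        )
    plan.append((output_channels, 3, 1, "same"))
    return tuple(plan)


@dataclass(frozen=True)
class HeadConfig:
    """Two-dense-layer head shared by classifier (softmax 2) and
    discriminator (sigmoid 1)."""

    input_features: int = 1024
    hidden_units: int = 512
    dropout_rate: float = 0.5
    output_units: int = 2

    def validate(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ArchitectureError("dropout_rate must be in [0, 1)")
        if self.output_units not in (1, 2):
            raise ArchitectureError("output_units must be 1 (discriminator) or 2 (classifier)")


def build_encoder(cfg: EncoderConfig, rng: np.random.Generator | None = None) -> nn.Sequential:
    """Backbone -> trainable conv head -> batch norm -> ReLU -> GAP."""
    cfg.validate()
    if cfg.backbone in PRETRAINED_BACKBONES:
        raise PretrainedWeightsUnavailable(
            f"backbone {cfg.backbone!r} requires pretrained ImageNet weights, "
            f"which are not bundled; use backbone='scratch_small'"
        )
    rng = rng or np.random.default_rng(0)
    layers: list[nn.Layer] = []
    c_in = cfg.input_channels
    backbone_layers: list[nn.Layer] = []
    for c_out in SCRATCH_CHANNELS:
        backbone_layers += [nn.Conv2D(c_in, c_out, 3, 1, "same", rng), nn.ReLU(), nn.MaxPool2()]
        c_in = c_out
    if cfg.frozen:
        for layer in backbone_layers:
            layer.trainable = False
    layers += backbone_layers
    layers += [
        nn.Conv2D(c_in, cfg.head_filters, cfg.head_kernel[0], cfg.head_stride[0], "same", rng),
        nn.BatchNorm(cfg.head_filters),
        nn.ReLU(),
        nn.GlobalAvgPool(),
    ]
    return nn.Sequential(layers)


def build_decoder(cfg: DecoderConfig, rng: np.random.Generator | None = None) -> nn.Sequential:
    """Dense seed -> reshape -> transposed convolutions (ReLU, final linear)."""
    cfg.validate()
    rng = rng or np.random.default_rng(0)
    h, w, c = cfg.seed_shape
    layers: list[nn.Layer] = [nn.Dense(cfg.input_features, h * w * c, rng), nn.Reshape((h, w, c))]
    c_in = c
    for i, (filters, kernel, stride, padding) in enumerate(cfg.layer_plan):
        layers.append(nn.ConvTranspose2D(c_in, filters, kernel, stride, padding, rng))
        if i < len(cfg.layer_plan) - 1:
            layers.append(nn.ReLU())
        c_in = filters
    return nn.Sequential(layers)


def _build_head(cfg: HeadConfig, final_activation: nn.Layer,
                rng: np.random.Generator) -> nn.Sequential:
    cfg.validate()
    return nn.Sequential([
        nn.Dropout(cfg.dropout_rate, rng),
        nn.Dense(cfg.input_features, cfg.hidden_units, rng),
        nn.ReLU(),
        nn.Dropout(cfg.dropout_rate, rng),
        nn.Dense(cfg.hidden_units, cfg.output_units, rng),
        final_activation,
    ])


def build_classifier(cfg: HeadConfig, rng: np.random.Generator | None = None) -> nn.Sequential:
    """Dropout -> Dense(hidden) -> ReLU -> Dropout -> Dense(2) -> Softmax."""
    if cfg.output_units != 2:
        raise ArchitectureError("classifier head needs output_units=2")
    return _build_head(cfg, nn.Softmax(), rng or np.random.default_rng(0))


def build_discriminator(cfg: HeadConfig, rng: np.random.Generator | None = None) -> nn.Sequential:
    """Dropout -> Dense(hidden) -> ReLU -> Dropout -> Dense(1) -> Sigmoid."""
    if cfg.output_units != 1:
        raise ArchitectureError("discriminator head needs output_units=1")
    return _build_head(cfg, nn.Sigmoid(), rng or np.random.default_rng(0))


@dataclass
class ModelBundle:
    """The component networks of one training mode, with disjoint parameters."""

    encoder: nn.Sequential
    classifier: nn.Sequential
    decoder: nn.Sequential | None = None
    discriminator: nn.Sequential | None = None
    encoder_cfg: EncoderConfig | None = None

    def components(self) -> dict[str, nn.Sequential]:
        out = {"encoder": self.encoder, "classifier": self.classifier}
        if self.decoder is not None:
            out["decoder"] = self.decoder
        if self.discriminator is not None:
            out["discriminator"] = self.discriminator
        return out

    def check_disjoint(self) -> None:
        seen: dict[int, str] = {}
        for name, comp in self.components().items():
            for layer in comp.iter_layers():
                for p in layer.params.values():
                    if id(p) in seen:
                        raise ArchitectureError(
                            f"parameter shared between {seen[id(p)]} and {name}"
                        )
                    seen[id(p)] = name

    def set_training(self, flag: bool) -> None:
        for comp in self.components().values():
            comp.set_training(flag)

    def n_params(self) -> int:
        return sum(comp.n_params() for comp in self.components().values())


def build_bundle(mode: str,
                 encoder_cfg: EncoderConfig,
                 decoder_cfg: DecoderConfig | None = None,
                 classifier_cfg: HeadConfig | None = None,
                 discriminator_cfg: HeadConfig | None = None,
                 seed: int = 0) -> ModelBundle:
    """Build all components a training mode needs, with independent
    seed-derived initialization streams per component (so adding the
    discriminator in 'rdrda' leaves the other components' weights unchanged).
    """
    if mode not in ("source_only", "drda", "rdrda"):
        raise ArchitectureError(f"unknown mode {mode!r}")
    encoder_cfg.validate()
    feat = encoder_cfg.head_filters
    ss = np.random.SeedSequence(seed)
    r_enc, r_cls, r_dec, r_dis = (np.random.default_rng(c) for c in ss.spawn(4))
    encoder = build_encoder(encoder_cfg, r_enc)
    classifier_cfg = classifier_cfg or HeadConfig(input_features=feat, output_units=2)
    classifier = build_classifier(classifier_cfg, r_cls)
    decoder = None
    if mode in ("drda", "rdrda"):
        if decoder_cfg is None:
            if encoder_cfg.input_side == 299:
                decoder_cfg = DecoderConfig(input_features=feat)
            else:
                decoder_cfg = DecoderConfig(
                    input_features=feat,
                    seed_shape=(8, 8, 64),
                    layer_plan=auto_decoder_plan(encoder_cfg.input_side),
                    output_side=encoder_cfg.input_side,
                )
        decoder = build_decoder(decoder_cfg, r_dec)
    discriminator = None
    if mode == "rdrda":
        discriminator_cfg = discriminator_cfg or HeadConfig(input_features=feat, output_units=1)
        discriminator = build_discriminator(discriminator_cfg, r_dis)
    bundle = ModelBundle(encoder=encoder, classifier=classifier, decoder=decoder,
                         discriminator=discriminator, encoder_cfg=encoder_cfg)
    bundle.check_disjoint()
    return bundle
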
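"""Network builders: the continuous damage-score regressor and binary heads.

The regression network (pest damage score, PDS) is a VGG-style convolutional
backbone followed by four two-conv residual blocks, global average pooling,
three fully connected layers with dropout, and a sigmoid output rescaled to
the 0-5 damage range. Binary classifiers share the engine and differ in the
head: two fully connected layers (4096 neurons at full scale) with dropout
0.5 and a plain sigmoid.

Full-scale presets reproduce the layer widths of the published recipe; the
named third-party backbones (alexnet ... densenet121) are architecture
presets at configurable scale inside this engine — VGG-style stacks, with
residual stages for the resnet-named ones — not the published topologies.
The ``tiny`` presets exist so the whole pipeline trains on a CPU in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pestgs.nn import (
    GAP,
    Conv2D,
    Dense,
    Dropout,
    MaxPool2D,
    ReLU,
    Residual,
    ScaledSigmoid,
    Sequential,
)

_VGG16_STAGES = [[64, 64], [128, 128], [256, 256, 256], [512, 512, 512], [512, 512, 512]]

#: Early-stopping patience per binary backbone: 20 at the shallow end
#: (alexnet) through 40 for the deepest (densenet121), interpolated between.
BINARY_PATIENCE = {
    "tiny": 20,
    "alexnet": 20,
    "vgg16": 24,
    "inceptionv3": 28,
    "resnet50": 32,
    "resnet101": 36,
    "densenet121": 40,
}

_BINARY_STAGES = {
    "tiny": [[8], [16]],
    "alexnet": [[48], [128], [192, 192, 128]],
    "vgg16": _VGG16_STAGES,
    "inceptionv3": [[32, 32], [64, 80], [192, 192], [288, 288]],
    "resnet50": [[64], [128], [256], [512]],
    "resnet101": [[64], [128], [256], [512]],
    "densenet121": [[64], [128], [256], [512]],
}
_RESIDUAL_BACKBONES = {"resnet50", "resnet101"}


def _stages(channels) -> list[list[int]]:
    """Accept a flat list (one conv per stage) or explicit per-stage lists."""
    if not channels:
        raise ValueError("backbone_channels must be non-empty")
    if isinstance(channels[0], (list, tuple)):
        return [list(s) for s in channels]
    return [[int(c)] for c in channels]


@dataclass
class PdsNetConfig:
    """Configuration of the continuous damage-score network."""

    input_size: int = 224
    backbone_channels: list = field(default_factory=lambda: [s[:] for s in _VGG16_STAGES])
    residual_block_filters: list[int] = field(default_factory=lambda: [512, 256, 128, 64])
    conv_per_block: int = 2
    fc_width: int = 1024
    fc_count: int = 3
    dropout_fc: float = 0.3
    output_scale: float = 5.0
    freeze_backbone: bool = False

    def __post_init__(self) -> None:
        if len(self.residual_block_filters) != 4:
            raise ValueError("exactly four residual blocks are required")
        if self.conv_per_block != 2:
            raise ValueError("residual blocks contain exactly two conv layers")
        if self.fc_count != 3:
            raise ValueError("the head has exactly three fully connected layers")
        stages = _stages(self.backbone_channels)
        if self.input_size % (2 ** len(stages)) != 0:
            raise ValueError("input_size must be divisible by 2^n_stages")

    @classmethod
    def tiny(cls) -> "PdsNetConfig":
        """Desk-scale preset: trains on a CPU in minutes on 64 x 64 leaves."""
        return cls(
            input_size=64,
            backbone_channels=[16, 32],
            residual_block_filters=[32, 16, 8, 8],
            fc_width=64,
        )


@dataclass
class BinaryNetConfig:
    """Configuration of one binary (mild/severe) classification network."""

    backbone_name: str = "vgg16"
    input_size: int = 224
    fc_width: int = 4096
    fc_count: int = 2
    dropout_fc: float = 0.5
    patience: int | None = None

    def __post_init__(self) -> None:
        if self.backbone_name not in _BINARY_STAGES:
            raise ValueError(
                f"unknown backbone {self.backbone_name!r}; "
                f"choose from {sorted(_BINARY_STAGES)}"
            )
        if self.patience is None:
            self.patience = BINARY_PATIENCE[self.backbone_name]
        stages = _BINARY_STAGES[self.backbone_name]
        if self.input_size % (2 ** len(stages)) != 0:
            raise ValueError("input_size must be divisible by 2^n_stages")

    @classmethod
    def tiny(cls) -> "BinaryNetConfig":
        return cls(backbone_name="tiny", input_size=64, fc_width=64)


def _conv_backbone(stages: list[list[int]], residual: bool, rng) -> tuple[list, int]:
    layers: list = []
    in_ch = 3
    for stage in stages:
        for width in stage:
            if residual and in_ch != 3:
                layers.append(Residual(in_ch, width, rng))
            else:
                layers.extend([Conv2D(in_ch, width, 3, rng), ReLU()])
            in_ch = width
        layers.append(MaxPool2D())
    return layers, in_ch


def build_pds_network(cfg: PdsNetConfig, seed: int = 0) -> Sequential:
    """Build the damage-score regressor; forward output lies in [0, output_scale]."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 551]))
    stages = _stages(cfg.backbone_channels)
    layers, in_ch = _conv_backbone(stages, residual=False, rng=rng)
    if cfg.freeze_backbone:
        for layer in layers:
            layer.frozen = True
    for width in cfg.residual_block_filters:
        layers.append(Residual(in_ch, width, rng))
        in_ch = width
    layers.append(GAP())
    feat = in_ch
    for _ in range(cfg.fc_count):
        layers.extend([Dense(feat, cfg.fc_width, rng), ReLU(), Dropout(cfg.dropout_fc)])
        feat = cfg.fc_width
    layers.extend([Dense(feat, 1, rng), ScaledSigmoid(cfg.output_scale)])
    return Sequential(layers)


def build_binary_network(cfg: BinaryNetConfig, seed: int = 0) -> Sequential:
    """Build one binary classifier; forward output is a probability in (0, 1)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 661]))
    stages = _BINARY_STAGES[cfg.backbone_name]
    layers, in_ch = _conv_backbone(
        stages, residual=cfg.backbone_name in _RESIDUAL_BACKBONES, rng=rng
    )
    layers.append(GAP())
    feat = in_ch
    for _ in range(cfg.fc_count):
        layers.extend([Dense(feat, cfg.fc_width, rng), ReLU(), Dropout(cfg.dropout_fc)])
        feat = cfg.fc_width
    layers.extend([Dense(feat, 1, rng), ScaledSigmoid(1.0)])
    return Sequential(layers)
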
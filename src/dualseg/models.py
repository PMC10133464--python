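"""Network families: a configurable U-Net segmentor and a 5-layer
stride-2 fully convolutional discriminator, with Xavier/Kaiming builders
so the two students start genuinely different.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import BatchNorm, ConvNd, Dropout, MaxPoolNd, Module, Tensor, UpsampleNd
from .nn.init import SCHEMES, initialize
from .types import SoftPrediction


@dataclass
class SegNetConfig:
    spatial_rank: int = 2
    in_channels: int = 2
    num_classes: int = 4
    depth: int = 4            # encoder levels (= number of 2x poolings)
    base_width: int = 16
    dropout: float = 0.1
    batchnorm: bool = True

    def __post_init__(self):
        if self.spatial_rank not in (2, 3):
            raise ValueError("spatial_rank must be 2 or 3")
        if self.in_channels < 1 or self.num_classes < 2 or self.depth < 1:
            raise ValueError("invalid segmentor config")


@dataclass
class DiscConfig:
    in_channels: int = 4      # = num_classes of the segmentor
    spatial_rank: int = 2
    base_width: int = 16
    layers: int = 5
    kernel: int = 4
    stride: int = 2
    leaky_slope: float = 0.2
    dropout: float = 0.5
    input_kind: str = "probs"  # "probs" | "logits"

    def __post_init__(self):
        if self.input_kind not in ("probs", "logits"):
            raise ValueError("input_kind must be 'probs' or 'logits'")


class ConvBlock(Module):
    """(conv3 -> [BN] -> ReLU -> dropout) x 2, same spatial shape."""

    def __init__(self, rank: int, in_ch: int, out_ch: int, dropout: float,
                 batchnorm: bool):
        super().__init__()
        self.conv1 = ConvNd(rank, in_ch, out_ch, kernel=3, pad=1)
        self.bn1 = BatchNorm(out_ch) if batchnorm else None
        self.drop1 = Dropout(dropout)
        self.conv2 = ConvNd(rank, out_ch, out_ch, kernel=3, pad=1)
        self.bn2 = BatchNorm(out_ch) if batchnorm else None

    def forward(self, x: Tensor) -> Tensor:
        x = self.conv1(x)
        if self.bn1 is not None:
            x = self.bn1(x)
        x = nn.relu(x)
        x = self.drop1(x)
        x = self.conv2(x)
        if self.bn2 is not None:
            x = self.bn2(x)
        return nn.relu(x)


class UNet(Module):
    """Encoder-decoder segmentor with skip connections.

    Input [N, C, *spatial] -> :class:`SoftPrediction` over M classes with
    the input's spatial shape.  Spatial dims must be divisible by 2^depth.
    """

    def __init__(self, config: SegNetConfig):
        super().__init__()
        self.config = config
        r, w, d = config.spatial_rank, config.base_width, config.depth
        widths = [w * 2 ** i for i in range(d + 1)]
        self.encoders = [
            ConvBlock(r, config.in_channels if i == 0 else widths[i - 1],
                      widths[i], config.dropout, config.batchnorm)
            for i in range(d)
        ]
        self.pool = MaxPoolNd(r)
        self.bottleneck = ConvBlock(r, widths[d - 1], widths[d],
                                    config.dropout, config.batchnorm)
        self.up = UpsampleNd(r)
        self.upconvs = [ConvNd(r, widths[i + 1], widths[i], kernel=3, pad=1)
                        for i in reversed(range(d))]
        self.decoders = [
            ConvBlock(r, 2 * widths[i], widths[i], config.dropout,
                      config.batchnorm)
            for i in reversed(range(d))
        ]
        self.head = ConvNd(r, widths[0], config.num_classes, kernel=1)

    def _check_input(self, x):
        shape = x.shape[2:]
        div = 2 ** self.config.depth
        if len(shape) != self.config.spatial_rank:
            raise ValueError(f"expected rank-{self.config.spatial_rank} input, "
                             f"got spatial shape {shape}")
        if any(s % div for s in shape):
            raise ValueError(f"spatial dims {shape} not divisible by 2^depth={div}")

    def forward(self, x) -> SoftPrediction:
        x = nn.astensor(x)
        self._check_input(x)
        skips = []
        for enc in self.encoders:
            x = enc(x)
            skips.append(x)
            x = self.pool(x)
        x = self.bottleneck(x)
        for upconv, dec, skip in zip(self.upconvs, self.decoders,
                                     reversed(skips)):
            x = upconv(self.up(x))
            x = dec(nn.concat([skip, x], axis=1))
        logits = self.head(x)
        return SoftPrediction.from_logits(logits)


class Discriminator(Module):
    """Five stride-2 convs (kernel 4, pad 1); leaky-ReLU(0.2) + dropout(0.5)
    after all but the last; emits a 1-channel domain-score logit map."""

    def __init__(self, config: DiscConfig):
        super().__init__()
        self.config = config
        r, w = config.spatial_rank, config.base_width
        chans = [config.in_channels] + [w * 2 ** i for i in range(config.layers - 1)] + [1]
        self.convs = [ConvNd(r, chans[i], chans[i + 1], kernel=config.kernel,
                             stride=config.stride, pad=1)
                      for i in range(config.layers)]
        self.drops = [Dropout(config.dropout) for _ in range(config.layers - 1)]

    def forward(self, x) -> Tensor:
        x = nn.astensor(x)
        for i, conv in enumerate(self.convs):
            x = conv(x)
            if i < len(self.convs) - 1:
                x = nn.leaky_relu(x, self.config.leaky_slope)
                x = self.drops[i](x)
        return x


def build_segmentor(config: SegNetConfig, init_scheme: str = "xavier",
                    seed: int = 0) -> UNet:
    """Deterministically built and initialized U-Net."""
    if init_scheme not in SCHEMES:
        raise ValueError(f"unknown init scheme {init_scheme!r}")
    net = UNet(config)
    initialize(net, init_scheme, np.random.default_rng(seed))
    return net


def build_discriminator(config: DiscConfig, seed: int = 0) -> Discriminator:
    net = Discriminator(config)
    initialize(net, "kaiming", np.random.default_rng(seed))
    return net


def disc_output_extent(input_extent: int, config: DiscConfig) -> int:
    """Spatial extent after the stride-2 conv stack (conv arithmetic)."""
    e = input_extent
    for _ in range(config.layers):
        e = (e + 2 * 1 - config.kernel) // config.stride + 1
        if e < 1:
            raise ValueError(f"input extent {input_extent} too small for "
                             f"{config.layers} stride-{config.stride} layers")
    return e
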
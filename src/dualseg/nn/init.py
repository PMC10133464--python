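"""Weight-initialization schemes (Xavier uniform / Kaiming normal)."""
from __future__ import annotations

from math import prod, sqrt

import numpy as np

from .layers import BatchNorm, ConvNd, Dropout, Module

SCHEMES = ("xavier", "kaiming")


def _fans(weight_shape: tuple) -> tuple[int, int]:
    out_ch, in_ch = weight_shape[:2]
    receptive = prod(weight_shape[2:]) if len(weight_shape) > 2 else 1
    return in_ch * receptive, out_ch * receptive


def initialize(net: Module, scheme: str, rng: np.random.Generator) -> Module:
    """Initialize all conv weights in ``net`` in-place; returns ``net``.

    Also attaches ``rng`` to every dropout layer so stochastic forward
    passes are reproducible per-network.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown init scheme {scheme!r}; choose from {SCHEMES}")
    for m in net.modules():
        if isinstance(m, ConvNd):
            fan_in, fan_out = _fans(m.weight.data.shape)
            if scheme == "xavier":
                limit = sqrt(6.0 / (fan_in + fan_out))
                m.weight.data = rng.uniform(-limit, limit, m.weight.data.shape)
            else:
                std = sqrt(2.0 / fan_in)
                m.weight.data = rng.normal(0.0, std, m.weight.data.shape)
            if m.bias is not None:
                m.bias.data = np.zeros_like(m.bias.data)
        elif isinstance(m, BatchNorm):
            m.gamma.data = np.ones_like(m.gamma.data)
            m.beta.data = np.zeros_like(m.beta.data)
        elif isinstance(m, Dropout):
            m.rng = rng
    return net
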
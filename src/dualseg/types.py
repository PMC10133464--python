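"""Shared domain types: soft predictions, reliability bundles, loss bundles."""
from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .nn import Tensor, astensor, softmax

_PROB_EPS = 1e-7  # probabilities clipped to [eps, 1-eps] before any log


@dataclass
class SoftPrediction:
    """Per-voxel class probabilities plus the pre-normalization logits.

    ``logits``/``probs`` have shape [M, *spatial] or [N, M, *spatial]; the
    class axis is the one before the spatial axes.  Both are autodiff
    tensors so losses can back-propagate; wrap plain arrays freely.
    """

    logits: Tensor
    probs: Tensor

    def __post_init__(self):
        self.logits = astensor(self.logits)
        self.probs = astensor(self.probs)
        if self.logits.shape != self.probs.shape:
            raise ValueError("logits/probs shape mismatch")
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes (background + foreground)")

    @property
    def class_axis(self) -> int:
        # [M, *spatial] -> 0;  [N, M, *spatial] -> 1. Spatial rank is >= 2.
        return 0 if self.logits.ndim <= 3 else 1

    @property
    def num_classes(self) -> int:
        return self.logits.shape[self.class_axis]

    @classmethod
    def from_logits(cls, logits) -> "SoftPrediction":
        logits = astensor(logits)
        axis = 0 if logits.ndim <= 3 else 1
        return cls(logits=logits, probs=softmax(logits, axis=axis))

    @classmethod
    def from_probs(cls, probs) -> "SoftPrediction":
        probs = astensor(probs)
        p = np.clip(probs.data, _PROB_EPS, 1.0 - _PROB_EPS)
        return cls(logits=Tensor(np.log(p)), probs=probs)

    def detach(self) -> "SoftPrediction":
        return SoftPrediction(self.logits.detach(), self.probs.detach())


@dataclass
class ReliabilityBundle:
    """Per-voxel label/confidence/reliability state for one target sample."""

    labels: np.ndarray          # argmax class map, clean input
    labels_noisy: np.ndarray    # argmax class map, perturbed input
    maxprob: np.ndarray         # per-voxel max probability, clean
    maxprob_noisy: np.ndarray
    reliable: np.ndarray        # per-voxel boolean reliability bits
    epsilon: float              # sample-level stability distance (L2)
    sample_reliable: bool = False  # quorum-reduced sample-level bit


@dataclass
class LossBundle:
    """Named scalar loss components for one student on one step."""

    l_seg: float = 0.0
    l_con: float = 0.0
    l_cross: float = 0.0
    l_adv: float = 0.0
    l_disc: float | None = None
    total: float = 0.0

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}
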
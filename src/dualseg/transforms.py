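"""Replayable stochastic perturbations for consistency training.

A sampled :class:`TransformSpec` splits into a *spatial* part (exact lattice
symmetries: 90-degree rotations and axis flips, replayable identically on
images, label maps and soft predictions) and an *intensity* part (contrast
gain and additive Gaussian noise, images only).  Spatial ops are bit-exact
and invertible; the noise draw carries its own recorded sub-seed so image
replay is bit-exact too.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor
from .types import SoftPrediction


@dataclass(frozen=True)
class SpatialOp:
    """One exact lattice symmetry.

    ``op`` is ``"rot90"`` (params: k, plane=(ax1, ax2)) or ``"flip"``
    (params: axis).  Axis indices refer to *spatial* axes (0-based, i.e.
    ignoring any leading batch/channel axes).
    """

    op: str
    k: int = 0
    plane: tuple[int, int] = (0, 1)
    axis: int = 0

    def inverse(self) -> "SpatialOp":
        if self.op == "rot90":
            return SpatialOp("rot90", k=(-self.k) % 4, plane=self.plane)
        return self  # flip is its own inverse


@dataclass(frozen=True)
class IntensityOp:
    """``"contrast_scale"`` (gain > 0) or ``"gaussian_noise"`` (sigma, seed)."""

    op: str
    gain: float = 1.0
    sigma: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class TransformSpec:
    spatial_ops: tuple[SpatialOp, ...] = ()
    intensity_ops: tuple[IntensityOp, ...] = ()


@dataclass
class TransformConfig:
    """Enabled ops and parameter ranges for :func:`sample_transform`."""

    rot90: bool = True
    rot90_ks: tuple[int, ...] = (0, 1, 2, 3)
    rot90_plane: tuple[int, int] = (0, 1)
    flip: bool = True
    flip_axes: tuple[int, ...] = (0, 1)
    contrast: bool = True
    gamma_range: tuple[float, float] = (0.8, 1.2)
    noise: bool = True
    sigma_range: tuple[float, float] = (0.0, 0.1)

    def enabled(self) -> list[str]:
        return [name for name in ("rot90", "flip", "contrast", "noise")
                if getattr(self, name)]


def sample_transform(rng: np.random.Generator,
                     config: TransformConfig) -> TransformSpec:
    """Draw one fully deterministic, replayable perturbation spec."""
    if not config.enabled():
        raise ValueError("no transforms enabled")
    spatial: list[SpatialOp] = []
    intensity: list[IntensityOp] = []
    if config.rot90:
        k = int(rng.choice(config.rot90_ks))
        spatial.append(SpatialOp("rot90", k=k, plane=tuple(config.rot90_plane)))
    if config.flip:
        for axis in config.flip_axes:
            if rng.random() < 0.5:
                spatial.append(SpatialOp("flip", axis=int(axis)))
    if config.contrast:
        gamma = float(rng.uniform(*config.gamma_range))
        if gamma <= 0:
            raise ValueError("contrast gain must be positive")
        intensity.append(IntensityOp("contrast_scale", gain=gamma))
    if config.noise:
        sigma = float(rng.uniform(*config.sigma_range))
        seed = int(rng.integers(0, 2 ** 31 - 1))
        intensity.append(IntensityOp("gaussian_noise", sigma=sigma, seed=seed))
    return TransformSpec(tuple(spatial), tuple(intensity))


def _spatial_axis(array_ndim: int, spatial_rank: int, spatial_axis: int) -> int:
    # spatial axes are the trailing ``spatial_rank`` axes of the array
    if not 0 <= spatial_axis < spatial_rank:
        raise ValueError(f"spatial axis {spatial_axis} out of range for "
                         f"rank {spatial_rank}")
    return array_ndim - spatial_rank + spatial_axis


def _apply_spatial_array(x, ops: tuple[SpatialOp, ...], spatial_rank: int):
    """Apply spatial ops to an ndarray or autodiff Tensor (trailing spatial axes)."""
    is_tensor = isinstance(x, Tensor)
    ndim = x.ndim
    for op in ops:
        if op.op == "rot90":
            a1 = _spatial_axis(ndim, spatial_rank, op.plane[0])
            a2 = _spatial_axis(ndim, spatial_rank, op.plane[1])
            if op.k % 2 == 1 and x.shape[a1] != x.shape[a2]:
                raise ValueError(
                    f"rot90 with odd k needs a square plane, got "
                    f"{x.shape[a1]}x{x.shape[a2]}")
            x = x.rot90(op.k, (a1, a2)) if is_tensor \
                else np.rot90(x, k=op.k, axes=(a1, a2))
        elif op.op == "flip":
            ax = _spatial_axis(ndim, spatial_rank, op.axis)
            x = x.flip(ax) if is_tensor else np.flip(x, axis=ax)
        else:
            raise ValueError(f"unknown spatial op {op.op!r}")
    return x


def _apply_intensity_array(x: np.ndarray,
                           ops: tuple[IntensityOp, ...]) -> np.ndarray:
    for op in ops:
        if op.op == "contrast_scale":
            x = x * op.gain
        elif op.op == "gaussian_noise":
            if op.sigma > 0:
                noise_rng = np.random.default_rng(op.seed)
                x = x + noise_rng.normal(0.0, op.sigma, x.shape)
        else:
            raise ValueError(f"unknown intensity op {op.op!r}")
    return x


def apply_to_image(image: np.ndarray, spec: TransformSpec, spatial_rank: int,
                   label: np.ndarray | None = None):
    """Transform an image [..., C, *spatial]: spatial ops first, then intensity.

    Label maps, when passed, receive the spatial ops only.  Returns the
    image, or an (image, label) pair when a label is given.
    """
    image = np.asarray(image)
    out = _apply_spatial_array(image, spec.spatial_ops, spatial_rank)
    out = _apply_intensity_array(np.ascontiguousarray(out), spec.intensity_ops)
    if label is None:
        return out
    lab = _apply_spatial_array(np.asarray(label), spec.spatial_ops, spatial_rank)
    return out, np.ascontiguousarray(lab)


def apply_spatial_to_prediction(pred: SoftPrediction, spec: TransformSpec,
                                spatial_rank: int) -> SoftPrediction:
    """Replay ONLY the spatial part of ``spec`` onto a soft prediction.

    Probability vectors are moved, never altered, so per-voxel sums are
    conserved exactly.  Intensity ops are undefined on probability maps.
    """
    logits = _apply_spatial_array(pred.logits, spec.spatial_ops, spatial_rank)
    probs = _apply_spatial_array(pred.probs, spec.spatial_ops, spatial_rank)
    return SoftPrediction(logits=logits, probs=probs)


def invert_spatial(spec: TransformSpec) -> TransformSpec:
    """Spec whose spatial part undoes ``spec``'s (intensity part dropped)."""
    inv = tuple(op.inverse() for op in reversed(spec.spatial_ops))
    return TransformSpec(spatial_ops=inv, intensity_ops=())
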
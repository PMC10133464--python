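"""Synthetic nested-lesion phantom generator.

Produces paired source/target 2D or 3D segmentation domains with the
statistical structure of multi-channel tumor data: a small number of
nested foreground classes (whole > core > enhancing analogue), severe
class imbalance, and a controllable source-to-target domain shift
(per-channel intensity remap, lesion-morphology scaling, optional
contrast inversion of one class).  Everything is reproducible from
(spec, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DOMAINS = ("source", "target")


@dataclass
class DomainShift:
    """How the target domain differs from the source (labels shared)."""

    intensity_affine: tuple[tuple[float, float], ...] = ((1.0, 0.0), (1.0, 0.0))
    morphology_scale: float = 1.0     # multiplier on lesion radii
    contrast_inversion: bool = False  # invert one foreground class's intensity
    inverted_class: int = 2


@dataclass
class PhantomSpec:
    spatial_rank: int = 2
    size: int = 32
    channels: int = 2
    classes: int = 4                       # background + 3 nested rings
    lesion_count_range: tuple[int, int] = (1, 2)
    # worst case 2 * pi * (5 * 1.25)^2 voxels < 0.25 * 32^2 keeps imbalance
    radius_range: tuple[float, float] = (3.5, 5.0)
    nesting_ratios: tuple[float, float] = (0.65, 0.4)  # core/whole, enh/whole
    # class_means[c][ch]: mean intensity of class c on channel ch
    class_means: tuple[tuple[float, ...], ...] = (
        (0.1, 0.1), (0.55, 0.35), (0.75, 0.6), (0.95, 0.85))
    noise_sigma: float = 0.06
    shift: DomainShift = field(default_factory=DomainShift)
    seed: int = 0

    def __post_init__(self):
        if self.spatial_rank not in (2, 3):
            raise ValueError("spatial_rank must be 2 or 3")
        if self.classes < 2:
            raise ValueError("need at least 2 classes")
        if len(self.class_means) != self.classes:
            raise ValueError("class_means must have one row per class")
        if any(len(row) != self.channels for row in self.class_means):
            raise ValueError("class_means rows must match channel count")
        max_r = self.radius_range[1] * max(1.0, self.shift.morphology_scale)
        if max_r >= self.size / 2:
            raise ValueError(f"lesion radius {max_r} too large for image "
                             f"size {self.size}")


class LabelAccessError(RuntimeError):
    """Raised when adaptation code touches a hidden target label."""


@dataclass
class Sample:
    image: np.ndarray               # [C, *spatial]
    _label: np.ndarray | None
    domain: str = "source"
    hidden: bool = False

    @property
    def label(self) -> np.ndarray:
        if self.hidden:
            raise LabelAccessError(
                "target-domain training labels are hidden from adaptation; "
                "use reveal() only where supervision on the target is allowed")
        return self._label

    def reveal(self) -> np.ndarray:
        """Explicit unhiding (evaluation / super_all on synthetic data only)."""
        return self._label


@dataclass
class DatasetBundle:
    source_train: list[Sample]
    target_train: list[Sample]      # labels hidden
    target_val: list[Sample]
    target_test: list[Sample]
    source_test: list[Sample]
    spec: PhantomSpec
    seed: int


def _ellipsoid_mask(shape: tuple[int, ...], center: np.ndarray,
                    radii: np.ndarray) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return q <= 1.0


def generate_sample(spec: PhantomSpec, domain: str,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One (image [C, *spatial], labelmap [*spatial]) pair.

    The label-generation process is shared across domains; the domain-shift
    block is applied iff ``domain == "target"``.  The random stream is
    consumed identically for both domains, so a null shift yields
    bit-identical samples from the same generator state.
    """
    if domain not in DOMAINS:
        raise ValueError(f"domain must be one of {DOMAINS}")
    shape = (spec.size,) * spec.spatial_rank
    is_target = domain == "target"
    morph = spec.shift.morphology_scale if is_target else 1.0

    labels = np.zeros(shape, dtype=np.int64)
    n_lesions = int(rng.integers(spec.lesion_count_range[0],
                                 spec.lesion_count_range[1] + 1))
    for _ in range(n_lesions):
        radius = float(rng.uniform(*spec.radius_range))
        # anisotropy per axis, then domain morphology scaling
        radii = radius * rng.uniform(0.75, 1.25, size=spec.spatial_rank) * morph
        lo, hi = spec.size * 0.25, spec.size * 0.75
        center = rng.uniform(lo, hi, size=spec.spatial_rank)
        whole = _ellipsoid_mask(shape, center, radii)
        labels[whole] = np.maximum(labels[whole], 1)
        if spec.classes > 2:
            core = _ellipsoid_mask(shape, center,
                                   radii * spec.nesting_ratios[0])
            labels[core] = np.maximum(labels[core], 2)
        if spec.classes > 3:
            enh = _ellipsoid_mask(shape, center,
                                  radii * spec.nesting_ratios[1])
            labels[enh] = np.maximum(labels[enh], 3)

    means = np.array(spec.class_means)  # [classes, channels]
    if is_target and spec.shift.contrast_inversion:
        c = spec.shift.inverted_class
        means = means.copy()
        # mirror the class's intensity through the background level
        means[c] = 2.0 * means[0] - means[c]
    image = means.T[:, labels]  # [C, *spatial]
    image = image + rng.normal(0.0, spec.noise_sigma, image.shape)
    if is_target:
        for ch, (a, b) in enumerate(spec.shift.intensity_affine):
            image[ch] = a * image[ch] + b
    return image, labels


def _make_samples(spec: PhantomSpec, domain: str, n: int,
                  rng: np.random.Generator, hidden: bool) -> list[Sample]:
    out = []
    for _ in range(n):
        image, labels = generate_sample(spec, domain, rng)
        out.append(Sample(image=image, _label=labels, domain=domain,
                          hidden=hidden))
    return out


def generate_dataset(spec: PhantomSpec, n_source: int, n_target: int,
                     n_val: int, n_test: int,
                     rng: np.random.Generator | None = None,
                     n_source_test: int = 0) -> DatasetBundle:
    """Labeled source train, unlabeled (hidden-label) target train, and
    held-out target val/test splits with exact sizes."""
    for name, n in [("n_source", n_source), ("n_target", n_target),
                    ("n_val", n_val), ("n_test", n_test)]:
        if n <= 0:
            raise ValueError(f"{name} must be positive, got {n}")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    return DatasetBundle(
        source_train=_make_samples(spec, "source", n_source, rng, hidden=False),
        target_train=_make_samples(spec, "target", n_target, rng, hidden=True),
        target_val=_make_samples(spec, "target", n_val, rng, hidden=False),
        target_test=_make_samples(spec, "target", n_test, rng, hidden=False),
        source_test=_make_samples(spec, "source", max(n_source_test, n_test),
                                  rng, hidden=False),
        spec=spec, seed=int(rng.integers(0, 2 ** 31 - 1)),
    )


def preset_task(name: str) -> PhantomSpec:
    """Stylized analogues of the cross-grade and cross-modality shifts.

    ``cross_grade``: target lesions smaller (morphology scale 0.6) with a
    mild intensity shift.  ``cross_modality``: strong per-channel intensity
    remap plus contrast inversion of one foreground class; morphology
    unchanged (labels marginally identical across domains).
    """
    if name == "cross_grade":
        return PhantomSpec(shift=DomainShift(
            intensity_affine=((1.0, 0.08), (1.0, -0.08)),
            morphology_scale=0.6,
            contrast_inversion=False))
    if name == "cross_modality":
        return PhantomSpec(shift=DomainShift(
            intensity_affine=((0.55, 0.3), (1.5, -0.12)),
            morphology_scale=1.0,
            contrast_inversion=True,
            inverted_class=2))
    raise ValueError(f"unknown preset {name!r}; "
                     "choose 'cross_grade' or 'cross_modality'")


def onehot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    """[*] int labels -> [M, *] one-hot float array."""
    out = np.zeros((num_classes,) + labels.shape)
    for c in range(num_classes):
        out[c] = labels == c
    return out
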
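"""Segmentation metrics: per-class dice similarity and Hausdorff distance
over the nested class convention (whole > core > enhancing analogue),
aggregated into result tables.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion, generate_binary_structure
from scipy.spatial import cKDTree

NESTED_CLASSES = ("whole", "core", "enhancing")
EMPTY_HD_SENTINEL = 373.13  # returned when a mask is empty; configurable


def dice_score(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """2|A.B| / (|A|+|B|); both masks empty counts as a perfect 1.0."""
    pred_mask = np.asarray(pred_mask)
    true_mask = np.asarray(true_mask)
    if pred_mask.shape != true_mask.shape:
        raise ValueError("mask shapes differ")
    for m in (pred_mask, true_mask):
        if m.dtype != bool and not np.all((m == 0) | (m == 1)):
            raise ValueError("masks must be binary")
    a = pred_mask.astype(bool)
    b = true_mask.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """Coordinates of foreground voxels with >= 1 background face-neighbor.

    Voxels on the image border count as boundary (outside is background).
    """
    mask = np.asarray(mask).astype(bool)
    struct = generate_binary_structure(mask.ndim, 1)  # face connectivity
    interior = binary_erosion(mask, structure=struct, border_value=0)
    return np.argwhere(mask & ~interior)


def hausdorff_distance(mask_a: np.ndarray, mask_b: np.ndarray,
                       variant: str = "max",
                       spacing: tuple[float, ...] | None = None,
                       empty_sentinel: float = EMPTY_HD_SENTINEL) -> float:
    """Boundary distance between two binary masks.

    ``max``: classical symmetric directed-max Hausdorff distance.
    ``avg``: mean of all minimum boundary distances (both directions
    pooled).  ``spacing`` scales voxel coordinates to physical units.
    An empty mask yields ``empty_sentinel`` with a warning.
    """
    if variant not in ("max", "avg"):
        raise ValueError("variant must be 'max' or 'avg'")
    pa = boundary_points(mask_a).astype(float)
    pb = boundary_points(mask_b).astype(float)
    if len(pa) == 0 or len(pb) == 0:
        if len(pa) == 0 and len(pb) == 0:
            return 0.0
        warnings.warn("empty mask in Hausdorff distance; returning sentinel",
                      stacklevel=2)
        return float(empty_sentinel)
    if spacing is not None:
        sp = np.asarray(spacing, dtype=float)
        pa = pa * sp
        pb = pb * sp
    d_ab = cKDTree(pb).query(pa)[0]  # min dist from each a-point to b
    d_ba = cKDTree(pa).query(pb)[0]
    if variant == "max":
        return float(max(d_ab.max(), d_ba.max()))
    return float((d_ab.sum() + d_ba.sum()) / (len(d_ab) + len(d_ba)))


def nested_masks(labels: np.ndarray) -> dict[str, np.ndarray]:
    """Raw integer labels -> nested evaluation masks.

    whole = all foreground labels, core = labels >= 2, enhancing = label 3.
    """
    labels = np.asarray(labels)
    return {
        "whole": labels >= 1,
        "core": labels >= 2,
        "enhancing": labels == 3,
    }


@dataclass
class MetricReport:
    """Mean per-class DSC (%) and HD for one model on one split."""

    dsc: dict[str, float]            # percent, per nested class
    hd: dict[str, float]
    hd_variant: str
    per_sample: list[dict[str, float]] = field(default_factory=list)
    n_samples: int = 0

    def mean_foreground_dsc(self) -> float:
        return float(np.mean([self.dsc[c] for c in NESTED_CLASSES]))

    def row(self) -> dict[str, float]:
        out = {f"DSC_{c}": self.dsc[c] for c in NESTED_CLASSES}
        out.update({f"HD_{c}": self.hd[c] for c in NESTED_CLASSES})
        return out


def predict_labels(model, image: np.ndarray) -> np.ndarray:
    """Argmax segmentation of one [C, *spatial] image (eval mode)."""
    was_training = model.training
    model.eval()
    try:
        pred = model(image[None])
        return pred.probs.data[0].argmax(axis=0)
    finally:
        model.train(was_training)


def evaluate_model(model, samples, hd_variant: str = "max",
                   spacing: tuple[float, ...] | None = None,
                   empty_sentinel: float = EMPTY_HD_SENTINEL) -> MetricReport:
    """Per-sample nested-class DSC/HD, averaged over the split."""
    if len(samples) == 0:
        raise ValueError("empty evaluation split")
    rows = []
    for sample in samples:
        label = sample.reveal() if hasattr(sample, "reveal") else sample.label
        pred = predict_labels(model, sample.image)
        pm = nested_masks(pred)
        tm = nested_masks(label)
        row = {}
        for cls in NESTED_CLASSES:
            row[f"DSC_{cls}"] = 100.0 * dice_score(pm[cls], tm[cls])
            row[f"HD_{cls}"] = hausdorff_distance(
                pm[cls], tm[cls], variant=hd_variant, spacing=spacing,
                empty_sentinel=empty_sentinel)
        rows.append(row)
    dsc = {c: float(np.mean([r[f"DSC_{c}"] for r in rows]))
           for c in NESTED_CLASSES}
    hd = {c: float(np.mean([r[f"HD_{c}"] for r in rows]))
          for c in NESTED_CLASSES}
    return MetricReport(dsc=dsc, hd=hd, hd_variant=hd_variant,
                        per_sample=rows, n_samples=len(rows))


def report_table(reports: dict[str, MetricReport]) -> pd.DataFrame:
    """Rows = methods, columns = nested classes x {DSC, HD}."""
    return pd.DataFrame({name: rep.row() for name, rep in reports.items()}).T
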
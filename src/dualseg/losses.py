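"""Scalar training objectives.

Supervised compound loss (0.5*dice + class-normalized cross-entropy),
transform-consistency MSE, reliability computation, the reliability-gated
cross-coordination constraint between the two students, adversarial and
discriminator binary cross-entropies, and the weighted per-student total.

All functions accept/return autodiff tensors so they can drive training,
and plain arrays wrapped in :class:`SoftPrediction` for testing.
"""
from __future__ import annotations

import numpy as np

from .nn import Tensor, astensor, clip, softplus
from .nn.tensor import log as tlog, tsum
from .types import _PROB_EPS, LossBundle, ReliabilityBundle, SoftPrediction

DICE_SMOOTH = 1e-5


def _check_onehot(target: np.ndarray, class_axis: int):
    if not np.all((target == 0) | (target == 1)):
        raise ValueError("target must be one-hot (0/1 entries)")
    if not np.allclose(target.sum(axis=class_axis), 1.0):
        raise ValueError("target must be one-hot (per-voxel class sums of 1)")


def _class_reduce_axes(pred: SoftPrediction) -> tuple:
    """All axes except the class axis (i.e. batch + spatial)."""
    ax = pred.class_axis
    return tuple(i for i in range(pred.probs.ndim) if i != ax)


def dice_loss(pred: SoftPrediction, target, smooth: float = DICE_SMOOTH) -> Tensor:
    """Class-averaged soft dice loss, smoothed in numerator and denominator.

    1 - (1/M) * sum_c (2*sum p*y + s) / (sum p + sum y + s); an absent and
    unpredicted class therefore contributes a perfect per-class dice of 1.
    """
    target = np.asarray(target, dtype=np.float64)
    if target.shape != pred.probs.shape:
        raise ValueError(f"shape mismatch: pred {pred.probs.shape} vs "
                         f"target {target.shape}")
    _check_onehot(target, pred.class_axis)
    axes = _class_reduce_axes(pred)
    m = pred.num_classes
    inter = tsum(pred.probs * target, axis=axes)
    sums = tsum(pred.probs, axis=axes) + target.sum(axis=axes)
    per_class = (2.0 * inter + smooth) / (sums + smooth)
    return 1.0 - tsum(per_class) * (1.0 / m)


def cross_entropy_loss(pred: SoftPrediction, target) -> Tensor:
    """Class-normalized CE: mean over voxels of -(1/M) * sum_c y*log p."""
    target = np.asarray(target, dtype=np.float64)
    if target.shape != pred.probs.shape:
        raise ValueError(f"shape mismatch: pred {pred.probs.shape} vs "
                         f"target {target.shape}")
    m = pred.num_classes
    logp = tlog(clip(pred.probs, _PROB_EPS, 1.0 - _PROB_EPS))
    per_voxel = tsum(logp * target, axis=pred.class_axis)
    n_vox = per_voxel.size
    return -tsum(per_voxel) * (1.0 / (m * n_vox))


def supervised_loss(pred: SoftPrediction, target) -> Tensor:
    """Compound segmentation loss: 0.5*dice + cross-entropy."""
    return 0.5 * dice_loss(pred, target) + cross_entropy_loss(pred, target)


def consistency_loss(pred_on_transformed: SoftPrediction,
                     transformed_pred: SoftPrediction) -> Tensor:
    """MSE between two probability maps in the same (transformed) frame."""
    a, b = pred_on_transformed.probs, transformed_pred.probs
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    d = a - b
    return tsum(d * d) * (1.0 / a.size)


def entropy_loss(pred: SoftPrediction) -> Tensor:
    """Mean over voxels of the Shannon entropy of the softmax output."""
    logp = tlog(clip(pred.probs, _PROB_EPS, 1.0 - _PROB_EPS))
    per_voxel = -tsum(pred.probs * logp, axis=pred.class_axis)
    return tsum(per_voxel) * (1.0 / per_voxel.size)


def compute_reliability(pred_clean: SoftPrediction, pred_noisy: SoftPrediction,
                        xi: float, quorum: float = 0.5) -> ReliabilityBundle:
    """Label agreement + confidence gating + stability distance for one sample.

    Both predictions must be for the same sample in a common frame (the
    clean prediction spatially replayed to the perturbed frame).  A voxel is
    reliable iff its clean and perturbed argmax labels agree AND at least
    one of the two max-probabilities exceeds ``xi``.  The stability distance
    is the L2 norm of the difference of the two full probability maps (one
    scalar per sample).  The sample-level bit is 1 iff the reliable-voxel
    fraction exceeds ``quorum``.
    """
    if not 0.0 <= xi <= 1.0:
        raise ValueError(f"xi must be in [0, 1], got {xi}")
    p0 = pred_clean.probs.data
    p1 = pred_noisy.probs.data
    if p0.shape != p1.shape:
        raise ValueError(f"shape mismatch: {p0.shape} vs {p1.shape}")
    ax = pred_clean.class_axis
    labels = p0.argmax(axis=ax)
    labels_noisy = p1.argmax(axis=ax)
    maxprob = p0.max(axis=ax)
    maxprob_noisy = p1.max(axis=ax)
    reliable = (labels == labels_noisy) & ((maxprob > xi) | (maxprob_noisy > xi))
    epsilon = float(np.linalg.norm(p0 - p1))
    return ReliabilityBundle(
        labels=labels, labels_noisy=labels_noisy,
        maxprob=maxprob, maxprob_noisy=maxprob_noisy,
        reliable=reliable, epsilon=epsilon,
        sample_reliable=bool(reliable.mean() > quorum),
    )


def cross_coordination_loss(bundle_i: ReliabilityBundle,
                            bundle_j: ReliabilityBundle,
                            pred_i: SoftPrediction,
                            pred_j: SoftPrediction) -> tuple[Tensor, Tensor]:
    """Reliability-gated knowledge exchange between the two students.

    For student i: when both students are reliable, i learns from j only if
    i is the less stable one (epsilon_i > epsilon_j); otherwise i learns
    from j iff j is reliable.  The target (the other student's prediction)
    is gradient-detached, so knowledge flows one way per term.
    """
    if pred_i.probs.shape != pred_j.probs.shape:
        raise ValueError("mismatched sample shapes")
    r_i, r_j = bundle_i.sample_reliable, bundle_j.sample_reliable
    e_i, e_j = bundle_i.epsilon, bundle_j.epsilon

    def mse_to(pred, target_pred):
        return consistency_loss(pred, target_pred.detach())

    if r_i and r_j:
        loss_i = mse_to(pred_i, pred_j) if e_i > e_j else Tensor(0.0)
        loss_j = mse_to(pred_j, pred_i) if e_j > e_i else Tensor(0.0)
    else:
        loss_i = mse_to(pred_i, pred_j) if r_j else Tensor(0.0)
        loss_j = mse_to(pred_j, pred_i) if r_i else Tensor(0.0)
    return loss_i, loss_j


def _bce_with_logits(logits: Tensor, label: float) -> Tensor:
    # -label*log(sig(z)) - (1-label)*log(1-sig(z)), stable via softplus
    logits = astensor(logits)
    if label == 1.0:
        per = softplus(-logits)
    elif label == 0.0:
        per = softplus(logits)
    else:
        per = softplus(logits) - label * logits
    return tsum(per) * (1.0 / per.size)


def adversarial_generator_loss(disc_out_on_target) -> Tensor:
    """BCE of discriminator logits on target outputs against the SOURCE label.

    The generator tries to make target-derived maps look like source
    (label convention: source=1, target=0).
    """
    return _bce_with_logits(disc_out_on_target, 1.0)


def discriminator_loss(disc_out_source, disc_out_target) -> Tensor:
    """BCE with source maps labeled 1 and target maps labeled 0, averaged."""
    return 0.5 * (_bce_with_logits(disc_out_source, 1.0)
                  + _bce_with_logits(disc_out_target, 0.0))


def total_student_loss(l_seg, l_con, l_cross, l_adv,
                       xi_weight: float, lambda_adv: float) -> tuple[Tensor, LossBundle]:
    """Weighted per-student total; components recorded unweighted."""
    if xi_weight < 0 or lambda_adv < 0:
        raise ValueError("loss weights must be nonnegative")
    l_seg, l_con = astensor(l_seg), astensor(l_con)
    l_cross, l_adv = astensor(l_cross), astensor(l_adv)
    total = l_seg + xi_weight * l_con + l_cross + lambda_adv * l_adv
    bundle = LossBundle(l_seg=l_seg.item(), l_con=l_con.item(),
                        l_cross=l_cross.item(), l_adv=l_adv.item(),
                        total=total.item())
    return total, bundle
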
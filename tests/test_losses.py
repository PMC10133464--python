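import itertools
import math

import numpy as np
import pytest

from dualseg import losses as L
from dualseg.nn import Tensor
from dualseg.types import ReliabilityBundle, SoftPrediction

from conftest import random_soft_prediction


# ---------------------------------------------------------------------
# independent scalar-loop oracles
# ---------------------------------------------------------------------

def dice_oracle(probs, onehot, smooth=L.DICE_SMOOTH):
    m = probs.shape[0]
    total = 0.0
    for c in range(m):
        inter = psum = ysum = 0.0
        for idx in np.ndindex(*probs.shape[1:]):
            inter += probs[(c,) + idx] * onehot[(c,) + idx]
            psum += probs[(c,) + idx]
            ysum += onehot[(c,) + idx]
        total += (2.0 * inter + smooth) / (psum + ysum + smooth)
    return 1.0 - total / m


def ce_oracle(probs, onehot, eps=1e-7):
    m = probs.shape[0]
    acc = 0.0
    n_vox = 0
    for idx in np.ndindex(*probs.shape[1:]):
        n_vox += 1
        for c in range(m):
            p = min(max(probs[(c,) + idx], eps), 1 - eps)
            acc += -onehot[(c,) + idx] * math.log(p)
    return acc / (m * n_vox)


def mse_oracle(a, b):
    acc = 0.0
    for x, y in zip(a.ravel(), b.ravel()):
        acc += (x - y) ** 2
    return acc / a.size


def bce_oracle(logits, label):
    acc = 0.0
    for z in logits.ravel():
        p = 1.0 / (1.0 + math.exp(-z))
        acc += -(label * math.log(p) + (1 - label) * math.log(1 - p))
    return acc / logits.size


def random_onehot(rng, shape_with_classes):
    m = shape_with_classes[0]
    labels = rng.integers(0, m, size=shape_with_classes[1:])
    out = np.zeros(shape_with_classes)
    for c in range(m):
        out[c] = labels == c
    return out


# ---------------------------------------------------------------------
# dice
# ---------------------------------------------------------------------

class TestDiceLoss:
    def test_perfect_prediction_is_zero(self, rng):
        y = random_onehot(rng, (3, 4, 4))
        pred = SoftPrediction.from_probs(y.astype(float))
        assert L.dice_loss(pred, y).item() == pytest.approx(0.0, abs=1e-4)

    def test_hand_computed_two_voxel_case(self):
        # single fg class over 4 voxels: p=(1,1,0,0), y=(1,0,0,0)
        probs = np.zeros((2, 2, 2))
        probs[1] = [[1, 1], [0, 0]]
        probs[0] = 1 - probs[1]
        y = np.zeros((2, 2, 2))
        y[1, 0, 0] = 1
        y[0] = 1 - y[1]
        pred = SoftPrediction.from_probs(probs)
        # fg dice = 2*1/(2+1) = 2/3; bg dice = 2*2/(2+3) = 4/5
        expected = 1.0 - 0.5 * (2 / 3 + 4 / 5)
        assert L.dice_loss(pred, y).item() == pytest.approx(expected, abs=1e-4)

    def test_absent_class_contribution_governed_by_smoothing(self):
        # class 2 absent in pred and target -> per-class dice s/s = 1
        probs = np.zeros((3, 2, 2))
        probs[0] = 1.0
        y = probs.copy()
        pred = SoftPrediction.from_probs(probs)
        assert L.dice_loss(pred, y).item() == pytest.approx(0.0, abs=1e-5)

    def test_matches_loop_oracle_on_random_inputs(self, rng):
        for _ in range(5):
            m = int(rng.integers(2, 5))
            pred = random_soft_prediction(rng, m, (4, 4))
            y = random_onehot(rng, (m, 4, 4))
            assert L.dice_loss(pred, y).item() == pytest.approx(
                dice_oracle(pred.probs.data, y), abs=1e-6)

    def test_shape_mismatch_and_not_onehot_errors(self, rng):
        pred = random_soft_prediction(rng, 3, (4, 4))
        with pytest.raises(ValueError, match="shape"):
            L.dice_loss(pred, np.zeros((3, 5, 5)))
        bad = np.full((3, 4, 4), 0.5)
        with pytest.raises(ValueError, match="one-hot"):
            L.dice_loss(pred, bad)


class TestCrossEntropyLoss:
    def test_confident_correct_prediction_is_zero(self, rng):
        y = random_onehot(rng, (4, 3, 3))
        pred = SoftPrediction.from_probs(y.astype(float))
        assert L.cross_entropy_loss(pred, y).item() == pytest.approx(
            0.0, abs=1e-5)

    @pytest.mark.parametrize("m", [2, 3, 4])
    def test_uniform_prediction_closed_form(self, m, rng):
        probs = np.full((m, 4, 4), 1.0 / m)
        y = random_onehot(rng, (m, 4, 4))
        pred = SoftPrediction.from_probs(probs)
        assert L.cross_entropy_loss(pred, y).item() == pytest.approx(
            math.log(m) / m, rel=1e-9)

    def test_two_voxel_toy_matches_scalar_oracle(self):
        probs = np.array([[[0.7], [0.2]], [[0.3], [0.8]]])  # [2, 2, 1]
        y = np.array([[[1.0], [0.0]], [[0.0], [1.0]]])
        pred = SoftPrediction.from_probs(probs)
        assert L.cross_entropy_loss(pred, y).item() == pytest.approx(
            ce_oracle(probs, y), abs=1e-9)

    def test_matches_loop_oracle_on_random_inputs(self, rng):
        for _ in range(5):
            m = int(rng.integers(2, 5))
            pred = random_soft_prediction(rng, m, (4, 4))
            y = random_onehot(rng, (m, 4, 4))
            assert L.cross_entropy_loss(pred, y).item() == pytest.approx(
                ce_oracle(pred.probs.data, y), abs=1e-6)


class TestSupervisedLoss:
    def test_perfect_prediction_is_zero(self, rng):
        y = random_onehot(rng, (3, 4, 4))
        pred = SoftPrediction.from_probs(y.astype(float))
        assert L.supervised_loss(pred, y).item() == pytest.approx(0.0, abs=1e-4)

    def test_composition_of_oracles(self, rng):
        pred = random_soft_prediction(rng, 3, (4, 4))
        y = random_onehot(rng, (3, 4, 4))
        expected = 0.5 * dice_oracle(pred.probs.data, y) \
            + ce_oracle(pred.probs.data, y)
        assert L.supervised_loss(pred, y).item() == pytest.approx(
            expected, abs=1e-6)


class TestConsistencyLoss:
    def test_identical_maps_zero(self, rng):
        pred = random_soft_prediction(rng, 3, (4, 4))
        assert L.consistency_loss(pred, pred).item() == 0.0

    def test_single_element_delta(self):
        a = np.full((2, 2, 2), 0.5)
        b = a.copy()
        delta = 0.25
        b[0, 0, 0] += delta
        pa = SoftPrediction.from_probs(a)
        pb = SoftPrediction.from_probs(b)
        assert L.consistency_loss(pa, pb).item() == pytest.approx(
            delta ** 2 / a.size, rel=1e-12)

    def test_matches_loop_oracle(self, rng):
        a = random_soft_prediction(rng, 4, (4, 4))
        b = random_soft_prediction(rng, 4, (4, 4))
        assert L.consistency_loss(a, b).item() == pytest.approx(
            mse_oracle(a.probs.data, b.probs.data), abs=1e-6)

    def test_shape_mismatch(self, rng):
        a = random_soft_prediction(rng, 3, (4, 4))
        b = random_soft_prediction(rng, 3, (5, 5))
        with pytest.raises(ValueError):
            L.consistency_loss(a, b)


class TestEntropyLoss:
    def test_onehot_prediction_zero(self, rng):
        y = random_onehot(rng, (3, 4, 4))
        pred = SoftPrediction.from_probs(y.astype(float))
        assert L.entropy_loss(pred).item() == pytest.approx(0.0, abs=1e-5)

    def test_uniform_maximizes(self):
        m = 4
        pred = SoftPrediction.from_probs(np.full((m, 3, 3), 1.0 / m))
        assert L.entropy_loss(pred).item() == pytest.approx(
            math.log(m), rel=1e-9)


# ---------------------------------------------------------------------
# reliability + cross-coordination
# ---------------------------------------------------------------------

class TestComputeReliability:
    def test_identical_confident_predictions(self):
        probs = np.zeros((2, 3, 3))
        probs[1] = 1.0
        pred = SoftPrediction.from_probs(probs)
        rb = L.compute_reliability(pred, pred, xi=0.5)
        assert rb.reliable.all()
        assert rb.epsilon == 0.0
        assert rb.sample_reliable

    def test_agreeing_labels_low_confidence_unreliable(self):
        probs = np.zeros((3, 1, 1))
        probs[:, 0, 0] = [0.4, 0.35, 0.25]
        pred = SoftPrediction.from_probs(probs)
        rb = L.compute_reliability(pred, pred, xi=0.8)
        assert not rb.reliable[0, 0]

    def test_disagreeing_argmax_confident_still_unreliable(self):
        a = np.zeros((2, 1, 1))
        a[:, 0, 0] = [0.99, 0.01]
        b = np.zeros((2, 1, 1))
        b[:, 0, 0] = [0.01, 0.99]
        rb = L.compute_reliability(SoftPrediction.from_probs(a),
                                   SoftPrediction.from_probs(b), xi=0.5)
        assert not rb.reliable[0, 0]

    def test_epsilon_is_l2_of_prob_difference(self, rng):
        a = random_soft_prediction(rng, 3, (4, 4))
        b = random_soft_prediction(rng, 3, (4, 4))
        rb = L.compute_reliability(a, b, xi=0.5)
        expected = math.sqrt(((a.probs.data - b.probs.data) ** 2).sum())
        assert rb.epsilon == pytest.approx(expected, rel=1e-12)

    def test_epsilon_zero_iff_identical(self, rng):
        a = random_soft_prediction(rng, 3, (4, 4))
        assert L.compute_reliability(a, a, xi=0.5).epsilon == 0.0
        b = random_soft_prediction(rng, 3, (4, 4))
        assert L.compute_reliability(a, b, xi=0.5).epsilon > 0.0

    def test_invalid_xi(self, rng):
        a = random_soft_prediction(rng, 2, (2, 2))
        with pytest.raises(ValueError):
            L.compute_reliability(a, a, xi=1.5)

    @pytest.mark.parametrize("xi", [0.0, 0.5, 0.8, 1.0])
    def test_voxelwise_boolean_oracle(self, xi, rng):
        for _ in range(10):
            a = random_soft_prediction(rng, int(rng.integers(2, 5)), (4, 4))
            b = random_soft_prediction(rng, a.num_classes, (4, 4))
            rb = L.compute_reliability(a, b, xi=xi)
            pa, pb = a.probs.data, b.probs.data
            for i in range(4):
                for j in range(4):
                    agree = pa[:, i, j].argmax() == pb[:, i, j].argmax()
                    conf = (pa[:, i, j].max() > xi) or (pb[:, i, j].max() > xi)
                    assert rb.reliable[i, j] == (agree and conf)


def _bundle(reliable: bool, epsilon: float) -> ReliabilityBundle:
    shape = (2, 2)
    return ReliabilityBundle(
        labels=np.zeros(shape, int), labels_noisy=np.zeros(shape, int),
        maxprob=np.ones(shape), maxprob_noisy=np.ones(shape),
        reliable=np.full(shape, reliable), epsilon=epsilon,
        sample_reliable=reliable)


class TestCrossCoordination:
    def test_identical_predictions_zero_both(self, rng):
        p = random_soft_prediction(rng, 3, (4, 4))
        li, lj = L.cross_coordination_loss(_bundle(True, 1.0),
                                           _bundle(True, 0.5), p, p)
        assert li.item() == 0.0 and lj.item() == 0.0

    def test_both_reliable_less_stable_learns(self, rng):
        pi = random_soft_prediction(rng, 3, (4, 4))
        pj = random_soft_prediction(rng, 3, (4, 4))
        mse = L.consistency_loss(pi, pj).item()
        li, lj = L.cross_coordination_loss(_bundle(True, 2.0),
                                           _bundle(True, 1.0), pi, pj)
        assert li.item() == pytest.approx(mse, rel=1e-12)
        assert lj.item() == 0.0

    def test_full_truth_table(self, rng):
        """All 8 combinations of (R_i, R_j, sign(eps_i - eps_j)) against a
        hand-enumerated table of the gating rule."""
        pi = random_soft_prediction(rng, 3, (4, 4))
        pj = random_soft_prediction(rng, 3, (4, 4))
        mse = L.consistency_loss(pi, pj).item()
        for r_i, r_j, i_less_stable in itertools.product(
                [False, True], repeat=3):
            e_i, e_j = (2.0, 1.0) if i_less_stable else (1.0, 2.0)
            li, lj = L.cross_coordination_loss(
                _bundle(r_i, e_i), _bundle(r_j, e_j), pi, pj)
            if r_i and r_j:
                exp_i = mse if e_i > e_j else 0.0
                exp_j = mse if e_j > e_i else 0.0
            else:
                exp_i = mse if r_j else 0.0
                exp_j = mse if r_i else 0.0
            assert li.item() == pytest.approx(exp_i, rel=1e-12), \
                (r_i, r_j, i_less_stable)
            assert lj.item() == pytest.approx(exp_j, rel=1e-12), \
                (r_i, r_j, i_less_stable)

    def test_target_carries_no_gradient(self, rng):
        logits_i = Tensor(rng.normal(size=(3, 4, 4)), requires_grad=True)
        logits_j = Tensor(rng.normal(size=(3, 4, 4)), requires_grad=True)
        pi = SoftPrediction.from_logits(logits_i)
        pj = SoftPrediction.from_logits(logits_j)
        li, _ = L.cross_coordination_loss(_bundle(True, 2.0),
                                          _bundle(True, 1.0), pi, pj)
        li.backward()
        assert logits_i.grad is not None
        assert logits_j.grad is None  # detached target


# ---------------------------------------------------------------------
# adversarial / discriminator
# ---------------------------------------------------------------------

class TestAdversarialLosses:
    def test_perfectly_fooled_generator_loss_near_zero(self):
        logits = np.full((1, 1, 2, 2), 50.0)  # sigmoid ~ 1 = source label
        assert L.adversarial_generator_loss(Tensor(logits)).item() < 1e-6

    def test_half_probability_closed_form(self):
        logits = np.zeros((1, 1, 2, 2))  # sigmoid = 0.5
        assert L.adversarial_generator_loss(Tensor(logits)).item() == \
            pytest.approx(-math.log(0.5), rel=1e-12)

    def test_generator_matches_bce_oracle(self, rng):
        logits = rng.normal(size=(2, 1, 3, 3))
        assert L.adversarial_generator_loss(Tensor(logits)).item() == \
            pytest.approx(bce_oracle(logits, 1.0), abs=1e-9)

    def test_perfect_discrimination_near_zero(self):
        src = np.full((1, 1, 2, 2), 50.0)
        tgt = np.full((1, 1, 2, 2), -50.0)
        assert L.discriminator_loss(Tensor(src), Tensor(tgt)).item() < 1e-6

    def test_constant_half_closed_form(self):
        z = np.zeros((1, 1, 2, 2))
        assert L.discriminator_loss(Tensor(z), Tensor(z)).item() == \
            pytest.approx(-math.log(0.5), rel=1e-12)

    def test_discriminator_matches_bce_oracle(self, rng):
        src = rng.normal(size=(2, 1, 2, 2))
        tgt = rng.normal(size=(2, 1, 2, 2))
        expected = 0.5 * (bce_oracle(src, 1.0) + bce_oracle(tgt, 0.0))
        assert L.discriminator_loss(Tensor(src), Tensor(tgt)).item() == \
            pytest.approx(expected, abs=1e-9)


class TestTotalStudentLoss:
    def test_all_zero(self):
        total, bundle = L.total_student_loss(0.0, 0.0, 0.0, 0.0, 1.0, 0.1)
        assert total.item() == 0.0 and bundle.total == 0.0

    def test_weighted_arithmetic(self):
        total, bundle = L.total_student_loss(1.0, 1.0, 1.0, 1.0,
                                             xi_weight=0.8, lambda_adv=0.1)
        assert total.item() == pytest.approx(2.9, rel=1e-12)
        assert bundle.l_con == 1.0  # recorded unweighted

    def test_lambda_zero_recovers_nonadversarial(self, rng):
        vals = rng.random(4)
        t1, _ = L.total_student_loss(*vals, xi_weight=0.7, lambda_adv=0.0)
        t2, _ = L.total_student_loss(vals[0], vals[1], vals[2], 0.0,
                                     xi_weight=0.7, lambda_adv=1.0)
        assert t1.item() == pytest.approx(t2.item(), rel=1e-12)

    def test_negative_weights_error(self):
        with pytest.raises(ValueError):
            L.total_student_loss(1, 1, 1, 1, xi_weight=-0.1, lambda_adv=0.1)

    def test_linear_in_each_component(self, rng):
        base = rng.random(4)
        xi_w, lam = 0.8, 0.1
        t0, _ = L.total_student_loss(*base, xi_w, lam)
        coeffs = [1.0, xi_w, 1.0, lam]
        for k in range(4):
            bumped = base.copy()
            bumped[k] += 0.5
            t1, _ = L.total_student_loss(*bumped, xi_w, lam)
            assert t1.item() - t0.item() == pytest.approx(
                0.5 * coeffs[k], rel=1e-9)
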
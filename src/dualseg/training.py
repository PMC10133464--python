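"""Training procedures: the proposed dual-student adversarial framework and
the baseline experiment arms, with poly learning-rate decay and the staged
adversarial weight schedule.

Every source of randomness is a named child stream of the run seed, so two
runs with the same config produce identical loss histories, and single-
student arms consume exactly the same sampling streams as each student of
the dual arms (which makes the ablation-reduction equivalences exact).
"""
from __future__ import annotations

import copy
import sys
from dataclasses import dataclass

import numpy as np

from . import losses as L
from .evaluation import evaluate_model
from .models import (DiscConfig, Discriminator, SegNetConfig, UNet,
                     build_discriminator, build_segmentor)
from .nn import Tensor
from .nn.optim import SGD, Adam
from .synthetic import DatasetBundle, onehot
from .transforms import (TransformConfig, apply_spatial_to_prediction,
                         apply_to_image, sample_transform)
from .types import LossBundle, SoftPrediction

MODES = ("proposed", "super_all", "super_source", "da_mt",
         "da_entropy_mini", "da_adv", "da_ds")
DUAL_MODES = ("proposed", "da_ds")
ADV_MODES = ("proposed", "da_adv")


@dataclass
class TrainConfig:
    mode: str = "proposed"
    max_iter: int = 15000
    batch_size: int = 2
    base_lr: float = 0.01
    poly_power: float = 0.9
    sgd_momentum: float = 0.9
    weight_decay: float = 1e-4
    adam_beta1: float = 0.45
    adam_beta2: float = 0.999
    disc_lr: float = 1e-4
    lambda_adv_initial: float = 0.1
    lambda_adv_final: float = 1.0
    lambda_switch_iter: int | None = None   # default 0.8 * max_iter
    xi_threshold: float = 0.8
    xi_weight: float = 1.0
    entropy_weight: float = 1.0
    reliability_quorum: float = 0.5         # > 1 forces sample-level R = 0
    ema_alpha: float = 0.99                 # da_mt only
    share_transforms: bool = False
    init_schemes: tuple[str, str] = ("xavier", "kaiming")
    single_student_index: int = 0           # which stream single-student arms use
    val_interval: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; choose from {MODES}")
        for name in ("base_lr", "disc_lr", "batch_size", "max_iter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.lambda_switch_iter is not None \
                and self.lambda_switch_iter > self.max_iter:
            raise ValueError("lambda_switch_iter must be <= max_iter")


def poly_lr(base_lr: float, it: int, max_iter: int, power: float) -> float:
    """base_lr * (1 - iter/max_iter)^power."""
    if not 0 <= it <= max_iter:
        raise ValueError(f"iter {it} outside [0, {max_iter}]")
    return base_lr * (1.0 - it / max_iter) ** power


def lambda_adv_at(it: int, config: TrainConfig) -> float:
    """Step schedule: the initial small weight until the switch, then the
    final weight ("after all iterations" implemented as a late switch)."""
    switch = config.lambda_switch_iter
    if switch is None:
        switch = int(0.8 * config.max_iter)
    return config.lambda_adv_initial if it < switch else config.lambda_adv_final


class _EpochSampler:
    """Infinite sampler; reshuffles a permutation on exhaustion."""

    def __init__(self, n: int, rng: np.random.Generator):
        self.n = n
        self.rng = rng
        self._queue: list[int] = []

    def draw(self, k: int) -> list[int]:
        out = []
        while len(out) < k:
            if not self._queue:
                self._queue = list(self.rng.permutation(self.n))
            out.append(int(self._queue.pop()))
        return out


def _nan_guard(name: str, value: float, it: int):
    if not np.isfinite(value):
        raise FloatingPointError(
            f"non-finite loss component {name!r} ({value}) at iteration {it}")


def _per_sample_pred(pred: SoftPrediction, b: int) -> SoftPrediction:
    return SoftPrediction(logits=pred.logits[b:b + 1], probs=pred.probs[b:b + 1])


@dataclass
class TrainResult:
    history: list[dict]
    val_history: list[dict]
    best_iter: int
    best_student: int
    best_val_dsc: float
    trainer: "Trainer"


class Trainer:
    """Holds the students, discriminators, optimizers and RNG streams for
    one run of one experiment arm."""

    def __init__(self, config: TrainConfig, seg_config: SegNetConfig,
                 data: DatasetBundle,
                 disc_config: DiscConfig | None = None,
                 transform_config: TransformConfig | None = None):
        self.config = config
        self.seg_config = seg_config
        self.data = data
        self.transform_config = transform_config or TransformConfig()
        if disc_config is None:
            disc_config = DiscConfig(in_channels=seg_config.num_classes,
                                     spatial_rank=seg_config.spatial_rank,
                                     base_width=max(8, seg_config.base_width))
        self.disc_config = disc_config

        # named child streams: identical spawning order in every mode
        ss = np.random.SeedSequence(config.seed)
        (s_init1, s_init2, d_init1, d_init2,
         src_ss, tgt_ss, tf1, tf2) = ss.spawn(8)
        init_seeds = [s_init1, s_init2]
        disc_seeds = [d_init1, d_init2]
        self._src_rng = np.random.default_rng(src_ss)
        self._tgt_rng = np.random.default_rng(tgt_ss)
        self._tf_rngs = [np.random.default_rng(tf1), np.random.default_rng(tf2)]

        mode = config.mode
        self.n_students = 2 if mode in DUAL_MODES else 1
        if self.n_students == 2:
            student_ids = [0, 1]
        else:
            student_ids = [config.single_student_index]
        self.student_ids = student_ids
        self.students: list[UNet] = [
            build_segmentor(seg_config, config.init_schemes[i],
                            np.random.default_rng(init_seeds[i]).integers(2 ** 31))
            for i in student_ids
        ]
        self.opts = [SGD(s.parameters(), config.base_lr,
                         momentum=config.sgd_momentum,
                         weight_decay=config.weight_decay)
                     for s in self.students]

        self.discriminators: list[Discriminator] = []
        self.disc_opts: list[Adam] = []
        if mode in ADV_MODES:
            for i in student_ids:
                d = build_discriminator(
                    disc_config,
                    np.random.default_rng(disc_seeds[i]).integers(2 ** 31))
                self.discriminators.append(d)
                self.disc_opts.append(Adam(d.parameters(), config.disc_lr,
                                           beta1=config.adam_beta1,
                                           beta2=config.adam_beta2))

        self.teacher: UNet | None = None
        if mode == "da_mt":
            self.teacher = copy.deepcopy(self.students[0])
            self.teacher.requires_grad_(False)

        self._src_sampler = _EpochSampler(len(data.source_train), self._src_rng)
        self._tgt_sampler = _EpochSampler(len(data.target_train), self._tgt_rng)
        self.iteration = 0

    # -- data ----------------------------------------------------------
    def next_batch(self) -> dict:
        """One DomainBatch: labeled source + unlabeled target halves."""
        cfg = self.config
        rank = self.seg_config.spatial_rank
        m = self.seg_config.num_classes
        src = [self.data.source_train[i]
               for i in self._src_sampler.draw(cfg.batch_size)]
        xs = np.stack([s.image for s in src])
        ys = np.stack([onehot(s.label, m) for s in src])
        batch = {"source_images": xs, "source_labels": ys}
        if cfg.mode != "super_source":
            tgt = [self.data.target_train[i]
                   for i in self._tgt_sampler.draw(cfg.batch_size)]
            batch["target_images"] = np.stack([t.image for t in tgt])
            if cfg.mode == "super_all":
                labels = [t.reveal() for t in tgt]
                if any(lab is None for lab in labels):
                    raise ValueError(
                        "super_all requested without target labels")
                batch["target_labels"] = np.stack(
                    [onehot(lab, m) for lab in labels])
        return batch

    # -- schedules -----------------------------------------------------
    def _set_lr(self, it: int):
        lr = poly_lr(self.config.base_lr, it, self.config.max_iter,
                     self.config.poly_power)
        for opt in self.opts:
            opt.lr = lr
        return lr

    # -- pieces --------------------------------------------------------
    def _consistency_piece(self, student: UNet, xt: np.ndarray, tf_rng):
        """Target forwards + transform replay for one student.

        Returns (pred_clean, pred_aug_frame_clean, pred_on_aug, l_con).
        """
        rank = self.seg_config.spatial_rank
        spec = sample_transform(tf_rng, self.transform_config)
        xt_aug = apply_to_image(xt, spec, rank)
        pred_clean = student(xt)
        pred_on_aug = student(xt_aug)
        replayed = apply_spatial_to_prediction(pred_clean, spec, rank)
        l_con = L.consistency_loss(pred_on_aug, replayed)
        return pred_clean, replayed, pred_on_aug, l_con

    def _adv_piece(self, disc: Discriminator, pred_t: SoftPrediction):
        """Generator-side adversarial loss; no gradient into the disc.

        The discriminator's parameters stay requires_grad=False until its
        own step so the student's backward cannot touch them.
        """
        disc.requires_grad_(False)
        x = pred_t.probs if self.disc_config.input_kind == "probs" \
            else pred_t.logits
        out = disc(x)
        return L.adversarial_generator_loss(out)

    def _disc_step(self, idx: int, pred_s: SoftPrediction,
                   pred_t: SoftPrediction) -> float:
        disc, opt = self.discriminators[idx], self.disc_opts[idx]
        disc.requires_grad_(True)
        kind = self.disc_config.input_kind
        src_in = (pred_s.probs if kind == "probs" else pred_s.logits).detach()
        tgt_in = (pred_t.probs if kind == "probs" else pred_t.logits).detach()
        l_disc = L.discriminator_loss(disc(src_in), disc(tgt_in))
        disc.zero_grad()
        l_disc.backward()
        opt.step()
        return l_disc.item()

    # -- the step ------------------------------------------------------
    def train_step(self, batch: dict, it: int) -> list[LossBundle]:
        cfg = self.config
        mode = cfg.mode
        self._set_lr(it)
        if mode in DUAL_MODES:
            bundles = self._dual_step(batch, it, adversarial=(mode == "proposed"))
        else:
            bundles = [self._single_step(batch, it)]
        self.iteration = it + 1
        for b in bundles:
            for name, value in b.as_dict().items():
                if value is not None:
                    _nan_guard(name, value, it)
        return bundles

    def _dual_step(self, batch: dict, it: int, adversarial: bool) -> list[LossBundle]:
        cfg = self.config
        xs, ys = batch["source_images"], batch["source_labels"]
        xt = batch["target_images"]
        lam = lambda_adv_at(it, cfg) if adversarial else 0.0
        # lambda_adv = 0 disables the whole adversarial branch, which makes
        # the da_ds / dual-supervised reduction equivalences exact
        adversarial = adversarial and lam > 0

        seg_losses, con_losses, preds_clean, bundles_rel = [], [], [], []
        for i, student in enumerate(self.students):
            pred_s = student(xs)
            seg_losses.append((L.supervised_loss(pred_s, ys), pred_s))
            tf_rng = self._tf_rngs[0] if cfg.share_transforms else self._tf_rngs[i]
            pred_clean, replayed, pred_on_aug, l_con = \
                self._consistency_piece(student, xt, tf_rng)
            con_losses.append(l_con)
            preds_clean.append(pred_clean)
            per_sample = []
            for b in range(xt.shape[0]):
                per_sample.append(L.compute_reliability(
                    _per_sample_pred(replayed, b).detach(),
                    _per_sample_pred(pred_on_aug, b).detach(),
                    cfg.xi_threshold, quorum=cfg.reliability_quorum))
            bundles_rel.append(per_sample)

        # cross-coordination, per sample, averaged over the batch
        nb = xt.shape[0]
        cross = [0.0, 0.0]
        for b in range(nb):
            p_i = _per_sample_pred(preds_clean[0], b)
            p_j = _per_sample_pred(preds_clean[1], b)
            li, lj = L.cross_coordination_loss(
                bundles_rel[0][b], bundles_rel[1][b], p_i, p_j)
            cross[0] = cross[0] + li * (1.0 / nb)
            cross[1] = cross[1] + lj * (1.0 / nb)

        out = []
        for i, student in enumerate(self.students):
            l_seg, pred_s = seg_losses[i]
            if adversarial:
                l_adv = self._adv_piece(self.discriminators[i], preds_clean[i])
            else:
                l_adv = Tensor(0.0)
            total, bundle = L.total_student_loss(
                l_seg, con_losses[i], cross[i], l_adv,
                xi_weight=cfg.xi_weight, lambda_adv=lam)
            student.zero_grad()
            total.backward()
            self.opts[i].step()
            if adversarial:
                bundle.l_disc = self._disc_step(i, pred_s, preds_clean[i])
            out.append(bundle)
        return out

    def _single_step(self, batch: dict, it: int) -> LossBundle:
        cfg = self.config
        mode = cfg.mode
        student = self.students[0]
        xs, ys = batch["source_images"], batch["source_labels"]
        pred_s = student(xs)
        l_seg = L.supervised_loss(pred_s, ys)
        l_con, l_adv = Tensor(0.0), Tensor(0.0)
        lam = 0.0
        pred_t = None

        if mode == "super_all":
            pred_t = student(batch["target_images"])
            l_seg = l_seg + L.supervised_loss(pred_t, batch["target_labels"])
        elif mode == "da_mt":
            xt = batch["target_images"]
            rank = self.seg_config.spatial_rank
            spec = sample_transform(self._tf_rngs[0], self.transform_config)
            xt_aug = apply_to_image(xt, spec, rank)
            teacher_pred = self.teacher(xt)
            teacher_replayed = apply_spatial_to_prediction(
                teacher_pred, spec, rank).detach()
            pred_on_aug = student(xt_aug)
            l_con = L.consistency_loss(pred_on_aug, teacher_replayed)
        elif mode == "da_entropy_mini":
            pred_t = student(batch["target_images"])
            l_con = L.entropy_loss(pred_t)  # recorded in the l_con slot
        elif mode == "da_adv":
            pred_t = student(batch["target_images"])
            lam = lambda_adv_at(it, cfg)
            if lam > 0:
                l_adv = self._adv_piece(self.discriminators[0], pred_t)

        weight = {"da_mt": cfg.xi_weight,
                  "da_entropy_mini": cfg.entropy_weight}.get(mode, 0.0)
        total, bundle = L.total_student_loss(
            l_seg, l_con, 0.0, l_adv, xi_weight=weight, lambda_adv=lam)
        student.zero_grad()
        total.backward()
        self.opts[0].step()

        if mode == "da_adv" and pred_t is not None and lam > 0:
            bundle.l_disc = self._disc_step(0, pred_s, pred_t)
        if mode == "da_mt":
            self._ema_update()
        return bundle

    def _ema_update(self):
        a = self.config.ema_alpha
        for tp, sp in zip(self.teacher.parameters(),
                          self.students[0].parameters()):
            tp.data = a * tp.data + (1.0 - a) * sp.data
        for tm, sm in zip(self.teacher.modules(), self.students[0].modules()):
            for name, buf in getattr(tm, "_buffers", {}).items():
                tm._buffers[name] = a * buf + (1.0 - a) * sm._buffers[name]

    # -- the loop ------------------------------------------------------
    def train(self, log_every: int = 0) -> TrainResult:
        cfg = self.config
        history: list[dict] = []
        val_history: list[dict] = []
        best = (-1.0, 0, 0, None)  # (dsc, iter, student_idx, state)
        for it in range(cfg.max_iter):
            batch = self.next_batch()
            bundles = self.train_step(batch, it)
            for si, b in enumerate(bundles):
                row = {"iter": it, "student": si}
                row.update({k: v for k, v in b.as_dict().items()})
                history.append(row)
            if log_every and (it + 1) % log_every == 0:
                print(f"[iter {it + 1}/{cfg.max_iter}] "
                      f"lr={self.opts[0].lr:.5f} "
                      f"total={bundles[0].total:.4f}", file=sys.stderr)
            last = it == cfg.max_iter - 1
            if (it + 1) % cfg.val_interval == 0 or last:
                for si, student in enumerate(self.students):
                    rep = evaluate_model(student, self.data.target_val)
                    dsc = rep.mean_foreground_dsc()
                    val_history.append({"iter": it, "student": si,
                                        "mean_fg_dsc": dsc})
                    if dsc > best[0]:
                        best = (dsc, it, si, student.state_dict())
        best_dsc, best_it, best_si, best_state = best
        if best_state is not None:
            self.students[best_si].load_state_dict(best_state)
        return TrainResult(history=history, val_history=val_history,
                           best_iter=best_it, best_student=best_si,
                           best_val_dsc=best_dsc, trainer=self)

    def best_model(self, result: TrainResult) -> UNet:
        return self.students[result.best_student]


def train(config: TrainConfig, seg_config: SegNetConfig, data: DatasetBundle,
          disc_config: DiscConfig | None = None,
          transform_config: TransformConfig | None = None,
          log_every: int = 0) -> TrainResult:
    """Build a trainer and run the full schedule."""
    trainer = Trainer(config, seg_config, data, disc_config, transform_config)
    return trainer.train(log_every=log_every)
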
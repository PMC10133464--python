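# dualseg

Dual-student adversarial unsupervised domain adaptation (UDA) for semantic
segmentation, with a synthetic nested-lesion phantom benchmark so the whole
mechanism runs and is testable on a single CPU.

Two independently initialized U-Net students are trained side by side with
no weight coupling (no EMA teacher). Each student carries:

- a supervised compound loss on the labeled source domain
  (`0.5 * dice + class-normalized cross-entropy`),
- a transform-consistency MSE on the unlabeled target domain (exact,
  replayable 90-degree-rotation/flip spatial perturbations plus
  contrast/noise intensity perturbations on the image side only),
- a reliability-gated **cross-coordination** constraint: per target sample,
  each student's prediction stability (argmax agreement under perturbation,
  confidence threshold, L2 stability distance) decides which student learns
  from the other's (gradient-detached) prediction,
- an adversarial loss from its own domain discriminator (5-layer stride-2
  conv net), with a small initial weight stepped up late in training.

Seven experiment arms are implemented: `proposed`, `super_all`,
`super_source`, `da_mt` (mean teacher), `da_entropy_mini`, `da_adv`,
`da_ds` (dual student without discriminators).

The networks run on a small numpy reverse-mode autodiff backend
(`dualseg.nn`) — no GPU or deep-learning framework required.

## Layout

| module | contents |
| --- | --- |
| `dualseg.transforms` | replayable perturbation specs; identical spatial replay on images, labels, predictions |
| `dualseg.losses` | all scalar objectives incl. reliability + cross-coordination |
| `dualseg.models` | configurable 2D/3D U-Net, discriminator, Xavier/Kaiming builders |
| `dualseg.training` | `TrainConfig`, `Trainer`, poly LR + adversarial-weight schedules, all arms |
| `dualseg.synthetic` | phantom generator: nested classes, class imbalance, controllable source→target shift (`cross_grade`, `cross_modality` presets) |
| `dualseg.evaluation` | per-class DSC (%) and Hausdorff distance (`max`/`avg` variants) over nested whole/core/enhancing masks |
| `dualseg.io` / `dualseg.cli` | NIfTI volumes, YAML config, manifests, checkpoints (`.npz`), CLI |
| `dualseg.experiments` | canned desk-scale experiment recipes used by the acceptance suite |

## CLI

```bash
dualseg simulate --preset cross_modality --n-source 60 --n-target 40 \
    --n-val 10 --n-test 20 --seed 1 --out data/
dualseg train --config run.yaml --dataset data/ --mode proposed --out runs/proposed/
dualseg evaluate --config run.yaml --dataset data/ \
    --checkpoint runs/proposed/checkpoint.npz --out metrics.json
dualseg ablate --config run.yaml --dataset data/ --out runs/ablation/
```

A run config is one YAML file with `train:`, `model:`, `discriminator:`
and `transforms:` sections mirroring the dataclasses in `training`,
`models` and `transforms`; unknown/missing keys are reported exhaustively.
Every output directory contains a `manifest.json` sufficient to re-run the
experiment identically (training is deterministic per seed).

Example `run.yaml`:

```yaml
train:
  mode: proposed
  max_iter: 600
  batch_size: 2
  base_lr: 0.05
  xi_threshold: 0.6
  seed: 1
model:
  spatial_rank: 2
  in_channels: 2
  num_classes: 4
  depth: 3
  base_width: 8
  dropout: 0.0
```

## Notes

- Checkpoints are numpy `.npz` archives holding both students, both
  discriminators, optimizer states and the iteration counter.
- Real-data mode reads BraTS-style per-modality NIfTI volumes via
  `dualseg.io.read_multichannel`; 3D configs (`spatial_rank: 3`) use the
  same code paths as 2D.
- Determinism: all randomness flows from named child streams of the run
  seed; identical config + seed reproduces loss histories bit-for-bit.
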
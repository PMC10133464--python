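"""File I/O: NIfTI volumes, run configs, manifests, datasets, checkpoints."""
from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .models import DiscConfig, SegNetConfig
from .synthetic import DatasetBundle, DomainShift, PhantomSpec, Sample
from .training import TrainConfig, Trainer
from .transforms import TransformConfig


# -- volumes -----------------------------------------------------------

def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """NIfTI file -> (data array, 4x4 affine)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj), img.affine


def write_volume(path: str | Path, data: np.ndarray,
                 affine: np.ndarray | None = None):
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def read_multichannel(paths: list[str | Path]) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-modality NIfTI files into one [C, *spatial] array."""
    channels, affine, shape = [], None, None
    for p in paths:
        data, aff = read_volume(p)
        if shape is None:
            shape, affine = data.shape, aff
        elif data.shape != shape:
            raise ValueError(f"channel shape mismatch in {p}: "
                             f"{data.shape} vs {shape}")
        channels.append(data)
    return np.stack(channels), affine


# -- configs -----------------------------------------------------------

CONFIG_SECTIONS = {
    "train": TrainConfig,
    "model": SegNetConfig,
    "discriminator": DiscConfig,
    "transforms": TransformConfig,
}


def load_config(path: str | Path) -> dict:
    """One YAML/JSON file -> dict of typed config sections.

    Unknown keys and missing required sections are reported exhaustively
    in a single error message.
    """
    path = Path(path)
    text = path.read_text()
    raw = yaml.safe_load(text) or {}
    problems: list[str] = []
    out: dict = {}
    for section, cls in CONFIG_SECTIONS.items():
        block = raw.get(section, {}) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(block) - names
        if unknown:
            problems.append(f"{section}: unknown keys {sorted(unknown)}")
            block = {k: v for k, v in block.items() if k in names}
        # yaml lists -> tuples where the dataclass expects tuples
        coerced = {}
        for k, v in block.items():
            coerced[k] = tuple(v) if isinstance(v, list) else v
        try:
            out[section] = cls(**coerced)
        except (TypeError, ValueError) as exc:
            problems.append(f"{section}: {exc}")
    if problems:
        raise ValueError("config errors: " + "; ".join(problems))
    out["data"] = raw.get("data", {}) or {}
    return out


def config_to_dict(configs: dict) -> dict:
    out = {}
    for section, value in configs.items():
        out[section] = dataclasses.asdict(value) \
            if dataclasses.is_dataclass(value) else value
    return out


# -- manifests ---------------------------------------------------------

@dataclass
class RunManifest:
    config: dict
    seed: int
    created: str
    outputs: dict
    version: str = "0.1.0"

    def save(self, directory: str | Path):
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "manifest.json").write_text(
            json.dumps(dataclasses.asdict(self), indent=2, default=str))

    @classmethod
    def load(cls, directory: str | Path) -> "RunManifest":
        raw = json.loads((Path(directory) / "manifest.json").read_text())
        return cls(**raw)


def make_manifest(configs: dict, seed: int, outputs: dict) -> RunManifest:
    return RunManifest(config=config_to_dict(configs), seed=seed,
                       created=time.strftime("%Y-%m-%dT%H:%M:%S"),
                       outputs=outputs)


# -- datasets ----------------------------------------------------------

_SPLITS = ("source_train", "target_train", "target_val", "target_test",
           "source_test")


def export_dataset(data: DatasetBundle, directory: str | Path):
    """Write a phantom dataset as a BraTS-like NIfTI directory layout:
    one file per channel plus the segmentation, grouped per sample."""
    directory = Path(directory)
    for split in _SPLITS:
        split_dir = directory / split
        split_dir.mkdir(parents=True, exist_ok=True)
        for i, sample in enumerate(getattr(data, split)):
            sdir = split_dir / f"sample_{i:04d}"
            sdir.mkdir(exist_ok=True)
            for ch in range(sample.image.shape[0]):
                write_volume(sdir / f"channel_{ch}.nii", sample.image[ch])
            write_volume(sdir / "seg.nii", sample._label.astype(np.int16))
    meta = {
        "spec": dataclasses.asdict(data.spec),
        "seed": data.seed,
        "splits": {s: len(getattr(data, s)) for s in _SPLITS},
    }
    (directory / "manifest.json").write_text(
        json.dumps(meta, indent=2, default=str))


def import_dataset(directory: str | Path) -> DatasetBundle:
    directory = Path(directory)
    meta = json.loads((directory / "manifest.json").read_text())
    spec_raw = dict(meta["spec"])
    shift_raw = spec_raw.pop("shift")
    shift_raw["intensity_affine"] = tuple(
        tuple(p) for p in shift_raw["intensity_affine"])
    for key in ("lesion_count_range", "radius_range", "nesting_ratios"):
        spec_raw[key] = tuple(spec_raw[key])
    spec_raw["class_means"] = tuple(tuple(r) for r in spec_raw["class_means"])
    spec = PhantomSpec(shift=DomainShift(**shift_raw), **spec_raw)
    splits = {}
    for split in _SPLITS:
        samples = []
        split_dir = directory / split
        hidden = split == "target_train"
        domain = "source" if split.startswith("source") else "target"
        for sdir in sorted(split_dir.iterdir()):
            channels = sorted(sdir.glob("channel_*.nii"))
            image = np.stack([read_volume(p)[0] for p in channels])
            label = read_volume(sdir / "seg.nii")[0].astype(np.int64)
            samples.append(Sample(image=image, _label=label, domain=domain,
                                  hidden=hidden))
        splits[split] = samples
    return DatasetBundle(spec=spec, seed=meta["seed"], **splits)


# -- checkpoints -------------------------------------------------------

def save_checkpoint(path: str | Path, trainer: Trainer):
    """All students + discriminators + optimizer states + iteration."""
    arrays: dict[str, np.ndarray] = {"iteration": np.array(trainer.iteration)}
    for i, s in enumerate(trainer.students):
        for k, v in s.state_dict().items():
            arrays[f"student{i}/{k}"] = v
        for j, vel in enumerate(trainer.opts[i].state_dict()["velocity"]):
            arrays[f"opt{i}/velocity/{j}"] = vel
    for i, d in enumerate(trainer.discriminators):
        for k, v in d.state_dict().items():
            arrays[f"disc{i}/{k}"] = v
        st = trainer.disc_opts[i].state_dict()
        arrays[f"dopt{i}/t"] = np.array(st["t"])
        for j, m in enumerate(st["m"]):
            arrays[f"dopt{i}/m/{j}"] = m
        for j, v in enumerate(st["v"]):
            arrays[f"dopt{i}/v/{j}"] = v
    np.savez(str(path), **arrays)


def load_checkpoint(path: str | Path, trainer: Trainer):
    with np.load(str(path)) as z:
        arrays = {k: z[k] for k in z.files}
    trainer.iteration = int(arrays["iteration"])
    for i, s in enumerate(trainer.students):
        prefix = f"student{i}/"
        s.load_state_dict({k[len(prefix):]: v for k, v in arrays.items()
                           if k.startswith(prefix)})
        n = len(trainer.opts[i]._velocity)
        trainer.opts[i]._velocity = [
            np.array(arrays[f"opt{i}/velocity/{j}"]) for j in range(n)]
    for i, d in enumerate(trainer.discriminators):
        prefix = f"disc{i}/"
        d.load_state_dict({k[len(prefix):]: v for k, v in arrays.items()
                           if k.startswith(prefix)})
        opt = trainer.disc_opts[i]
        opt.t = int(arrays[f"dopt{i}/t"])
        opt._m = [np.array(arrays[f"dopt{i}/m/{j}"]) for j in range(len(opt._m))]
        opt._v = [np.array(arrays[f"dopt{i}/v/{j}"]) for j in range(len(opt._v))]


def history_to_csv(history: list[dict], path: str | Path):
    import csv
    if not history:
        return
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(history[0]))
        writer.writeheader()
        writer.writerows(history)
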
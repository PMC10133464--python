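"""Canned desk-scale experiment recipes.

These fix the exact configurations used by the acceptance checks and the
report script: 2D 32x32 phantoms, a small U-Net, and the published
optimizer/schedule settings scaled down to CPU budgets.  Everything is
deterministic per seed.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .evaluation import evaluate_model
from .models import SegNetConfig
from .synthetic import generate_dataset, preset_task
from .training import TrainConfig, train

DESK_SEG_CONFIG = SegNetConfig(spatial_rank=2, in_channels=2, num_classes=4,
                               depth=3, base_width=8, dropout=0.0)


def desk_train_config(mode: str, seed: int, max_iter: int = 600,
                      **overrides) -> TrainConfig:
    base = dict(mode=mode, max_iter=max_iter, batch_size=2, base_lr=0.05,
                val_interval=200, xi_threshold=0.6, seed=seed)
    base.update(overrides)
    return TrainConfig(**base)


def make_phantom_data(preset: str, seed: int, n_source: int = 60,
                      n_target: int = 40, n_val: int = 10, n_test: int = 20):
    spec = dataclasses.replace(preset_task(preset), seed=seed)
    return generate_dataset(spec, n_source, n_target, n_val, n_test,
                            rng=np.random.default_rng(seed))


def adaptation_gain_experiment(seeds=(1, 2, 3),
                               modes=("super_source", "da_mt", "proposed"),
                               preset: str = "cross_modality",
                               max_iter: int = 600) -> dict:
    """Scaled-down adaptation comparison on the cross-modality phantom.

    Returns {mode: {seed: mean foreground DSC (%) on held-out target}}.
    """
    results: dict = {mode: {} for mode in modes}
    for seed in seeds:
        data = make_phantom_data(preset, seed)
        for mode in modes:
            cfg = desk_train_config(mode, seed, max_iter=max_iter)
            res = train(cfg, DESK_SEG_CONFIG, data)
            model = res.trainer.best_model(res)
            rep = evaluate_model(model, data.target_test)
            results[mode][seed] = rep.mean_foreground_dsc()
    return results


def domain_gap_experiment(presets=("cross_grade", "cross_modality"),
                          seeds=(1, 2, 3), max_iter: int = 300) -> dict:
    """Source-only training, tested on both domains.

    Returns {preset: {seed: (source-test DSC, target-test DSC)}}; a real
    synthetic domain shift shows target < source for every run.
    """
    results: dict = {preset: {} for preset in presets}
    for preset in presets:
        for seed in seeds:
            data = make_phantom_data(preset, seed, n_source=30, n_target=10,
                                     n_val=5, n_test=10)
            cfg = desk_train_config("super_source", seed, max_iter=max_iter,
                                    val_interval=150)
            res = train(cfg, DESK_SEG_CONFIG, data)
            model = res.trainer.best_model(res)
            src = evaluate_model(model, data.source_test).mean_foreground_dsc()
            tgt = evaluate_model(model, data.target_test).mean_foreground_dsc()
            results[preset][seed] = (src, tgt)
    return results
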
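"""Desk-scale synthetic benchmark: the full pipeline at CPU-friendly size.

This preset runs the complete method — four base networks trained on
synthetic fundus data, a stacking meta-model fused on top — at a problem
size a single CPU core handles in minutes: 64×64 images, 40 training and
10 test samples, width-reduced networks (``base_channels=8``), 30 epochs
with batches of 8.

Learning rates: the batch-norm-equipped ResNet variants train stably at
3e-3; the plain U-Net variants use 1e-3 (at 1/8 width the protocol's 0.01
is unstable for them).  The meta-model — a two-layer convolutional fuser —
keeps the protocol rate of 0.01, matching the convention of reusing the
base hyperparameters for meta training.

Used by the test suite and the reproduction script; it is ordinary package
code and can be called directly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import ensemble as ens
from .architectures import ArchitectureSpec, SegmentationModel, build_model
from .io_datasets import split_dataset
from .metrics import MetricReport, evaluate_model
from .synth_fundus import default_configs, make_synthetic_dataset
from .training_pipeline import TrainConfig, train_segmentation_model

__all__ = ["BenchmarkResult", "run_synthetic_benchmark", "BASE_LEARNING_RATES"]

BASE_LEARNING_RATES = {
    "unet": 1e-3,
    "ctu_net": 1e-3,
    "resnet50_seg": 3e-3,
    "unet_resnet_backbone": 3e-3,
}
META_LEARNING_RATE = 0.01


@dataclass
class BenchmarkResult:
    seed: int
    base_reports: dict[str, MetricReport]
    meta_report: MetricReport
    models: dict[str, SegmentationModel] = field(repr=False, default_factory=dict)
    meta: object = field(repr=False, default=None)
    split: object = field(repr=False, default=None)

    @property
    def best_base_f1(self) -> float:
        return max(r.f1 for r in self.base_reports.values())


def run_synthetic_benchmark(seed: int, n: int = 50, n_train: int = 40,
                            image_size: tuple[int, int] = (64, 64),
                            base_channels: int = 8, epochs: int = 30,
                            batch_size: int = 8,
                            auc_max_pixels: int | None = 100_000,
                            keep_models: bool = False) -> BenchmarkResult:
    """Train the four base models and the meta-model on one seeded synthetic
    dataset; return micro-averaged test reports for all five."""
    tree, render = default_configs(image_size, seed=seed)
    samples = make_synthetic_dataset(n, tree, render, seed=seed)
    split = split_dataset(samples, n_train)
    base_cfg = TrainConfig(learning_rate=1e-3, epochs=epochs,
                           batch_size=batch_size, seed=seed,
                           auc_max_pixels=auc_max_pixels)
    init_rng = np.random.default_rng(np.random.SeedSequence(seed))

    models: dict[str, SegmentationModel] = {}
    base_reports: dict[str, MetricReport] = {}
    for name in ens.CANONICAL_ORDER:
        cfg = dataclasses.replace(base_cfg,
                                  learning_rate=BASE_LEARNING_RATES[name])
        spec = ArchitectureSpec(name=name, input_size=image_size,
                                base_channels=base_channels,
                                seed=int(init_rng.integers(2 ** 31)))
        model, _ = train_segmentation_model(build_model(spec), split, cfg)
        models[name] = model
        base_reports[name] = evaluate_model(model, split.test,
                                            auc_max_pixels=auc_max_pixels,
                                            seed=seed)

    meta_cfg = dataclasses.replace(base_cfg, learning_rate=META_LEARNING_RATE)
    bases = [models[name] for name in ens.CANONICAL_ORDER]
    meta, _ = train_meta(bases, split, meta_cfg)
    meta_report = ens.evaluate_ensemble(bases, meta, split.test,
                                        auc_max_pixels=auc_max_pixels,
                                        seed=seed)
    result = BenchmarkResult(seed=seed, base_reports=base_reports,
                             meta_report=meta_report)
    if keep_models:
        result.models, result.meta, result.split = models, meta, split
    return result


def train_meta(bases, split, cfg):
    return ens.train_meta_model(bases, split, cfg,
                                model_order=list(ens.CANONICAL_ORDER))
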
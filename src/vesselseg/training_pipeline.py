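"""Training protocol and the end-to-end experiment runner.

The default protocol mirrors the reference study conditions: Adam with
learning rate 0.01, 500 epochs, batch size 32, ``steps_per_epoch =
max(1, floor(n_train / batch_size))``, validation at the end of every epoch
on the held-out set, and a checkpoint of the parameters at the (first)
epoch with the lowest validation BCE.  The validation set equals the test
set — no third split exists in the protocol — which is a known leakage
caveat; pass an explicit ``val`` set to :func:`train_segmentation_model`
for a cleaner setup.

Desk-scale runs (small widths, 64×64 synthetic images) are stabler at a
learning rate of 1e-3; both rates are plain config values recorded in the
experiment manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .architectures import (ArchitectureSpec, SegmentationModel, build_model,
                            save_checkpoint)
from .errors import ConfigurationError, TrainingDivergedError
from .io_datasets import (DatasetSplit, FundusSample, load_dataset,
                          split_dataset, write_probability_map,
                          write_split_manifest)
from .metrics import MetricReport, evaluate_model, reports_to_frame
from .nn import Adam, Tensor, bce_with_logits
from .synth_fundus import AugmentConfig, augment_sample, default_configs, \
    make_synthetic_dataset

__all__ = ["TrainConfig", "TrainingHistory", "train_segmentation_model",
           "run_experiment", "load_experiment_config"]


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 0.01
    epochs: int = 500
    batch_size: int = 32
    checkpoint_metric: str = "val_loss"
    seed: int = 0
    augment: AugmentConfig | None = None
    validate_each_epoch: bool = True
    auc_max_pixels: int | None = 200_000

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ConfigurationError(f"unsupported optimizer {self.optimizer!r}")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if self.epochs < 0 or self.batch_size < 1:
            raise ConfigurationError("epochs must be >= 0 and batch_size >= 1")
        if self.checkpoint_metric != "val_loss":
            raise ConfigurationError(
                f"unsupported checkpoint metric {self.checkpoint_metric!r}")

    def steps_per_epoch(self, n_train: int) -> int:
        return max(1, n_train // self.batch_size)


@dataclass
class TrainingHistory:
    """Per-epoch train/validation records plus the checkpoint bookmark.

    ``best_epoch`` is the FIRST epoch attaining the minimum validation BCE.
    """

    records: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("nan")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def _make_batch(samples: Sequence[FundusSample], idx: np.ndarray,
                augment: AugmentConfig | None,
                aug_rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    imgs, msks = [], []
    for i in idx:
        s = samples[int(i)]
        if augment is not None:
            s = augment_sample(s, augment, int(aug_rng.integers(2 ** 31)))
        imgs.append(s.image)
        msks.append(s.mask)
    x = np.stack(imgs).transpose(0, 3, 1, 2)
    y = np.stack(msks)[:, None, :, :]
    return x, y


def _val_record(model, val_samples, cfg: TrainConfig) -> dict:
    report = evaluate_model(model, val_samples, threshold=0.5,
                            auc_max_pixels=cfg.auc_max_pixels, seed=cfg.seed)
    return {"val_bce": report.loss, "val_acc": report.acc,
            "val_auc": report.auc, "val_f1": report.f1}


def train_segmentation_model(model: SegmentationModel, split: DatasetSplit,
                             cfg: TrainConfig,
                             val: Sequence[FundusSample] | None = None
                             ) -> tuple[SegmentationModel, TrainingHistory]:
    """Train ``model`` by seeded minibatch BCE minimisation; return it with
    the best-validation-loss parameters restored, plus the history.

    Validation defaults to ``split.test`` (the protocol's convention).  With
    ``cfg.validate_each_epoch=False`` no validation runs and the final
    parameters are kept.
    """
    if not split.train:
        raise ValueError("training set is empty")
    h, w = split.train[0].mask.shape
    if (h, w) != model.spec.input_size:
        raise ConfigurationError(
            f"sample size {(h, w)} does not match model input "
            f"{model.spec.input_size}")
    val_samples = list(val) if val is not None else list(split.test)
    history = TrainingHistory()
    if cfg.epochs == 0:
        return model, history

    ss = np.random.SeedSequence(cfg.seed)
    batch_rng, aug_rng = [np.random.default_rng(c) for c in ss.spawn(2)]
    opt = Adam(model.trainable_parameters(), lr=cfg.learning_rate)
    n = len(split.train)
    spe = cfg.steps_per_epoch(n)
    take = min(cfg.batch_size, n)
    best_state: dict | None = None

    for epoch in range(cfg.epochs):
        model.train(True)
        losses = []
        for step in range(spe):
            idx = batch_rng.choice(n, size=take, replace=False)
            x, y = _make_batch(split.train, idx, cfg.augment, aug_rng)
            logits = model.logits(Tensor(x))
            loss = bce_with_logits(logits, y)
            value = float(loss.data)
            if not np.isfinite(value):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, step {step}")
            model.net.zero_grad()
            loss.backward()
            opt.step()
            losses.append(value)
        record = {"epoch": epoch, "train_bce": float(np.mean(losses))}
        if cfg.validate_each_epoch and val_samples:
            record.update(_val_record(model, val_samples, cfg))
            if (history.best_epoch < 0
                    or record["val_bce"] < history.best_val_loss):
                history.best_epoch = epoch
                history.best_val_loss = record["val_bce"]
                best_state = model.net.state_dict()
        history.records.append(record)

    if best_state is not None:
        model.net.load_state_dict(best_state)
    else:
        history.best_epoch = cfg.epochs - 1
        history.best_val_loss = history.records[-1].get("val_bce", float("nan"))
    return model, history


# ---------------------------------------------------------------------------
# experiment runner
# ---------------------------------------------------------------------------

def load_experiment_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    _validate_experiment_config(cfg)
    return cfg


_REQUIRED_KEYS = ("data", "architectures", "training")


def _validate_experiment_config(cfg: dict) -> None:
    missing = [k for k in _REQUIRED_KEYS if k not in cfg]
    if missing:
        raise ConfigurationError(f"config missing keys: {missing}")
    data = cfg["data"]
    source = data.get("source", "synthetic")
    if source not in ("synthetic", "real"):
        raise ConfigurationError(f"data.source must be synthetic|real, got {source!r}")
    if source == "real":
        bad = [k for k in ("images_dir", "masks_dir") if k not in data]
        if bad:
            raise ConfigurationError(f"real data config missing keys: {bad}")
    if not isinstance(cfg["architectures"], list) or not cfg["architectures"]:
        raise ConfigurationError("architectures must be a non-empty list")


def _load_samples(data_cfg: dict, seed: int) -> list[FundusSample]:
    size = tuple(data_cfg.get("image_size", (256, 256)))
    if data_cfg.get("source", "synthetic") == "synthetic":
        tree, render = default_configs(size, seed=seed)
        return make_synthetic_dataset(int(data_cfg.get("n", 40)),
                                      tree, render, seed=seed)
    return load_dataset(data_cfg["images_dir"], data_cfg["masks_dir"], size)


def _train_config_from(cfg: dict, seed: int) -> TrainConfig:
    t = dict(cfg.get("training", {}))
    aug = t.pop("augment", None)
    if isinstance(aug, dict):
        aug = AugmentConfig(**aug)
    t.setdefault("seed", seed)
    return TrainConfig(augment=aug, **t)


def run_experiment(config_path, seed: int | None = None,
                   out_dir=None) -> Path:
    """Run the full pipeline from one YAML config: train the four base
    models, train the meta-model on the frozen bases, evaluate everything
    on the test split, and write histories, a benchmark-style report CSV,
    predicted masks, optional ablation CSV, and a manifest.

    Returns the experiment directory.
    """
    from . import ensemble as ens  # local import: ensemble depends on us

    cfg = load_experiment_config(config_path)
    seed = int(cfg.get("seed", 0)) if seed is None else int(seed)
    out = Path(out_dir if out_dir is not None else cfg.get("output_dir", "experiment"))
    for sub in ("checkpoints", "histories", "predictions"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    data_cfg = cfg["data"]
    samples = _load_samples(data_cfg, seed)
    n_train = int(data_cfg.get("n_train", max(1, len(samples) // 2)))
    split = split_dataset(samples, n_train, seed=seed,
                          shuffle=bool(data_cfg.get("shuffle", False)))
    write_split_manifest(split, out / "split.csv")

    size = split.train[0].mask.shape
    train_cfg = _train_config_from(cfg, seed)
    arch_seed_rng = np.random.default_rng(np.random.SeedSequence(seed))
    arch_seeds = {}

    models: dict[str, SegmentationModel] = {}
    reports: dict[str, MetricReport] = {}
    for arch_cfg in cfg["architectures"]:
        arch_cfg = dict(arch_cfg)
        arch_cfg.setdefault("input_size", list(size))
        init_seed = int(arch_seed_rng.integers(2 ** 31))
        arch_cfg.setdefault("seed", init_seed)
        spec = ArchitectureSpec.from_dict(arch_cfg)
        arch_seeds[spec.name] = spec.seed
        model = build_model(spec)
        model, history = train_segmentation_model(model, split, train_cfg)
        models[spec.name] = model
        history.to_dataframe().to_csv(out / "histories" / f"{spec.name}.csv",
                                      index=False, float_format="%.6f")
        save_checkpoint(model, out / "checkpoints" / f"{spec.name}.npz")
        reports[spec.name] = evaluate_model(
            model, split.test, auc_max_pixels=train_cfg.auc_max_pixels,
            seed=seed)

    ens_cfg = dict(cfg.get("ensemble", {}))
    meta_train_cfg = dataclasses.replace(
        train_cfg, epochs=int(ens_cfg.get("epochs", train_cfg.epochs)),
        augment=None)
    order = [name for name in ens.CANONICAL_ORDER if name in models]
    order += [name for name in models if name not in order]
    bases = [models[name] for name in order]
    meta, meta_history = ens.train_meta_model(
        bases, split, meta_train_cfg,
        hidden_filters=int(ens_cfg.get("hidden_filters", 64)),
        model_order=order)
    meta_history.to_dataframe().to_csv(out / "histories" / "meta.csv",
                                       index=False, float_format="%.6f")
    ens.save_meta_checkpoint(meta, out / "checkpoints" / "meta.npz")

    meta_maps = [predict_one(bases, meta, s.image) for s in split.test]
    reports["Meta-model"] = ens.evaluate_ensemble(
        bases, meta, split.test, auc_max_pixels=train_cfg.auc_max_pixels,
        seed=seed)
    for s, pmap in zip(split.test, meta_maps):
        write_probability_map(pmap[..., 0], out / "predictions" / f"{s.id}.png")

    frame = reports_to_frame(reports)
    frame.to_csv(out / "report.csv", float_format="%.6f")

    if ens_cfg.get("ablation", False):
        table = ens.run_ablation({n: models[n] for n in order}, None, split,
                                 meta_train_cfg,
                                 hidden_filters=int(ens_cfg.get("hidden_filters", 64)))
        table.to_csv(out / "ablation.csv", index=False, float_format="%.6f")

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "architecture_init_seeds": arch_seeds,
        "model_order": order,
        "config": cfg,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def predict_one(bases, meta, image: np.ndarray) -> np.ndarray:
    from . import ensemble as ens
    return ens.predict_ensemble(bases, meta, image)
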
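"""Stacking ensemble: fuse base-model probability maps with a meta-model.

For an input image x each base model k produces a probability map P_k(x).
The maps are concatenated channel-wise into a feature tensor
Z(x) = [P_1(x), ..., P_K(x)], and a small convolutional meta-model g is
trained with pixel-wise binary cross-entropy against the ground truth to
produce the final segmentation P_final(x) = g(Z(x)).  The meta-model is a
3×3 convolution with 64 filters and ReLU followed by a 1×1 convolution and
sigmoid — enough capacity to learn a spatially aware, non-linear weighting
of the base models' complementary strengths.

Base models are frozen throughout: their parameters are bit-identical
before and after meta training.  The meta-model is fit on base predictions
over the *training* split (no out-of-fold stacking), which carries an
overfitting risk when the bases have memorised the training set; see the
methods note.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit
import pandas as pd

from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor
from .architectures import SegmentationModel
from .errors import ConfigurationError, DimensionMismatchError
from .io_datasets import DatasetSplit, FundusSample
from .metrics import (MetricReport, REPORT_COLUMNS,
                      evaluate_probability_maps)
from .training_pipeline import TrainConfig, TrainingHistory

__all__ = [
    "StackedPredictions", "MetaModel", "stack_predictions",
    "build_meta_model", "train_meta_model", "predict_ensemble",
    "evaluate_ensemble", "run_ablation", "CANONICAL_ORDER",
    "DEFAULT_SUBSETS", "save_meta_checkpoint", "load_meta_checkpoint",
]

CANONICAL_ORDER = ("unet", "resnet50_seg", "ctu_net", "unet_resnet_backbone")

# the ten ablation combinations: 5 pairs, 4 triples, the full quadruple
DEFAULT_SUBSETS: tuple[tuple[str, ...], ...] = (
    ("unet", "resnet50_seg"),
    ("resnet50_seg", "ctu_net"),
    ("resnet50_seg", "unet_resnet_backbone"),
    ("unet", "ctu_net"),
    ("unet", "unet_resnet_backbone"),
    ("resnet50_seg", "unet", "ctu_net"),
    ("resnet50_seg", "unet", "unet_resnet_backbone"),
    ("resnet50_seg", "ctu_net", "unet_resnet_backbone"),
    ("unet", "ctu_net", "unet_resnet_backbone"),
    ("unet", "resnet50_seg", "ctu_net", "unet_resnet_backbone"),
)


@dataclass
class StackedPredictions:
    """H×W×K channel concatenation of K base-model probability maps; the
    channel order is part of the identity and recorded in ``model_order``."""

    tensor: np.ndarray
    model_order: tuple[str, ...]

    def __post_init__(self):
        if self.tensor.ndim != 3:
            raise ValueError(f"expected H×W×K tensor, got {self.tensor.shape}")
        if self.tensor.shape[2] != len(self.model_order):
            raise ValueError("model_order length must equal channel count")

    @property
    def k(self) -> int:
        return self.tensor.shape[2]

    def channel(self, name: str) -> np.ndarray:
        return self.tensor[..., self.model_order.index(name)]


def stack_predictions(maps: Sequence[np.ndarray],
                      model_order: Sequence[str] | None = None
                      ) -> StackedPredictions:
    """Concatenate probability maps channel-wise, preserving order and
    values exactly."""
    maps = [np.asarray(m, dtype=np.float64) for m in maps]
    if len(maps) < 2:
        raise ValueError(f"stacking requires >= 2 maps, got {len(maps)}")
    squeezed = []
    for m in maps:
        if m.ndim == 3 and m.shape[-1] == 1:
            m = m[..., 0]
        if m.ndim != 2:
            raise DimensionMismatchError(f"maps must be H×W, got {m.shape}")
        squeezed.append(m)
    shapes = {m.shape for m in squeezed}
    if len(shapes) > 1:
        raise DimensionMismatchError(f"map shapes differ: {sorted(shapes)}")
    if model_order is None:
        model_order = tuple(f"model_{i}" for i in range(len(maps)))
    return StackedPredictions(tensor=np.stack(squeezed, axis=-1),
                              model_order=tuple(model_order))


class MetaModel(nn.Module):
    """g: B×H×W×K stacked base predictions -> B×H×W×1 fused probabilities.

    Architecture: 3×3 conv (``hidden_filters`` filters, same padding, ReLU,
    no bias) then a 1×1 conv with bias, sigmoid on output.
    """

    def __init__(self, k_inputs: int, hidden_filters: int = 64,
                 seed: int = 0):
        super().__init__()
        if k_inputs < 2:
            raise ValueError(f"k_inputs must be >= 2, got {k_inputs}")
        rng = np.random.default_rng(seed)
        self.k_inputs = k_inputs
        self.hidden_filters = hidden_filters
        self.seed = seed
        self.conv1 = nn.Conv2d(k_inputs, hidden_filters, 3, rng, padding=1,
                               bias=False)
        self.conv2 = nn.Conv2d(hidden_filters, 1, 1, rng)

    def forward(self, x: Tensor) -> Tensor:       # logits, NCHW
        return self.conv2(ag.relu(self.conv1(x)))

    def predict(self, stacked: np.ndarray) -> np.ndarray:
        """B×H×W×K (or H×W×K) -> B×H×W×1 probabilities, inference mode."""
        stacked = np.asarray(stacked, dtype=np.float64)
        single = stacked.ndim == 3
        if single:
            stacked = stacked[None]
        if stacked.shape[-1] != self.k_inputs:
            raise ConfigurationError(
                f"stacked tensor has {stacked.shape[-1]} channels, "
                f"meta-model expects {self.k_inputs}")
        with ag.no_grad():
            z = self.forward(Tensor(stacked.transpose(0, 3, 1, 2)))
        probs = expit(z.data.astype(np.float64))
        probs = probs.transpose(0, 2, 3, 1)
        return probs[0] if single else probs


def build_meta_model(k_inputs: int, hidden_filters: int = 64,
                     seed: int = 0) -> MetaModel:
    return MetaModel(k_inputs, hidden_filters, seed)


def _base_stack(base_models: Sequence[SegmentationModel],
                samples: Sequence[FundusSample]) -> np.ndarray:
    """Inference-mode base predictions stacked to (N, K, H, W)."""
    batch = np.stack([s.image for s in samples])
    preds = [m.predict(batch)[..., 0] for m in base_models]   # K × (N,H,W)
    return np.stack(preds, axis=1)


def _check_bases(base_models: Sequence[SegmentationModel]) -> None:
    sizes = {m.spec.input_size for m in base_models}
    if len(sizes) > 1:
        raise ConfigurationError(f"base models disagree on input size: {sizes}")


def train_meta_model(base_models: Sequence[SegmentationModel],
                     split: DatasetSplit, cfg: TrainConfig,
                     hidden_filters: int = 64,
                     model_order: Sequence[str] | None = None
                     ) -> tuple[MetaModel, TrainingHistory]:
    """Fit the meta-model on frozen base predictions with pixel-wise BCE.

    Base predictions over train and validation sets are computed once in
    inference mode (the bases are never updated); only meta parameters
    receive gradients.  Checkpointing follows the shared protocol: the
    first epoch with minimal validation BCE wins.
    """
    if not split.train:
        raise ValueError("training set is empty")
    _check_bases(base_models)
    k = len(base_models)
    meta = build_meta_model(k, hidden_filters, seed=cfg.seed)
    history = TrainingHistory()
    if cfg.epochs == 0:
        return meta, history

    train_z = _base_stack(base_models, split.train)           # N,K,H,W
    train_y = np.stack([s.mask for s in split.train])[:, None]
    val_z = val_y = None
    if cfg.validate_each_epoch and split.test:
        val_z = _base_stack(base_models, split.test)
        val_y = np.stack([s.mask for s in split.test])[:, None]

    from .nn import Adam, bce_with_logits  # local to avoid cycle at import
    from .metrics import bce as bce_metric, confusion, ratio_metrics, roc_auc

    ss = np.random.SeedSequence(cfg.seed)
    batch_rng = np.random.default_rng(ss.spawn(1)[0])
    opt = Adam(meta.parameters(), lr=cfg.learning_rate)
    n = train_z.shape[0]
    spe = cfg.steps_per_epoch(n)
    take = min(cfg.batch_size, n)
    best_state = None

    for epoch in range(cfg.epochs):
        meta.train(True)
        losses = []
        for _ in range(spe):
            idx = batch_rng.choice(n, size=take, replace=False)
            logits = meta.forward(Tensor(train_z[idx]))
            loss = bce_with_logits(logits, train_y[idx])
            meta.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        record = {"epoch": epoch, "train_bce": float(np.mean(losses))}
        if val_z is not None:
            with ag.no_grad():
                zlogits = meta.forward(Tensor(val_z)).data.astype(np.float64)
            probs = expit(zlogits)
            record["val_bce"] = bce_metric(probs, val_y)
            r = ratio_metrics(confusion(probs, val_y, 0.5))
            record["val_acc"], record["val_f1"] = r["acc"], r["f1"]
            record["val_auc"] = roc_auc(probs, val_y,
                                        max_pixels=cfg.auc_max_pixels,
                                        seed=cfg.seed)
            if history.best_epoch < 0 or record["val_bce"] < history.best_val_loss:
                history.best_epoch = epoch
                history.best_val_loss = record["val_bce"]
                best_state = meta.state_dict()
        history.records.append(record)

    if best_state is not None:
        meta.load_state_dict(best_state)
    else:
        history.best_epoch = cfg.epochs - 1
        history.best_val_loss = history.records[-1].get("val_bce", float("nan"))
    if model_order is not None:
        meta.model_order = tuple(model_order)
    return meta, history


def predict_ensemble(base_models: Sequence[SegmentationModel],
                     meta: MetaModel, image: np.ndarray) -> np.ndarray:
    """P_final = g(Z(x)) for one H×W×3 image; returns H×W×1 probabilities."""
    if len(base_models) != meta.k_inputs:
        raise ConfigurationError(
            f"{len(base_models)} base models but meta-model expects "
            f"{meta.k_inputs} input channels")
    _check_bases(base_models)
    image = np.asarray(image, dtype=np.float64)
    batch = image[None]
    preds = [m.predict(batch)[0, ..., 0] for m in base_models]
    stacked = stack_predictions(preds)
    return meta.predict(stacked.tensor)


def evaluate_ensemble(base_models: Sequence[SegmentationModel],
                      meta: MetaModel, samples: Sequence[FundusSample],
                      threshold: float = 0.5,
                      auc_max_pixels: int | None = None,
                      seed: int = 0) -> MetricReport:
    z = _base_stack(base_models, samples).transpose(0, 2, 3, 1)  # N,H,W,K
    maps = [meta.predict(z[i])[..., 0] for i in range(z.shape[0])]
    return evaluate_probability_maps(maps, samples, threshold=threshold,
                                     auc_max_pixels=auc_max_pixels, seed=seed)


def _subset_seed(names: Sequence[str], base_seed: int) -> int:
    """Deterministic per-subset seed derived from the subset's content, so
    identical subsets reproduce identical rows regardless of position."""
    return (zlib.crc32(",".join(names).encode()) ^ base_seed) % (2 ** 31)


def run_ablation(base_models: dict[str, SegmentationModel],
                 subsets: Sequence[Sequence[str]] | None,
                 split: DatasetSplit, cfg: TrainConfig,
                 hidden_filters: int = 64) -> pd.DataFrame:
    """Train one meta-model per base-model subset and tabulate test metrics.

    ``subsets=None`` uses the default ten combinations (5 pairs, 4 triples,
    1 quadruple).  Each row gets a fresh seeded meta-model; the seed is a
    function of the subset's names, so duplicated subsets give identical
    rows.
    """
    if subsets is None:
        subsets = [s for s in DEFAULT_SUBSETS
                   if all(name in base_models for name in s)]
    rows = []
    for subset in subsets:
        unknown = [name for name in subset if name not in base_models]
        if unknown:
            raise ValueError(f"unknown model names in subset: {unknown}")
        if len(subset) < 2:
            raise ValueError(f"subset {subset} has fewer than 2 models")
        sub_cfg = dataclasses.replace(cfg, seed=_subset_seed(subset, cfg.seed))
        bases = [base_models[name] for name in subset]
        meta, _ = train_meta_model(bases, split, sub_cfg,
                                   hidden_filters=hidden_filters,
                                   model_order=subset)
        report = evaluate_ensemble(bases, meta, split.test,
                                   auc_max_pixels=cfg.auc_max_pixels,
                                   seed=sub_cfg.seed)
        label = ("All architectures" if set(subset) == set(base_models)
                 and len(subset) == len(base_models) else " + ".join(subset))
        rows.append({"Meta-Model": label, **report.as_row()})
    return pd.DataFrame(rows, columns=["Meta-Model", *REPORT_COLUMNS])


def save_meta_checkpoint(meta: MetaModel, path) -> None:
    state = meta.state_dict()
    header = {"k_inputs": meta.k_inputs, "hidden_filters": meta.hidden_filters,
              "seed": meta.seed,
              "model_order": list(getattr(meta, "model_order", ()))}
    state["__meta__"] = np.frombuffer(json.dumps(header).encode(),
                                      dtype=np.uint8)
    np.savez(path, **state)


def load_meta_checkpoint(path) -> MetaModel:
    archive = np.load(path)
    header = json.loads(archive["__meta__"].tobytes().decode())
    meta = MetaModel(header["k_inputs"], header["hidden_filters"],
                     header["seed"])
    meta.load_state_dict({k: archive[k] for k in archive.files
                          if k != "__meta__"})
    if header["model_order"]:
        meta.model_order = tuple(header["model_order"])
    return meta
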
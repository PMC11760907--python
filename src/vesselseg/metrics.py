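"""Pixel-wise binary segmentation metrics.

Implements the evaluation suite used throughout the package: confusion
counts at a threshold, the derived ratio metrics

    ACC = (TP+TN)/(TP+TN+FP+FN)      SN = TP/(TP+FN)
    SP  = TN/(TN+FP)                 F1 = 2·Prec·SN/(Prec+SN)

pixel-wise binary cross-entropy

    BCE = -(1/N) Σ [ y·log(ŷ) + (1-y)·log(1-ŷ) ]

and the rank-based ROC AUC (the Mann–Whitney statistic: the probability
that a random vessel pixel outscores a random background pixel, ties
counted one half).  Reports are micro-averaged: pixels are pooled across
all evaluated images before any ratio is formed, the dominant convention
for vessel-segmentation benchmarks.

Undefined ratios (0/0) are returned as 0.0 and flagged in the report
instead of raising, so batch evaluation of degenerate predictions never
crashes; an AUC on single-class truth, by contrast, is an error because no
value is defensible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DimensionMismatchError, UndefinedMetricError
from .io_datasets import FundusSample

__all__ = [
    "ConfusionCounts", "MetricReport", "confusion", "ratio_metrics",
    "bce", "roc_auc", "evaluate_model", "evaluate_probability_maps",
    "reports_to_frame", "REPORT_COLUMNS",
]

EPS = 1e-7
REPORT_COLUMNS = ["Loss", "Acc", "SN", "SP", "AUC", "F1-Score"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass
class MetricReport:
    """One model's scores on one evaluation set (a benchmark-table row)."""

    loss: float
    acc: float
    sn: float
    sp: float
    auc: float
    f1: float
    threshold: float = 0.5
    n_pixels: int = 0
    undefined: tuple[str, ...] = field(default_factory=tuple)

    def as_row(self) -> dict[str, float]:
        return {"Loss": self.loss, "Acc": self.acc, "SN": self.sn,
                "SP": self.sp, "AUC": self.auc, "F1-Score": self.f1}


def _check_shapes(pred: np.ndarray, truth: np.ndarray) -> None:
    if pred.shape != truth.shape:
        raise DimensionMismatchError(
            f"prediction shape {pred.shape} != truth shape {truth.shape}")


def confusion(pred_prob: np.ndarray, truth: np.ndarray,
              threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts of ``pred_prob >= threshold`` against binary truth."""
    pred_prob = np.asarray(pred_prob, dtype=np.float64)
    truth = np.asarray(truth)
    _check_shapes(pred_prob, truth)
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    pos = pred_prob >= threshold
    t = truth.astype(bool)
    tp = int(np.count_nonzero(pos & t))
    fp = int(np.count_nonzero(pos & ~t))
    fn = int(np.count_nonzero(~pos & t))
    tn = int(np.count_nonzero(~pos & ~t))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _safe_div(num: float, den: float, name: str,
              undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def ratio_metrics(c: ConfusionCounts) -> dict:
    """ACC, SN, SP, precision and F1 from confusion counts.

    0/0 ratios are defined as 0.0 and listed under the ``"undefined"`` key.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics from empty counts")
    undefined: list[str] = []
    acc = (c.tp + c.tn) / c.total
    sn = _safe_div(c.tp, c.tp + c.fn, "sn", undefined)
    sp = _safe_div(c.tn, c.tn + c.fp, "sp", undefined)
    precision = _safe_div(c.tp, c.tp + c.fp, "precision", undefined)
    f1 = _safe_div(2 * precision * sn, precision + sn, "f1", undefined)
    return {"acc": acc, "sn": sn, "sp": sp, "precision": precision,
            "f1": f1, "undefined": tuple(undefined)}


def bce(pred_prob: np.ndarray, truth: np.ndarray) -> float:
    """Mean binary cross-entropy; predictions clipped to [1e-7, 1-1e-7]."""
    pred_prob = np.asarray(pred_prob, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    _check_shapes(pred_prob, truth)
    p = np.clip(pred_prob, EPS, 1.0 - EPS)
    return float(-(truth * np.log(p) + (1.0 - truth) * np.log1p(-p)).mean())


def roc_auc(pred_prob: np.ndarray, truth: np.ndarray,
            max_pixels: int | None = None, seed: int = 0) -> float:
    """Rank-based ROC AUC (Mann–Whitney U / (P·N), average-tie ranks).

    ``max_pixels`` evaluates on a seeded uniform pixel subsample, useful
    when pooling millions of pixels.
    """
    pred = np.asarray(pred_prob, dtype=np.float64).ravel()
    y = np.asarray(truth).ravel().astype(bool)
    _check_shapes(pred, y)
    if max_pixels is not None and pred.size > max_pixels:
        idx = np.random.default_rng(seed).choice(pred.size, size=max_pixels,
                                                 replace=False)
        pred, y = pred[idx], y[idx]
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            "ROC AUC undefined: truth contains a single class")
    ranks = rankdata(pred)  # average ranks resolve ties as 1/2
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _pool(prob_maps: Sequence[np.ndarray],
          samples: Sequence[FundusSample]) -> tuple[np.ndarray, np.ndarray]:
    preds, truths = [], []
    for p, s in zip(prob_maps, samples):
        p = np.asarray(p, dtype=np.float64)
        if p.ndim == 3 and p.shape[-1] == 1:
            p = p[..., 0]
        _check_shapes(p, s.mask)
        preds.append(p.ravel())
        truths.append(s.mask.ravel())
    return np.concatenate(preds), np.concatenate(truths)


def evaluate_probability_maps(prob_maps: Sequence[np.ndarray],
                              samples: Sequence[FundusSample],
                              threshold: float = 0.5,
                              auc_max_pixels: int | None = None,
                              seed: int = 0) -> MetricReport:
    """Micro-averaged report over the pooled pixels of all samples."""
    if len(samples) == 0:
        raise ValueError("samples must be non-empty")
    if len(prob_maps) != len(samples):
        raise ValueError("one probability map per sample required")
    pred, truth = _pool(prob_maps, samples)
    c = confusion(pred, truth, threshold)
    r = ratio_metrics(c)
    auc = roc_auc(pred, truth, max_pixels=auc_max_pixels, seed=seed)
    return MetricReport(loss=bce(pred, truth), acc=r["acc"], sn=r["sn"],
                        sp=r["sp"], auc=auc, f1=r["f1"],
                        threshold=threshold, n_pixels=int(pred.size),
                        undefined=r["undefined"])


def evaluate_model(model_or_maps, samples: Sequence[FundusSample],
                   threshold: float = 0.5,
                   auc_max_pixels: int | None = None,
                   seed: int = 0) -> MetricReport:
    """Evaluate a segmentation model (anything with ``predict``) or a
    pre-computed list of probability maps on ``samples``."""
    if hasattr(model_or_maps, "predict"):
        batch = np.stack([s.image for s in samples])
        maps = list(model_or_maps.predict(batch)[..., 0])
    else:
        maps = list(model_or_maps)
    return evaluate_probability_maps(maps, samples, threshold=threshold,
                                     auc_max_pixels=auc_max_pixels, seed=seed)


def reports_to_frame(reports: dict[str, MetricReport]) -> pd.DataFrame:
    """Assemble named reports into a benchmark-style table
    (rows = models, columns = Loss/Acc/SN/SP/AUC/F1-Score)."""
    rows = {name: rep.as_row() for name, rep in reports.items()}
    frame = pd.DataFrame.from_dict(rows, orient="index")[REPORT_COLUMNS]
    frame.index.name = "Model"
    return frame
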
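"""Reading fundus image/mask pairs and building train/test splits.

Datasets follow the DRIVE/STARE layout: one directory of colour fundus
photographs and one directory of binary vessel annotations, paired by a
shared filename stem (DRIVE pairs ``21_training.tif`` with
``21_manual1.gif`` through the leading numeric token).  All rasters —
TIFF, PNG, GIF, PPM, JPEG — go through one generic reader; images are
rescaled to [0, 1] floats, masks are binarised.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize

from .errors import DimensionMismatchError

__all__ = [
    "FundusSample", "DatasetSplit", "load_pair", "load_dataset",
    "split_dataset", "write_probability_map", "read_probability_map",
    "write_split_manifest",
]


@dataclass
class FundusSample:
    """One fundus image with its binary vessel annotation."""

    id: str
    image: np.ndarray          # H×W×3 floats in [0, 1]
    mask: np.ndarray           # H×W values in {0, 1}
    source: Literal["real", "synthetic"] = "real"

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mask = np.asarray(self.mask)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError(f"image must be H×W×3, got {self.image.shape}")
        if self.image.shape[:2] != self.mask.shape:
            raise DimensionMismatchError(
                f"image {self.image.shape[:2]} vs mask {self.mask.shape}")
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask must be binary, found values {vals[:5]}")
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("image values must lie in [0, 1]")


@dataclass
class DatasetSplit:
    train: list[FundusSample] = field(default_factory=list)
    test: list[FundusSample] = field(default_factory=list)

    def __post_init__(self):
        ids_tr = {s.id for s in self.train}
        ids_te = {s.id for s in self.test}
        if ids_tr & ids_te:
            raise ValueError(f"train/test ids overlap: {sorted(ids_tr & ids_te)[:3]}")


def _read_raster(path: Path) -> np.ndarray:
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path named
        raise IOError(f"cannot read raster file {path}: {exc}") from exc
    return np.asarray(arr)


def _to_unit_float(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    arr = arr.astype(np.float64)
    if arr.max() > 1.0:
        arr = arr / 255.0
    return np.clip(arr, 0.0, 1.0)


def load_pair(image_path, mask_path, target_size: tuple[int, int]) -> FundusSample:
    """Load one image/mask pair, resize to ``target_size`` (H, W).

    The image is resized with bilinear interpolation; the mask with
    nearest-neighbour and re-binarised at 0.5 so anti-aliased source files
    cannot introduce intermediate values.
    """
    image_path, mask_path = Path(image_path), Path(mask_path)
    img = _read_raster(image_path)
    msk = _read_raster(mask_path)

    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[2] > 3:
        img = img[:, :, :3]
    if msk.ndim == 3:
        msk = msk.max(axis=2)
    if img.shape[:2] != msk.shape:
        raise DimensionMismatchError(
            f"{image_path.name} is {img.shape[:2]} but "
            f"{mask_path.name} is {msk.shape}")

    img = _to_unit_float(img)
    msk = (_to_unit_float(msk) >= 0.5).astype(np.uint8)

    h, w = target_size
    if (h, w) != img.shape[:2]:
        img = resize(img, (h, w), order=1, anti_aliasing=False,
                     preserve_range=True)
        msk = resize(msk.astype(np.float64), (h, w), order=0,
                     anti_aliasing=False, preserve_range=True)
        msk = (msk >= 0.5).astype(np.uint8)
    img = np.clip(img, 0.0, 1.0)
    return FundusSample(id=image_path.stem, image=img, mask=msk)


_STEM_KEY = re.compile(r"^(\d+)")


def _pair_key(stem: str) -> str:
    m = _STEM_KEY.match(stem)
    return m.group(1) if m else stem


def load_dataset(images_dir, masks_dir, target_size: tuple[int, int],
                 extensions: Sequence[str] = (".tif", ".tiff", ".png",
                                              ".gif", ".ppm", ".jpg",
                                              ".jpeg")) -> list[FundusSample]:
    """Load every image in ``images_dir`` paired with the mask in
    ``masks_dir`` whose stem shares its leading numeric token (or full stem)."""
    images_dir, masks_dir = Path(images_dir), Path(masks_dir)
    masks = {}
    for p in sorted(masks_dir.iterdir()):
        if p.suffix.lower() in extensions:
            masks[_pair_key(p.stem)] = p
    samples = []
    for p in sorted(images_dir.iterdir()):
        if p.suffix.lower() not in extensions:
            continue
        key = _pair_key(p.stem)
        if key not in masks:
            raise FileNotFoundError(
                f"no mask for image {p.name} (pair key {key!r}) in {masks_dir}")
        samples.append(load_pair(p, masks[key], target_size))
    if not samples:
        raise FileNotFoundError(f"no raster images found in {images_dir}")
    return samples


def split_dataset(samples: Sequence[FundusSample], n_train: int,
                  seed: int = 0, shuffle: bool = False) -> DatasetSplit:
    """Partition samples into ``n_train`` training and the rest for testing.

    With ``shuffle=False`` the input order is preserved (the fixed DRIVE
    20/20 convention); with ``shuffle=True`` the permutation is drawn from
    ``seed`` and is reproducible.
    """
    if not 0 < n_train < len(samples):
        raise ValueError(
            f"n_train must be in (0, {len(samples)}), got {n_train}")
    order = list(samples)
    if shuffle:
        rng = np.random.default_rng(seed)
        order = [order[i] for i in rng.permutation(len(order))]
    return DatasetSplit(train=order[:n_train], test=order[n_train:])


def write_probability_map(prob: np.ndarray, path,
                          threshold: float | None = None) -> None:
    """Write a per-pixel vessel probability map as an 8-bit PNG.

    ``threshold=None`` stores ``round(255 * p)`` grayscale; with a threshold
    ``t`` the output is binary (255 where ``p >= t``).
    """
    prob = np.asarray(prob, dtype=np.float64)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    if threshold is None:
        out = np.rint(prob * 255.0).astype(np.uint8)
    else:
        out = np.where(prob >= threshold, 255, 0).astype(np.uint8)
    path = Path(path)
    try:
        iio.imwrite(path, out)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot write probability map to {path}: {exc}") from exc


def read_probability_map(path) -> np.ndarray:
    """Inverse of :func:`write_probability_map` without a threshold."""
    arr = _read_raster(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr.astype(np.float64) / 255.0


def write_split_manifest(split: DatasetSplit, path) -> None:
    """Two-column CSV (id, partition) recording a split."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "partition"])
        for s in split.train:
            w.writerow([s.id, "train"])
        for s in split.test:
            w.writerow([s.id, "test"])
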
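"""Synthetic fundus-like images with branching vessel trees.

Real fundus photographs show a roughly circular field of view (FOV) on a
dark border, a branching tree of dark vessels whose caliber shrinks from
trunk to distal twigs, a reddish low-contrast background with a smooth
illumination gradient, and sensor noise.  This module generates images with
exactly those statistics plus pixel-perfect ground-truth masks, so the
whole segmentation pipeline is trainable and testable without downloading
clinical data.

The generator is not photorealistic — there is no optic disc, fovea or
pathology — it reproduces only the structure that makes vessel segmentation
hard: thin, low-contrast curvilinear foreground on textured background.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk
from skimage.transform import AffineTransform, warp

from .errors import DimensionMismatchError
from .io_datasets import FundusSample

__all__ = [
    "VesselTreeConfig", "FundusRenderConfig", "AugmentConfig",
    "generate_vessel_mask", "render_fundus_image", "augment_sample",
    "make_synthetic_dataset", "default_configs",
]


@dataclass(frozen=True)
class VesselTreeConfig:
    """Parameters of the recursive random-walk vessel tree.

    Each root starts on the FOV boundary heading inward.  A walk advances
    ``step_len`` pixels per depth level, perturbing its heading by
    ``Normal(0, angle_jitter_sd)``; with probability ``branch_prob`` it
    spawns a child rotated by ±(20–50°) whose width is the parent's times
    ``width_decay``.  Walks stop at ``max_depth``, below ``min_width``, or
    on leaving the image.
    """

    image_size: tuple[int, int] = (256, 256)
    n_roots: int = 5
    max_depth: int = 10
    branch_prob: float = 0.4
    step_len: float = 8.0
    angle_jitter_sd: float = 0.3
    root_width: float = 5.0
    width_decay: float = 0.75
    min_width: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size
        if h <= 0 or w <= 0:
            raise ValueError(f"image_size must be positive, got {self.image_size}")
        if self.n_roots < 1:
            raise ValueError("n_roots must be >= 1")
        if not 0 <= self.branch_prob <= 1:
            raise ValueError("branch_prob must lie in [0, 1]")
        if self.step_len <= 0 or self.root_width <= 0 or self.min_width <= 0:
            raise ValueError("step_len, root_width, min_width must be positive")
        if self.min_width > self.root_width:
            raise ValueError("min_width must not exceed root_width")
        if not 0 < self.width_decay <= 1:
            raise ValueError("width_decay must lie in (0, 1]")


@dataclass(frozen=True)
class FundusRenderConfig:
    """Photometry of the rendered image.

    Inside the FOV circle the intensity is ``background_level`` plus a
    linear illumination gradient, minus ``vessel_contrast`` times the
    blurred vessel mask, plus Gaussian noise; outside the FOV pixels are 0.
    The red channel carries the full intensity, green and blue are scaled
    down to mimic the fundus tint.
    """

    fov_radius_frac: float = 0.95
    background_level: float = 0.75
    vessel_contrast: float = 0.45
    noise_sd: float = 0.03
    illumination_gradient: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.fov_radius_frac <= 1:
            raise ValueError("fov_radius_frac must lie in (0, 1]")
        if self.vessel_contrast < 0 or self.noise_sd < 0:
            raise ValueError("vessel_contrast and noise_sd must be >= 0")
        if self.illumination_gradient < 0:
            raise ValueError("illumination_gradient must be >= 0")


@dataclass(frozen=True)
class AugmentConfig:
    """Train-time geometric augmentation policy: random rotations up to
    15°, width/height shifts up to 10%, zoom up to ±20%, horizontal flip."""

    max_rotation_deg: float = 15.0
    shift_frac: float = 0.10
    max_zoom_frac: float = 0.20
    hflip: bool = True
    seed: int = 0


def _stroke(mask: np.ndarray, p0: np.ndarray, p1: np.ndarray,
            width: float) -> None:
    """Rasterise a straight stroke by stamping disks of radius width/2."""
    length = float(np.hypot(*(p1 - p0)))
    n = max(2, int(np.ceil(length / 0.5)) + 1)
    r = max(width / 2.0, 0.5)
    for t in np.linspace(0.0, 1.0, n):
        c = p0 + t * (p1 - p0)
        rr, cc = disk((c[0], c[1]), r, shape=mask.shape)
        mask[rr, cc] = 1


def generate_vessel_mask(cfg: VesselTreeConfig) -> np.ndarray:
    """Draw a branching vessel tree; returns an H×W uint8 mask in {0, 1}."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    mask = np.zeros((h, w), dtype=np.uint8)
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    fov_r = 0.95 * min(h, w) / 2.0

    # stack of walks: (position, heading, width, depth)
    stack: list[tuple[np.ndarray, float, float, int]] = []
    for _ in range(cfg.n_roots):
        theta = rng.uniform(0, 2 * np.pi)
        pos = center + fov_r * np.array([np.sin(theta), np.cos(theta)])
        heading = float(np.arctan2(*(center - pos)))  # toward the centre
        stack.append((pos, heading, float(cfg.root_width), 0))

    while stack:
        pos, heading, width, depth = stack.pop()
        while depth < cfg.max_depth and width >= cfg.min_width:
            heading += rng.normal(0.0, cfg.angle_jitter_sd)
            nxt = pos + cfg.step_len * np.array([np.sin(heading),
                                                 np.cos(heading)])
            _stroke(mask, pos, nxt, width)
            pos = nxt
            depth += 1
            if not (0 <= pos[0] < h and 0 <= pos[1] < w):
                break
            if rng.random() < cfg.branch_prob:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                delta = sign * rng.uniform(np.deg2rad(20), np.deg2rad(50))
                child_w = width * cfg.width_decay
                if child_w >= cfg.min_width:
                    stack.append((pos.copy(), heading + delta, child_w, depth))
    return mask


def render_fundus_image(mask: np.ndarray,
                        cfg: FundusRenderConfig) -> np.ndarray:
    """Render an H×W×3 fundus-like image from a binary vessel mask."""
    cfg.validate()
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise DimensionMismatchError(f"mask must be 2-D, got shape {mask.shape}")
    rng = np.random.default_rng(cfg.seed)
    h, w = mask.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    fov = ((yy - cy) ** 2 + (xx - cx) ** 2) <= (
        cfg.fov_radius_frac * min(h, w) / 2.0) ** 2

    ramp = ((yy / max(h - 1, 1)) + (xx / max(w - 1, 1))) / 2.0 - 0.5
    vessels = gaussian_filter(mask.astype(np.float64), sigma=0.8)
    vessels = vessels / vessels.max() if vessels.max() > 0 else vessels
    intensity = (cfg.background_level
                 + cfg.illumination_gradient * ramp
                 - cfg.vessel_contrast * vessels)
    if cfg.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, cfg.noise_sd, size=(h, w))
    intensity = np.clip(intensity, 0.0, 1.0)
    img = np.stack([intensity, 0.60 * intensity, 0.35 * intensity], axis=-1)
    img[~fov] = 0.0
    return img


def augment_sample(s: FundusSample, cfg: AugmentConfig,
                   draw_seed: int) -> FundusSample:
    """Apply one random geometric transform identically to image and mask.

    Rotation, axis shifts, and zoom are drawn uniformly from the configured
    ranges; a horizontal flip fires with probability 0.5 when enabled.  The
    image is warped bilinearly, the mask with nearest-neighbour and
    re-binarised; out-of-bounds regions are filled with 0 (the dark FOV
    exterior).  Output size is unchanged.
    """
    rng = np.random.default_rng(draw_seed)
    angle = np.deg2rad(rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg))
    h, w = s.mask.shape
    dy = rng.uniform(-cfg.shift_frac, cfg.shift_frac) * h
    dx = rng.uniform(-cfg.shift_frac, cfg.shift_frac) * w
    zoom = rng.uniform(1.0 - cfg.max_zoom_frac, 1.0 + cfg.max_zoom_frac)
    flip = cfg.hflip and rng.random() < 0.5

    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    t = AffineTransform(translation=(-cx, -cy))
    if flip:
        t = t + AffineTransform(matrix=np.diag([-1.0, 1.0, 1.0]))
    t = (t + AffineTransform(scale=zoom)
         + AffineTransform(rotation=angle)
         + AffineTransform(translation=(cx + dx, cy + dy)))

    img = warp(s.image, t.inverse, order=1, cval=0.0, preserve_range=True)
    msk = warp(s.mask.astype(np.float64), t.inverse, order=0, cval=0.0,
               preserve_range=True)
    return FundusSample(id=s.id, image=np.clip(img, 0.0, 1.0),
                        mask=(msk >= 0.5).astype(np.uint8), source=s.source)


def default_configs(image_size: tuple[int, int] = (256, 256),
                    seed: int = 0) -> tuple[VesselTreeConfig, FundusRenderConfig]:
    """Size-proportional default generator configs.

    Tree geometry (stroke length, caliber) scales with image size so the
    vessel foreground fraction stays in the sparse regime typical of real
    fundus annotations (roughly 5–15%) at any resolution.
    """
    s = min(image_size) / 256.0
    tree = VesselTreeConfig(
        image_size=image_size,
        n_roots=5,
        max_depth=10,
        branch_prob=0.4,
        step_len=max(3.0, 8.0 * s),
        angle_jitter_sd=0.3,
        root_width=max(1.5, 5.0 * s),
        width_decay=0.75,
        min_width=min(1.0, max(0.75, 1.0 * s)),
        seed=seed,
    )
    render = FundusRenderConfig(seed=seed)
    return tree, render


def make_synthetic_dataset(n: int,
                           tree_cfg: VesselTreeConfig | None = None,
                           render_cfg: FundusRenderConfig | None = None,
                           seed: int = 0) -> list[FundusSample]:
    """Generate ``n`` independent samples with ids ``synth_0000``…

    Per-sample sub-seeds are derived deterministically from ``seed`` via a
    ``SeedSequence`` spawn, so any prefix of the dataset is stable under a
    larger ``n``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if tree_cfg is None or render_cfg is None:
        d_tree, d_render = default_configs()
        tree_cfg = tree_cfg or d_tree
        render_cfg = render_cfg or d_render
    children = np.random.SeedSequence(seed).spawn(n)
    samples = []
    for i, child in enumerate(children):
        s_tree, s_render = child.generate_state(2) % (2 ** 31)
        mask = generate_vessel_mask(replace(tree_cfg, seed=int(s_tree)))
        img = render_fundus_image(mask, replace(render_cfg, seed=int(s_render)))
        samples.append(FundusSample(id=f"synth_{i:04d}", image=img,
                                    mask=mask, source="synthetic"))
    return samples
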
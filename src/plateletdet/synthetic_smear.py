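"""Synthetic stained-blood-smear images with VOC annotations.

Renders a pale background, large round erythrocyte-like distractors with pale
centers (rendered but *not* labeled — they are the hard-negative structure),
and small dark-stained elliptical platelet blobs, one tight VOC box per
platelet.  Everything is reproducible from (config, seed); per-image streams
are derived as ``SeedSequence([seed, image_index])`` so datasets regenerate
identically regardless of generation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .geometry import Box, iou
from .voc_data import (DatasetSplit, ImageRecord, split_dataset, write_voc,
                       write_split_manifests)

logger = logging.getLogger(__name__)

__all__ = ["SmearConfig", "generate_image", "generate_dataset"]

#: labeled boxes may touch, but never overlap beyond this IOU
MAX_BOX_IOU = 0.6
#: minor/major axis ratio range for platelet ellipses (bounds box side lengths)
ECC_RANGE = (0.6, 1.0)


@dataclass
class SmearConfig:
    """Rendering parameters for one synthetic smear image.

    Platelet diameters default to roughly one tenth of the erythrocyte
    diameters, mirroring the 2-4 um platelet vs ~25 um-scale erythrocyte
    ratio of real stained smears.
    """

    image_size: int = 416
    n_platelets: tuple[int, int] = (3, 12)
    platelet_diameter: tuple[float, float] = (6.0, 16.0)
    n_erythrocytes: tuple[int, int] = (8, 20)
    erythrocyte_diameter: tuple[float, float] = (60.0, 110.0)
    background_color: tuple[int, int, int] = (232, 224, 234)
    erythrocyte_color: tuple[int, int, int] = (238, 190, 196)
    platelet_color: tuple[int, int, int] = (110, 52, 130)
    stain_tolerance: float = 60.0  # per-pixel L2 color distance counted as stained
    speckle: float = 12.0          # platelet texture amplitude
    noise_sigma: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_platelets", "platelet_diameter", "n_erythrocytes",
                     "erythrocyte_diameter"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name}={getattr(self, name)} is not a valid range")
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        if self.platelet_diameter[1] >= self.erythrocyte_diameter[0]:
            raise ValueError(
                "platelets must be smaller than erythrocytes: "
                f"platelet max {self.platelet_diameter[1]} >= "
                f"erythrocyte min {self.erythrocyte_diameter[0]}")
        if self.noise_sigma < 0 or self.speckle < 0:
            raise ValueError("noise parameters must be non-negative")


def _rng_for_image(seed: int, index: int | None = None) -> np.random.Generator:
    entropy = [seed] if index is None else [seed, index]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _draw_erythrocyte(img: np.ndarray, yy: np.ndarray, xx: np.ndarray,
                      cx: float, cy: float, radius: float,
                      color: np.ndarray, bg: np.ndarray) -> None:
    r2 = (xx - cx) ** 2 + (yy - cy) ** 2
    mask = r2 <= radius * radius
    # biconcave look: rim at full stain, center faded toward background
    frac = np.sqrt(np.clip(r2[mask], 0, None)) / radius
    fade = np.clip((0.55 - frac) / 0.55, 0.0, 1.0)[:, None]  # 1 at center, 0 at rim
    img[mask] = color[None, :] * (1 - 0.7 * fade) + bg[None, :] * (0.7 * fade)


def _platelet_mask(yy: np.ndarray, xx: np.ndarray, cx: float, cy: float,
                   a: float, b: float, theta: float) -> np.ndarray:
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_image(config: SmearConfig, seed: int | None = None,
                   index: int | None = None,
                   image_path: str | Path = "synthetic.png",
                   ) -> tuple[np.ndarray, ImageRecord]:
    """Render one smear image; returns (HxWx3 uint8 array, ImageRecord)."""
    config.validate()
    rng = _rng_for_image(config.seed if seed is None else seed, index)
    s = config.image_size
    bg = np.array(config.background_color, dtype=float)
    img = np.tile(bg, (s, s, 1))
    yy, xx = np.mgrid[0:s, 0:s].astype(float) + 0.5  # pixel centers

    ery_color = np.array(config.erythrocyte_color, dtype=float)
    n_ery = int(rng.integers(config.n_erythrocytes[0], config.n_erythrocytes[1] + 1))
    for _ in range(n_ery):
        radius = rng.uniform(*config.erythrocyte_diameter) / 2.0
        cx, cy = rng.uniform(0, s, size=2)
        _draw_erythrocyte(img, yy, xx, cx, cy, radius, ery_color, bg)

    pl_color = np.array(config.platelet_color, dtype=float)
    n_pl = int(rng.integers(config.n_platelets[0], config.n_platelets[1] + 1))
    boxes: list[Box] = []
    placed = 0
    attempts = 0
    while placed < n_pl and attempts < 50 * max(n_pl, 1):
        attempts += 1
        major = rng.uniform(*config.platelet_diameter)
        ratio = rng.uniform(*ECC_RANGE)
        a, b = major / 2.0, major * ratio / 2.0
        theta = rng.uniform(0, np.pi)
        margin = major / 2.0 + 1.0
        cx = rng.uniform(margin, s - margin)
        cy = rng.uniform(margin, s - margin)
        mask = _platelet_mask(yy, xx, cx, cy, a, b, theta)
        if not mask.any():
            continue
        ys, xs = np.nonzero(mask)
        cand = Box(float(xs.min()), float(ys.min()),
                   float(xs.max() + 1), float(ys.max() + 1))
        if any(iou(cand, existing) > MAX_BOX_IOU for existing in boxes):
            continue  # placement rejection keeps labeled boxes separable
        speckle = rng.normal(0.0, config.speckle, size=(mask.sum(), 3))
        img[mask] = pl_color[None, :] + speckle
        boxes.append(cand)
        placed += 1
    if placed < n_pl:
        logger.warning("placed only %d of %d platelets after rejection", placed, n_pl)

    if config.noise_sigma > 0:
        img += rng.normal(0.0, config.noise_sigma, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    record = ImageRecord(image_path=Path(image_path), width=s, height=s,
                         boxes=boxes)
    return img, record


def stained_fraction(img: np.ndarray, box: Box, config: SmearConfig) -> float:
    """Fraction of pixels inside ``box`` within the platelet stain band."""
    x0, y0 = int(box.x_min), int(box.y_min)
    x1, y1 = int(np.ceil(box.x_max)), int(np.ceil(box.y_max))
    patch = img[y0:y1, x0:x1].astype(float)
    if patch.size == 0:
        return 0.0
    dist = np.linalg.norm(
        patch - np.array(config.platelet_color, dtype=float), axis=-1)
    return float((dist <= config.stain_tolerance).mean())


def generate_dataset(config: SmearConfig, n_images: int = 412,
                     out_dir: str | Path = "smear_dataset",
                     seed: int | None = None,
                     counts: tuple[int, int, int] | None = None) -> DatasetSplit:
    """Write a VOC-layout dataset (PNGs + XML + split manifests) to disk.

    With default ``n_images=412`` the manifests follow the reference
    296/33/83 split.
    """
    if n_images < 5:
        raise ValueError(f"n_images must be >= 5, got {n_images}")
    config.validate()
    seed = config.seed if seed is None else seed
    out_dir = Path(out_dir)
    img_dir = out_dir / "JPEGImages"
    ann_dir = out_dir / "Annotations"
    img_dir.mkdir(parents=True, exist_ok=True)
    ann_dir.mkdir(parents=True, exist_ok=True)

    records: list[ImageRecord] = []
    for i in range(n_images):
        name = f"smear_{i:04d}"
        img_path = img_dir / f"{name}.png"
        img, record = generate_image(config, seed=seed, index=i,
                                     image_path=img_path)
        Image.fromarray(img).save(img_path)
        write_voc(record, ann_dir / f"{name}.xml")
        records.append(record)

    if counts is None and n_images == 412:
        counts = (296, 33, 83)
    split = split_dataset(records, counts=counts, seed=seed)
    write_split_manifests(split, out_dir / "ImageSets" / "Main")
    return split
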
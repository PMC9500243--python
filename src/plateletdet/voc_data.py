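"""Pascal VOC annotation I/O, dataset splitting, and letterbox preprocessing.

On disk, VOC bounding boxes are 1-based inclusive pixel indices; they are
converted to the package-internal 0-based half-open convention at this
boundary (``x_min = xmin - 1``, ``x_max = xmax``) and back on write.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .geometry import Box

logger = logging.getLogger(__name__)

__all__ = ["ImageRecord", "DatasetSplit", "read_voc", "write_voc",
           "split_dataset", "letterbox", "LetterboxMap",
           "DEFAULT_SPLIT_RATIOS", "load_split_dir"]

#: The reference 296/33/83-of-412 train/val/test proportions.
DEFAULT_SPLIT_RATIOS = (296 / 412, 33 / 412, 83 / 412)


@dataclass
class ImageRecord:
    """One image's path, dimensions, and ground-truth boxes."""

    image_path: Path
    width: int
    height: int
    boxes: list[Box] = field(default_factory=list)

    def __post_init__(self):
        self.image_path = Path(self.image_path)
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"image size {self.width}x{self.height} must be positive")

    @property
    def stem(self) -> str:
        return self.image_path.stem


@dataclass
class DatasetSplit:
    train: list[ImageRecord]
    val: list[ImageRecord]
    test: list[ImageRecord]

    def __iter__(self):
        yield from ("train", "val", "test")

    def __getitem__(self, name: str) -> list[ImageRecord]:
        return getattr(self, name)

    @property
    def all_records(self) -> list[ImageRecord]:
        return self.train + self.val + self.test


def _clip_box(b: Box, width: int, height: int) -> Box | None:
    clipped = Box(max(b.x_min, 0.0), max(b.y_min, 0.0),
                  min(b.x_max, float(width)), min(b.y_max, float(height)),
                  label=b.label)
    if (clipped.x_min, clipped.y_min, clipped.x_max, clipped.y_max) != (
            b.x_min, b.y_min, b.x_max, b.y_max):
        logger.warning("clipped out-of-bounds box %s to image %dx%d", b, width, height)
    if clipped.is_degenerate:
        return None
    return clipped


def read_voc(xml_path: str | Path) -> ImageRecord:
    """Parse one VOC annotation file into an :class:`ImageRecord`."""
    xml_path = Path(xml_path)
    root = ET.parse(xml_path).getroot()
    size = root.find("size")
    if size is None:
        raise ValueError(f"{xml_path}: missing <size> block")
    width = int(size.findtext("width"))
    height = int(size.findtext("height"))

    path_text = root.findtext("path")
    filename = root.findtext("filename") or xml_path.with_suffix(".png").name
    if path_text and Path(path_text).exists():
        image_path = Path(path_text)
    else:
        sibling = xml_path.parent.parent / "JPEGImages" / filename
        image_path = sibling if sibling.exists() else xml_path.parent / filename

    boxes: list[Box] = []
    for obj in root.iter("object"):
        name = obj.findtext("name") or "platelet"
        bb = obj.find("bndbox")
        xmin = float(bb.findtext("xmin"))
        ymin = float(bb.findtext("ymin"))
        xmax = float(bb.findtext("xmax"))
        ymax = float(bb.findtext("ymax"))
        # 1-based inclusive: xmax == xmin is a legal one-pixel box
        if xmax < xmin or ymax < ymin:
            logger.warning("%s: dropped degenerate object %s", xml_path, name)
            continue
        box = Box(xmin - 1.0, ymin - 1.0, xmax, ymax, label=name)
        box = _clip_box(box, width, height)
        if box is not None:
            boxes.append(box)
    return ImageRecord(image_path=image_path, width=width, height=height, boxes=boxes)


def write_voc(record: ImageRecord, xml_path: str | Path) -> None:
    """Write a VOC-dialect annotation file (inverse of :func:`read_voc`).

    Coordinates are written as integers (VOC stores pixel indices); records
    produced by the synthetic generator carry integer bounds and round-trip
    exactly.
    """
    xml_path = Path(xml_path)
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = str(record.image_path.parent.name)
    ET.SubElement(root, "filename").text = record.image_path.name
    ET.SubElement(root, "path").text = str(record.image_path)
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(record.width)
    ET.SubElement(size, "height").text = str(record.height)
    ET.SubElement(size, "depth").text = "3"
    for b in record.boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = b.label
        ET.SubElement(obj, "pose").text = "Unspecified"
        ET.SubElement(obj, "truncated").text = "0"
        ET.SubElement(obj, "difficult").text = "0"
        bb = ET.SubElement(obj, "bndbox")
        ET.SubElement(bb, "xmin").text = str(int(round(b.x_min)) + 1)
        ET.SubElement(bb, "ymin").text = str(int(round(b.y_min)) + 1)
        ET.SubElement(bb, "xmax").text = str(int(round(b.x_max)))
        ET.SubElement(bb, "ymax").text = str(int(round(b.y_max)))
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(xml_path, encoding="unicode")


def split_dataset(records: Sequence[ImageRecord],
                  counts: tuple[int, int, int] | None = None,
                  seed: int = 0) -> DatasetSplit:
    """Deterministic seeded random partition into train/val/test.

    Without explicit ``counts`` the reference 296/33/83-of-412 proportions
    are applied to ``len(records)``.
    """
    n = len(records)
    if counts is None:
        n_train = round(n * DEFAULT_SPLIT_RATIOS[0])
        n_val = round(n * DEFAULT_SPLIT_RATIOS[1])
        counts = (n_train, n_val, n - n_train - n_val)
    if sum(counts) != n:
        raise ValueError(f"split counts {counts} sum to {sum(counts)}, expected {n}")
    perm = np.random.default_rng(seed).permutation(n)
    order = [records[i] for i in perm]
    n_train, n_val, _ = counts
    return DatasetSplit(train=order[:n_train],
                        val=order[n_train:n_train + n_val],
                        test=order[n_train + n_val:])


@dataclass
class LetterboxMap:
    """The affine map applied by :func:`letterbox`, and its inverse."""

    scale: float
    pad_x: float
    pad_y: float

    def apply_box(self, b: Box) -> Box:
        return Box(b.x_min * self.scale + self.pad_x,
                   b.y_min * self.scale + self.pad_y,
                   b.x_max * self.scale + self.pad_x,
                   b.y_max * self.scale + self.pad_y, label=b.label)

    def invert_box(self, b: Box) -> Box:
        return Box((b.x_min - self.pad_x) / self.scale,
                   (b.y_min - self.pad_y) / self.scale,
                   (b.x_max - self.pad_x) / self.scale,
                   (b.y_max - self.pad_y) / self.scale, label=b.label)


def letterbox(image: np.ndarray, record: ImageRecord | None = None,
              target_size: int = 416, divisor: int = 32,
              pad_value: int = 128) -> tuple[np.ndarray, ImageRecord | None, LetterboxMap]:
    """Aspect-preserving resize with symmetric neutral-gray padding.

    Returns the resized HxWx3 uint8 array, the transformed record (boxes
    mapped by the same affine), and the :class:`LetterboxMap` whose inverse
    reports detections back in original image coordinates.
    """
    if target_size % divisor != 0:
        raise ValueError(
            f"target_size {target_size} must be divisible by {divisor}")
    h, w = image.shape[:2]
    scale = target_size / max(h, w)
    new_w, new_h = int(round(w * scale)), int(round(h * scale))
    resized = np.asarray(
        Image.fromarray(image).resize((new_w, new_h), Image.BILINEAR))
    canvas = np.full((target_size, target_size, 3), pad_value, dtype=np.uint8)
    pad_x = (target_size - new_w) // 2
    pad_y = (target_size - new_h) // 2
    canvas[pad_y:pad_y + new_h, pad_x:pad_x + new_w] = resized
    lmap = LetterboxMap(scale=scale, pad_x=float(pad_x), pad_y=float(pad_y))
    new_record = None
    if record is not None:
        new_record = ImageRecord(
            image_path=record.image_path, width=target_size, height=target_size,
            boxes=[lmap.apply_box(b) for b in record.boxes])
    return canvas, new_record, lmap


def write_split_manifests(split: DatasetSplit, out_dir: str | Path) -> None:
    """Write ImageSets/Main-style train/val/test manifests of image stems."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in split:
        (out_dir / f"{name}.txt").write_text(
            "".join(r.stem + "\n" for r in split[name]))


def load_split_dir(root: str | Path) -> DatasetSplit:
    """Load a generated VOC-layout dataset directory back into records."""
    root = Path(root)
    parts = {}
    for name in ("train", "val", "test"):
        manifest = root / "ImageSets" / "Main" / f"{name}.txt"
        stems = manifest.read_text().split() if manifest.exists() else []
        parts[name] = [read_voc(root / "Annotations" / f"{s}.xml") for s in stems]
    return DatasetSplit(**parts)
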
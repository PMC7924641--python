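"""Image-set loading, resizing, binary-level balancing and augmentation.

The unit flowing through the preprocessing stage is a :class:`LabeledImageSet`:
a list of ``H x W x 3`` uint8 arrays with integer labels, stable string sample
identifiers and a level tag (``multiclass`` = normal + four medulloblastoma
subtypes, ``binary`` = normal vs abnormal).

The augmentation policy mirrors a standard histopathology recipe: horizontal
and vertical flips, pixel translation in (-30, 30), isotropic scaling in
(0.9, 1.1) and shearing in (0, 45) degrees. Copies are produced per image
with independently seeded draws and edge-replication fill, and are intended
to be applied to training folds only (see :mod:`mbhis.evaluate`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage.transform import AffineTransform, resize, warp

from .exceptions import ConfigurationError, DataError

logger = logging.getLogger(__name__)

LEVELS = ("binary", "multiclass")
BINARY_CLASS_NAMES = ["normal", "abnormal"]
IMAGE_SUFFIXES = {".jpg", ".jpeg", ".png", ".tif", ".tiff"}


@dataclass
class LabeledImageSet:
    """Images + labels + class names + level tag + stable sample ids."""

    images: list[np.ndarray]
    labels: np.ndarray
    class_names: list[str]
    level: str
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.images) == len(self.labels) == len(self.sample_ids)):
            raise DataError("images, labels and sample_ids must have equal length")
        if self.level not in LEVELS:
            raise DataError(f"unknown level {self.level!r}")
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= len(self.class_names)):
            raise DataError("labels must index into class_names")
        if self.level == "binary" and self.class_names != BINARY_CLASS_NAMES:
            raise DataError("binary level requires class_names ['normal', 'abnormal']")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> dict[str, int]:
        return {
            name: int(np.sum(self.labels == i)) for i, name in enumerate(self.class_names)
        }

    def subset(self, idx) -> "LabeledImageSet":
        idx = np.asarray(idx, dtype=int)
        return LabeledImageSet(
            [self.images[i] for i in idx],
            self.labels[idx],
            list(self.class_names),
            self.level,
            [self.sample_ids[i] for i in idx],
        )


@dataclass
class AugmentationPolicy:
    """Random flip/translate/scale/shear policy with per-copy seeded draws."""

    flip_x: bool = True
    flip_y: bool = True
    translation_px: tuple[int, int] = (-30, 30)
    scale: tuple[float, float] = (0.9, 1.1)
    shear_deg: tuple[float, float] = (0.0, 45.0)
    per_image_copies: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("translation_px", "scale", "shear_deg"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name} range must be ordered, got ({lo}, {hi})")
        if self.per_image_copies < 1:
            raise ConfigurationError("per_image_copies must be >= 1")


def load_folder_dataset(root: str | Path, level: str = "multiclass") -> LabeledImageSet:
    """Load a folder-per-class tree of raster images.

    Class names are the sub-folder names sorted lexicographically; sample ids
    are the POSIX relative paths, so repeated loads of the same tree produce
    identical ordering.
    """
    root = Path(root)
    if not root.is_dir():
        raise DataError(f"dataset root {root} is not a directory")
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise DataError(f"dataset root {root} contains no class folders")
    images: list[np.ndarray] = []
    labels: list[int] = []
    sample_ids: list[str] = []
    class_names = [p.name for p in class_dirs]
    for ci, cdir in enumerate(class_dirs):
        files = sorted(
            p for p in cdir.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES
        )
        n_ok = 0
        for f in files:
            try:
                with Image.open(f) as im:
                    arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
            except (UnidentifiedImageError, OSError) as exc:
                logger.warning("skipping unreadable image %s (%s)", f, exc)
                continue
            images.append(arr)
            labels.append(ci)
            sample_ids.append(f.relative_to(root).as_posix())
            n_ok += 1
        if n_ok == 0:
            raise DataError(f"class folder {cdir} contains no readable images")
    return LabeledImageSet(images, np.array(labels), class_names, level, sample_ids)


def resize_images(data: LabeledImageSet, size: tuple[int, int] = (224, 224)) -> LabeledImageSet:
    """Resize every image to ``size`` (H, W) x 3; labels and ids unchanged.

    Images that already match are passed through pixel-identical.
    """
    h, w = size
    if h < 1 or w < 1:
        raise ConfigurationError(f"target size must be positive, got {size}")
    out = []
    for img in data.images:
        if img.shape[:2] == (h, w):
            out.append(img)
            continue
        res = resize(img, (h, w), order=1, preserve_range=True, anti_aliasing=True)
        out.append(np.clip(np.rint(res), 0, 255).astype(np.uint8))
    return replace(data, images=out)


def make_binary_level(
    data: LabeledImageSet,
    n_abnormal: int = 50,
    seed: int = 0,
    stratified: bool = True,
    normal_class: str = "normal",
) -> LabeledImageSet:
    """Build the balanced normal/abnormal subset for the binary level.

    Keeps every normal image and samples ``n_abnormal`` tumor images without
    replacement from the pooled subtype classes. By default the draw is
    stratified proportionally across subtypes (rounded largest-remainder);
    ``stratified=False`` samples uniformly from the pooled tumor images.
    """
    if data.level != "multiclass":
        raise DataError("binary-level construction expects a multiclass set")
    if normal_class not in data.class_names:
        raise DataError(f"no class named {normal_class!r} in {data.class_names}")
    normal_idx = data.class_names.index(normal_class)
    rng = np.random.default_rng(seed)
    norm_rows = np.flatnonzero(data.labels == normal_idx)
    tumor_rows = np.flatnonzero(data.labels != normal_idx)
    if len(tumor_rows) < n_abnormal:
        raise DataError(
            f"requested {n_abnormal} tumor images but only {len(tumor_rows)} available"
        )
    if stratified:
        picked: list[np.ndarray] = []
        subtype_rows = [
            np.flatnonzero(data.labels == ci)
            for ci in range(data.n_classes)
            if ci != normal_idx
        ]
        # largest-remainder apportionment of n_abnormal across subtypes
        quota = np.array([len(r) for r in subtype_rows], dtype=float)
        exact = n_abnormal * quota / quota.sum()
        take = np.floor(exact).astype(int)
        rem = np.argsort(-(exact - take))
        for j in rem[: n_abnormal - take.sum()]:
            take[j] += 1
        take = np.minimum(take, [len(r) for r in subtype_rows])
        short = n_abnormal - take.sum()  # spill over if a subtype ran dry
        while short > 0:
            for j in np.argsort(-quota):
                if take[j] < len(subtype_rows[j]):
                    take[j] += 1
                    short -= 1
                    if short == 0:
                        break
        for rows, t in zip(subtype_rows, take):
            picked.append(rng.choice(rows, size=t, replace=False))
        tumor_pick = np.concatenate(picked)
    else:
        tumor_pick = rng.choice(tumor_rows, size=n_abnormal, replace=False)
    keep = np.concatenate([norm_rows, np.sort(tumor_pick)])
    sub = data.subset(keep)
    new_labels = (sub.labels != normal_idx).astype(int)
    return LabeledImageSet(
        sub.images, new_labels, list(BINARY_CLASS_NAMES), "binary", sub.sample_ids
    )


def _augment_one(img: np.ndarray, policy: AugmentationPolicy, rng: np.random.Generator) -> np.ndarray:
    """One augmented copy: flip -> scale -> shear -> translate, edge fill."""
    out = img
    if policy.flip_x and rng.random() < 0.5:
        out = out[:, ::-1]
    if policy.flip_y and rng.random() < 0.5:
        out = out[::-1, :]
    s = rng.uniform(*policy.scale)
    shear = math.radians(rng.uniform(*policy.shear_deg))
    tx = rng.uniform(*policy.translation_px)
    ty = rng.uniform(*policy.translation_px)
    tf = (
        AffineTransform(scale=(s, s))
        + AffineTransform(shear=shear)
        + AffineTransform(translation=(tx, ty))
    )
    if np.allclose(tf.params, np.eye(3)):
        return np.ascontiguousarray(out)
    warped = warp(
        out.astype(np.float64), tf.inverse, order=1, mode="edge", preserve_range=True
    )
    return np.clip(np.rint(warped), 0, 255).astype(np.uint8)


def augment(data: LabeledImageSet, policy: AugmentationPolicy) -> LabeledImageSet:
    """Originals plus ``per_image_copies`` transformed copies per image.

    Copies inherit the source label and get sample ids derived from the
    source id (``<id>#aug<k>``) so fold-leakage audits can trace lineage.
    """
    rng = np.random.default_rng(policy.seed)
    images = list(data.images)
    labels = list(data.labels)
    ids = list(data.sample_ids)
    for i, (img, lab, sid) in enumerate(zip(data.images, data.labels, data.sample_ids)):
        for k in range(policy.per_image_copies):
            images.append(_augment_one(img, policy, rng))
            labels.append(int(lab))
            ids.append(f"{sid}#aug{k}")
    return LabeledImageSet(images, np.array(labels), list(data.class_names), data.level, ids)
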
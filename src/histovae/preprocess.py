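"""Patch loading and preprocessing for two-class histopathology tiles.

The on-disk layout mirrors the public IDC (invasive ductal carcinoma) patch
collections: a root directory with class subdirectories ``0`` (IDC negative)
and ``1`` (IDC positive) holding small RGB PNG tiles.  The preprocessing
chain is grayscale (BT.601 luma) -> bilinear resize to 64x64 -> divide by
255, producing float images in [0, 1]; balanced subsampling and the
train/test/validation split are both driven by explicit seeds so every
downstream result is reproducible from (directory, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

IMAGE_SIZE = 64  # working spatial resolution (pixels per side)
CLASS_DIRS = ("0", "1")

__all__ = [
    "RawPatch",
    "DatasetBundle",
    "load_patch_dir",
    "to_grayscale",
    "resize64",
    "normalize",
    "sample_balanced",
    "split_dataset",
    "preprocess_patches",
    "save_bundle",
    "load_bundle",
]


@dataclass
class RawPatch:
    """One labelled RGB tile as read from disk (uint8, any h x w >= 1)."""

    pixels: np.ndarray
    label: int
    source_path: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


@dataclass
class DatasetBundle:
    """Disjoint train/validation/test partitions with index-aligned labels."""

    train_images: np.ndarray
    train_labels: np.ndarray
    val_images: np.ndarray
    val_labels: np.ndarray
    test_images: np.ndarray
    test_labels: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return len(self.train_labels) + len(self.val_labels) + len(self.test_labels)


def load_patch_dir(root_path) -> list:
    """Read every PNG under ``root/0`` and ``root/1`` into ``RawPatch`` objects.

    Files are enumerated in lexicographic path order so any later seeded
    sampling depends only on the seed, never on filesystem order.  Unreadable
    files are skipped with a warning; a missing or empty class directory is a
    hard error because it silently breaks class balance.
    """
    root = Path(root_path)
    patches = []
    for class_name in CLASS_DIRS:
        class_dir = root / class_name
        if not class_dir.is_dir():
            raise FileNotFoundError(f"missing class subdirectory: {class_dir}")
        files = sorted(class_dir.glob("*.png"))
        if not files:
            raise ValueError(f"class subdirectory has no PNG files: {class_dir}")
        for path in files:
            try:
                with Image.open(path) as img:
                    arr = np.asarray(img.convert("RGB"), dtype=np.uint8)
            except OSError as exc:
                logger.warning("skipping unreadable image %s: %s", path, exc)
                continue
            patches.append(RawPatch(pixels=arr, label=int(class_name), source_path=str(path)))
    return patches


def to_grayscale(patch) -> np.ndarray:
    """BT.601 luma conversion (0.299 R + 0.587 G + 0.114 B), rounded to uint8."""
    pixels = patch.pixels if isinstance(patch, RawPatch) else np.asarray(patch)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected (h, w, 3) RGB input, got shape {pixels.shape}")
    luma = pixels[..., 0] * 0.299 + pixels[..., 1] * 0.587 + pixels[..., 2] * 0.114
    return np.rint(luma).astype(np.uint8)


def resize64(image, size: int = IMAGE_SIZE) -> np.ndarray:
    """Bilinear resize of a single-channel image to ``size`` x ``size``.

    Uses half-pixel-centre sampling (source coordinate
    ``(dst + 0.5) * scale - 0.5``) with edge clamping, the convention shared
    by mainstream image libraries, implemented directly so the interpolation
    semantics are fixed and testable.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D single-channel image, got shape {image.shape}")
    h, w = image.shape
    if h < 2 or w < 2:
        raise ValueError(f"image dimensions must be >= 2, got {h}x{w}")
    if (h, w) == (size, size):
        return image.copy()

    def axis_coords(n_src, n_dst):
        src = (np.arange(n_dst) + 0.5) * (n_src / n_dst) - 0.5
        lo = np.clip(np.floor(src).astype(int), 0, n_src - 1)
        hi = np.minimum(lo + 1, n_src - 1)
        frac = np.clip(src - lo, 0.0, 1.0)
        return lo, hi, frac

    r0, r1, fr = axis_coords(h, size)
    c0, c1, fc = axis_coords(w, size)
    fr = fr[:, None]
    top = image[r0][:, c0] * (1 - fc) + image[r0][:, c1] * fc
    bot = image[r1][:, c0] * (1 - fc) + image[r1][:, c1] * fc
    return top * (1 - fr) + bot * fr


def normalize(images) -> np.ndarray:
    """Map integer intensities 0-255 to float32 in [0, 1] by dividing by 255."""
    arr = np.asarray(images)
    if arr.size and (arr.min() < 0 or arr.max() > 255):
        raise ValueError("pixel values must lie in [0, 255]")
    return (arr / 255.0).astype(np.float32)


def sample_balanced(patches, per_class: int, seed: int) -> list:
    """Draw exactly ``per_class`` patches of each label, without replacement."""
    rng = np.random.default_rng(seed)
    selected = []
    for label in (0, 1):
        members = [p for p in patches if p.label == label]
        if len(members) < per_class:
            raise ValueError(
                f"class {label} has only {len(members)} patches, need {per_class}"
            )
        idx = rng.choice(len(members), size=per_class, replace=False)
        selected.extend(members[i] for i in sorted(idx))
    return selected


def split_dataset(images, labels, sizes, seed: int, stratify: bool = False) -> DatasetBundle:
    """Seeded shuffle-and-slice split into train/test/validation partitions.

    ``sizes`` is ``(n_train, n_test, n_validation)`` and must sum to the
    number of samples.  A single permutation is drawn, then contiguous slices
    taken in train/test/validation order; with ``stratify`` the same
    procedure is applied per class and the per-class quotas are proportional.
    """
    images = np.asarray(images)
    labels = np.asarray(labels)
    n = len(labels)
    n_train, n_test, n_val = (int(s) for s in sizes)
    if n_train + n_test + n_val != n:
        raise ValueError(f"split sizes {sizes} do not sum to the sample count {n}")
    if len(images) != n:
        raise ValueError("images and labels must have equal length")

    rng = np.random.default_rng(seed)
    if stratify:
        train_idx, test_idx, val_idx = [], [], []
        remainders = []
        for label in np.unique(labels):
            cls = np.flatnonzero(labels == label)
            cls = cls[rng.permutation(len(cls))]
            t = int(n_train * len(cls) / n)
            s = int(n_test * len(cls) / n)
            v = len(cls) - t - s
            train_idx.append(cls[:t])
            test_idx.append(cls[t : t + s])
            val_idx.append(cls[t + s :])
            remainders.append(v)
        train_idx = np.concatenate(train_idx)
        test_idx = np.concatenate(test_idx)
        val_idx = np.concatenate(val_idx)
        # rounding can leave the validation slice off by a few; rebalance
        pool = np.concatenate([train_idx, test_idx, val_idx])
        train_idx, test_idx, val_idx = pool[:n_train], pool[n_train : n_train + n_test], pool[n_train + n_test :]
    else:
        perm = rng.permutation(n)
        train_idx = perm[:n_train]
        test_idx = perm[n_train : n_train + n_test]
        val_idx = perm[n_train + n_test :]

    return DatasetBundle(
        train_images=images[train_idx],
        train_labels=labels[train_idx],
        val_images=images[val_idx],
        val_labels=labels[val_idx],
        test_images=images[test_idx],
        test_labels=labels[test_idx],
        meta={
            "seed": int(seed),
            "sizes": (n_train, n_test, n_val),
            "stratified": bool(stratify),
            "train_idx": train_idx,
            "test_idx": test_idx,
            "val_idx": val_idx,
        },
    )


def preprocess_patches(patches) -> tuple:
    """Full chain grayscale -> resize 64x64 -> normalise for a patch list.

    Returns ``(images, labels)`` with images shaped (n, 64, 64, 1) in [0, 1].
    Normalisation runs last so interpolation happens on integer intensities.
    """
    if not patches:
        raise ValueError("no patches to preprocess")
    stack = np.empty((len(patches), IMAGE_SIZE, IMAGE_SIZE), dtype=np.float64)
    labels = np.empty(len(patches), dtype=np.int64)
    for i, patch in enumerate(patches):
        gray = patch.pixels if patch.pixels.ndim == 2 else to_grayscale(patch)
        stack[i] = resize64(gray)
        labels[i] = patch.label
    images = normalize(np.clip(stack, 0, 255))
    return images[..., None], labels


def save_bundle(bundle: DatasetBundle, path) -> None:
    """Persist a split dataset (images, labels, split indices, seed, sizes)."""
    meta = bundle.meta
    np.savez_compressed(
        path,
        train_images=bundle.train_images,
        train_labels=bundle.train_labels,
        val_images=bundle.val_images,
        val_labels=bundle.val_labels,
        test_images=bundle.test_images,
        test_labels=bundle.test_labels,
        seed=meta.get("seed", -1),
        sizes=np.asarray(meta.get("sizes", (0, 0, 0))),
    )


def load_bundle(path) -> DatasetBundle:
    with np.load(path) as data:
        return DatasetBundle(
            train_images=data["train_images"],
            train_labels=data["train_labels"],
            val_images=data["val_images"],
            val_labels=data["val_labels"],
            test_images=data["test_images"],
            test_labels=data["test_labels"],
            meta={"seed": int(data["seed"]), "sizes": tuple(int(s) for s in data["sizes"])},
        )
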
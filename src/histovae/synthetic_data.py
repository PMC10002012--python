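"""Seeded two-class synthetic texture patches.

A statistical stand-in for IDC patch data so the whole
reconstruct-then-classify pipeline can be exercised without any download:
class 0 mimics benign tissue (a pale background with a few large, faint
blobs), class 1 mimics carcinoma-dense regions (many small dark "nuclei").
The classes are separable by construction — mean intensity and blob texture
differ — which gives fast, reliable end-to-end smoke surfaces.  This is not
a histology simulator: there is no staining model, no tissue architecture,
and no annotation noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .preprocess import IMAGE_SIZE

__all__ = ["TextureParams", "generate_patch", "generate_dataset", "write_patch_dir"]


@dataclass
class TextureParams:
    """Per-class blob statistics for the texture generator.

    Intensities are grayscale levels in [0, 1]; blobs are composited darkest-
    wins onto the background (both phenotypes are darker than the pale
    background, as haematoxylin-stained nuclei are).
    """

    blob_count_range: dict = field(
        default_factory=lambda: {0: (3, 6), 1: (25, 40)}
    )
    blob_radius_range: dict = field(
        default_factory=lambda: {0: (5, 9), 1: (2, 4)}
    )
    blob_intensity: dict = field(default_factory=lambda: {0: 0.62, 1: 0.25})
    background_level: float = 0.82
    noise_sd: float = 0.05

    def __post_init__(self):
        for label in (0, 1):
            lo, hi = self.blob_count_range[label]
            if hi < lo:
                raise ValueError(f"empty blob_count_range for class {label}")
            lo, hi = self.blob_radius_range[label]
            if hi < lo:
                raise ValueError(f"empty blob_radius_range for class {label}")
            if not 0.0 <= self.blob_intensity[label] <= 1.0:
                raise ValueError("blob_intensity must lie in [0, 1]")
        if not 0.0 <= self.background_level <= 1.0:
            raise ValueError("background_level must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _patch_rng(seed, label, index=None):
    entropy = (int(seed), int(label)) if index is None else (int(seed), int(label), int(index))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def generate_patch(label: int, params: TextureParams = None, seed: int = 0,
                   rng=None) -> np.ndarray:
    """One 64x64 grayscale patch in [0, 1] for the given class.

    Deterministic: the same (label, params, seed) always yields the identical
    image.  Background is filled at ``background_level``, seeded filled discs
    are composited darkest-wins, then Gaussian pixel noise of sd ``noise_sd``
    is added and the result clipped to [0, 1].
    """
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label}")
    params = params or TextureParams()
    rng = rng if rng is not None else _patch_rng(seed, label)

    img = np.full((IMAGE_SIZE, IMAGE_SIZE), params.background_level, dtype=np.float64)
    lo, hi = params.blob_count_range[label]
    n_blobs = int(rng.integers(lo, hi + 1))
    r_lo, r_hi = params.blob_radius_range[label]
    yy, xx = np.mgrid[0:IMAGE_SIZE, 0:IMAGE_SIZE]
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, IMAGE_SIZE, size=2)
        radius = rng.uniform(r_lo, r_hi)
        # jitter the blob darkness slightly so blobs are not flat discs
        level = np.clip(params.blob_intensity[label] + rng.normal(0, 0.04), 0, 1)
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        img[mask] = np.minimum(img[mask], level)
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_dataset(n_per_class: int, params: TextureParams = None, seed: int = 0):
    """Balanced dataset of 2*n_per_class patches, labels aligned index-wise.

    Per-image RNGs are derived from ``(seed, label, index)`` so the first
    ``n`` images of each class are stable when ``n_per_class`` grows.
    Returns ``(images, labels)`` with images shaped (2n, 64, 64, 1), class-0
    block first.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    params = params or TextureParams()
    images = np.empty((2 * n_per_class, IMAGE_SIZE, IMAGE_SIZE, 1), dtype=np.float32)
    labels = np.empty(2 * n_per_class, dtype=np.int64)
    pos = 0
    for label in (0, 1):
        for i in range(n_per_class):
            rng = _patch_rng(seed, label, i)
            images[pos, :, :, 0] = generate_patch(label, params, rng=rng)
            labels[pos] = label
            pos += 1
    return images, labels


def write_patch_dir(images, labels, root_path) -> int:
    """Write a dataset as 8-bit grayscale PNGs under ``root/0`` and ``root/1``.

    Produces exactly the layout :func:`histovae.preprocess.load_patch_dir`
    reads; pixel values round-trip within 1/255 (8-bit quantisation).
    Returns the number of files written.
    """
    images = np.asarray(images)
    labels = np.asarray(labels)
    if images.size == 0 or len(labels) == 0:
        raise ValueError("refusing to write an empty dataset")
    if len(images) != len(labels):
        raise ValueError("images and labels must have equal length")
    root = Path(root_path)
    counters = {0: 0, 1: 0}
    for img, label in zip(images, labels):
        label = int(label)
        class_dir = root / str(label)
        class_dir.mkdir(parents=True, exist_ok=True)
        arr = np.rint(np.clip(np.squeeze(img), 0, 1) * 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(class_dir / f"patch_{counters[label]:05d}.png")
        counters[label] += 1
    return counters[0] + counters[1]
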
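"""Preprocessing and dataset construction for network training.

Network input follows the acquisition-to-training pipeline: the density
resolution is reduced (14 -> 8 bits by linear rescaling of the intensity
range), the portrait image is padded equally on both lateral edges to a
square, and the square is resized with nearest-neighbour interpolation to
the network size (256 x 256 by default; this package's desk-scale
experiments use 128 x 128). Masks undergo the same pad/resize without the
intensity step and stay strictly binary.

Four orientation-dataset variants control how laterality is presented to
the network:

1. all images aligned with the chest wall on the left;
2. anatomical orientation (left breast faces left, right faces right);
3. variant 1 plus an independent random horizontal flip per image;
4. variant 2 plus an independent random horizontal flip per image.

Images and masks always flip together. Splitting into train / validation /
test is seeded and exhaustive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .images import Mammogram, ValidationError, as_mask

__all__ = [
    "PreprocessConfig",
    "OrientationMode",
    "preprocess",
    "preprocess_mask",
    "orient",
    "infer_laterality",
    "split_dataset",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Target size/bit depth, pad value, and interpolation (nearest only)."""

    out_size: int = 256
    out_bits: int = 8
    pad_value: int = 0
    interpolation: str = "nearest"

    def __post_init__(self) -> None:
        if self.out_size < 16:
            raise ValidationError(f"out_size must be >= 16, got {self.out_size}")
        if self.interpolation != "nearest":
            raise ValidationError("only nearest-neighbour interpolation is supported")


@dataclass(frozen=True)
class OrientationMode:
    """Orientation-dataset variant (1-4) with flip probability for 3/4."""

    mode: int = 1
    flip_probability: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in (1, 2, 3, 4):
            raise ValidationError(f"mode must be in {{1, 2, 3, 4}}, got {self.mode}")
        if self.mode in (3, 4) and not (0.0 < self.flip_probability < 1.0):
            raise ValidationError(
                f"flip_probability must be in (0, 1) for modes 3/4, got {self.flip_probability}"
            )


def _pad_widths(height: int, width: int) -> tuple[int, int]:
    total = height - width
    return total // 2, total - total // 2


def _pad_resize(arr: np.ndarray, out_size: int, pad_value, order: int = 0) -> np.ndarray:
    h, w = arr.shape
    left, right = _pad_widths(h, w)
    padded = np.pad(arr, ((0, 0), (left, right)), constant_values=pad_value)
    return resize(
        padded,
        (out_size, out_size),
        order=order,
        preserve_range=True,
        anti_aliasing=False,
    )


def preprocess(image: Mammogram, cfg: PreprocessConfig = PreprocessConfig()) -> Mammogram:
    """Rescale intensity range, pad to square on the lateral edges, resize.

    Intensities map linearly from ``[0, 2**in_bits - 1]`` to
    ``[0, 2**out_bits - 1]`` (range scaling, not bit truncation). Padding is
    split as evenly as possible between the two lateral edges (widths differ
    by at most one pixel), preserving the aspect ratio before the
    nearest-neighbour resize.
    """
    h, w = image.shape
    if w > h:
        raise ValidationError(f"portrait input required (width <= height), got {h}x{w}")
    if image.bit_depth < cfg.out_bits:
        raise ValidationError(
            f"cannot raise bit depth {image.bit_depth} -> {cfg.out_bits}"
        )
    in_max = (1 << image.bit_depth) - 1
    out_max = (1 << cfg.out_bits) - 1
    scaled = np.asarray(image.pixels, dtype=np.float64) * (out_max / in_max)
    out = _pad_resize(scaled, cfg.out_size, float(cfg.pad_value))
    dtype = np.uint8 if cfg.out_bits <= 8 else np.uint16
    pixels = np.clip(np.rint(out), 0, out_max).astype(dtype)
    return Mammogram(pixels=pixels, bit_depth=cfg.out_bits, laterality=image.laterality)


def preprocess_mask(mask: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Pad/resize a binary mask exactly as :func:`preprocess` does the image
    (no intensity step); output is boolean."""
    m = as_mask(mask)
    if m.shape[1] > m.shape[0]:
        raise ValidationError("portrait input required (width <= height)")
    return _pad_resize(m.astype(np.uint8), cfg.out_size, 0) > 0.5


def infer_laterality(image: Mammogram) -> str:
    """Fallback laterality from tissue mass: the image half containing more
    intensity mass is taken as the chest-wall side."""
    px = np.asarray(image.pixels, dtype=np.float64)
    half = px.shape[1] // 2
    return "left" if px[:, :half].sum() >= px[:, half:].sum() else "right"


def orient(
    image: Mammogram,
    mask: np.ndarray,
    mode: OrientationMode,
    rng: np.random.Generator,
) -> tuple[Mammogram, np.ndarray, bool]:
    """Apply one orientation-dataset variant to an image/mask pair.

    Modes 1/3 align every image chest-wall-left before any random flip;
    modes 2/4 keep anatomical orientation. Missing laterality raises for
    the anatomical modes and falls back to :func:`infer_laterality` (with a
    warning) for the aligned modes. Returns the pair plus whether the
    output is mirrored relative to the input.
    """
    mask = as_mask(mask)
    if mask.shape != image.shape:
        raise ValidationError("image and mask are on different grids")
    laterality = image.laterality
    if laterality is None:
        if mode.mode in (2, 4):
            raise ValidationError("laterality metadata required for modes 2 and 4")
        laterality = infer_laterality(image)
        warnings.warn("laterality missing; inferred from intensity mass", stacklevel=2)

    flip = False
    if mode.mode in (1, 3) and laterality == "right":
        flip = True  # align chest wall to the left
    if mode.mode in (3, 4) and rng.random() < mode.flip_probability:
        flip = not flip

    if flip:
        image = image.with_pixels(np.asarray(image.pixels)[:, ::-1].copy())
        mask = mask[:, ::-1].copy()
    return image, mask, flip


def split_dataset(
    manifest: list,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> dict[str, list]:
    """Seeded random split into train / validation / test.

    Split sizes are the largest-remainder rounding of ``n * fractions`` so
    they always sum to ``n`` (670 images at fractions 530/670, 70/670,
    70/670 give exactly 530/70/70). The three parts are disjoint and
    exhaustive and identical across runs with the same seed.
    """
    fractions = tuple(float(f) for f in fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError(f"fractions must sum to 1, got {fractions}")
    if any(f < 0 for f in fractions):
        raise ValidationError("fractions must be non-negative")
    n = len(manifest)
    n_nonzero = sum(1 for f in fractions if f > 0)
    if n < n_nonzero:
        raise ValidationError(f"cannot split {n} items into {n_nonzero} non-empty parts")

    raw = [n * f for f in fractions]
    sizes = [int(np.floor(r)) for r in raw]
    remainders = [r - s for r, s in zip(raw, sizes)]
    for _ in range(n - sum(sizes)):
        i = int(np.argmax(remainders))
        sizes[i] += 1
        remainders[i] = -1.0
    order = np.random.default_rng(seed).permutation(n)
    bounds = np.cumsum([0] + sizes)
    names = ("train", "validation", "test")
    return {
        name: [manifest[j] for j in order[bounds[i] : bounds[i + 1]]]
        for i, name in enumerate(names)
    }
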
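"""Core image containers and file I/O.

A mammogram is a single-channel image whose detector typically delivers
14-bit data inside a 16-bit container; binary region masks (gland truth,
calculation region, pectoral muscle, vessels) live on the same pixel grid.
Masks are plain boolean numpy arrays throughout the package; this module
holds the :class:`Mammogram` container plus PNG/TIFF/DICOM readers and
writers for both.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "Mammogram",
    "ValidationError",
    "as_mask",
    "check_same_grid",
    "read_image",
    "read_mask",
    "write_image",
    "write_mask",
    "read_manifest",
    "write_manifest",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class Mammogram:
    """A single-channel mammographic image.

    Parameters
    ----------
    pixels : ndarray
        2-D array of non-negative intensities, ``(rows, cols)``.
    bit_depth : int
        Effective bit depth of the data (values lie in ``[0, 2**bit_depth)``),
        independent of the storage container width.
    laterality : str or None
        ``"left"`` or ``"right"``; which breast the image shows. ``None``
        when unknown.
    """

    pixels: np.ndarray
    bit_depth: int = 14
    laterality: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError(
                f"mammogram pixels must be 2-D, got shape {self.pixels.shape}"
            )
        if not (1 <= self.bit_depth <= 16):
            raise ValidationError(f"bit_depth must be in [1, 16], got {self.bit_depth}")
        if self.laterality not in (None, "left", "right"):
            raise ValidationError(f"laterality must be 'left'/'right'/None, got {self.laterality!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def max_value(self) -> int:
        """Largest representable intensity at this bit depth."""
        return (1 << self.bit_depth) - 1

    def with_pixels(self, pixels: np.ndarray, **changes) -> "Mammogram":
        return replace(self, pixels=pixels, **changes)


def as_mask(arr: np.ndarray) -> np.ndarray:
    """Coerce an array (bool, {0,1} or {0,255}) to a boolean mask."""
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValidationError(f"mask must be 2-D, got shape {arr.shape}")
    if arr.dtype == bool:
        return arr
    return arr > 0


def check_same_grid(*arrays: np.ndarray) -> None:
    shapes = {np.asarray(a).shape for a in arrays}
    if len(shapes) > 1:
        raise ValidationError(f"arrays are on different grids: {sorted(shapes)}")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def write_image(path: str | Path, image: Mammogram) -> None:
    """Write a mammogram as 8- or 16-bit grayscale PNG/TIFF.

    Data above 8 bits is stored value-ranged (not left-justified) in a
    16-bit container; the effective bit depth travels in the manifest.
    """
    path = Path(path)
    px = np.asarray(image.pixels)
    if image.bit_depth <= 8:
        Image.fromarray(px.astype(np.uint8), mode="L").save(path)
    else:
        Image.fromarray(px.astype(np.uint16)).save(path)


def read_image(
    path: str | Path, bit_depth: int | None = None, laterality: str | None = None
) -> Mammogram:
    """Read a grayscale PNG/TIFF (or DICOM if ``pydicom`` is installed)."""
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        return _read_dicom(path)
    img = Image.open(path)
    px = np.asarray(img)
    if px.ndim == 3:  # tolerate grayscale saved as RGB
        px = px[..., 0]
    if bit_depth is None:
        bit_depth = 8 if px.dtype == np.uint8 else 16
    return Mammogram(pixels=px, bit_depth=bit_depth, laterality=laterality)


def _read_dicom(path: Path) -> Mammogram:
    import pydicom

    ds = pydicom.dcmread(path)
    px = ds.pixel_array
    bits = int(getattr(ds, "BitsStored", 16))
    lat = getattr(ds, "ImageLaterality", getattr(ds, "Laterality", None))
    laterality = {"L": "left", "R": "right"}.get(lat, None)
    return Mammogram(pixels=px, bit_depth=bits, laterality=laterality)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG with values {0, 255}."""
    m = as_mask(mask)
    Image.fromarray((m.astype(np.uint8)) * 255, mode="L").save(Path(path))


def read_mask(path: str | Path) -> np.ndarray:
    px = np.asarray(Image.open(Path(path)).convert("L"))
    return px > 127


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

MANIFEST_FIELDS = [
    "image",
    "gland_mask",
    "calc_mask",
    "objective_mask",
    "corrected_mask",
    "laterality",
    "bit_depth",
    "ratio",
    "category",
    "seed",
]


def write_manifest(path: str | Path, rows: list[dict]) -> None:
    """Write a dataset manifest CSV (one row per image, paths + labels)."""
    path = Path(path)
    fields = list(rows[0].keys()) if rows else MANIFEST_FIELDS
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        writer.writerows(rows)


def read_manifest(path: str | Path) -> list[dict]:
    with open(Path(path), newline="") as fh:
        return list(csv.DictReader(fh))
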
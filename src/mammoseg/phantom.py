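"""Synthetic MLO-mammogram phantoms with exact ground truth.

Clinical mammograms cannot be redistributed, so every downstream stage is
exercised on generated phantoms that reproduce the coarse anatomy of a
mediolateral-oblique (MLO) view:

* a breast contour (half-ellipse against the chest-wall image edge, side
  set by laterality) over a near-zero background;
* a pectoral-muscle wedge in the upper chest-wall corner with gland-like
  brightness;
* a subcutaneous-fat rim just inside the contour;
* a gland region inside the calculation region whose area fraction is
  controlled exactly, textured as thresholded smoothed noise so that
  mid-range fractions break into scattered islands;
* thin bright vessel-like curves, and optional additive Gaussian noise.

Gland intensities are drawn at or above the pectoral mean, matching the
definition of gland tissue as density equal or greater than the pectoral
reference. Vessels are rendered only where they contrast with surrounding
fat (a vessel overlying dense gland is not a separable structure), which
keeps the emulated reader correction well-posed.

The *calculation region* — the denominator of the content ratio — is the
breast interior minus the fat rim and a margin around the pectoral wedge;
it is generated truth here (its delineation on clinical images is a
reading-protocol matter, out of scope).

:func:`emulate_correction` plays the reader's role on synthetic data: it
deletes every connected component of an objective threshold mask that is
not dominated by true gland, emulating the deletion of vessels, pectoral
leakage and other non-gland structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion, gaussian_filter, label

from .composition import CompositionLabel, classify_composition, content_ratio
from .images import (
    Mammogram,
    ValidationError,
    as_mask,
    check_same_grid,
    write_image,
    write_manifest,
    write_mask,
)

__all__ = [
    "PhantomSpec",
    "PhantomBundle",
    "generate_phantom",
    "emulate_correction",
    "save_bundle",
    "generate_dataset",
]

# Intensity plateaus as fractions of the full intensity scale. Gland sits
# strictly above the pectoral level; vessels are the brightest structures.
_BACKGROUND = 0.02
_FAT = 0.35
_RIM = 0.30
_PECTORAL = 0.55
_GLAND_BASE = 0.62
_GLAND_SPAN = 0.12
_VESSEL = 0.72


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic mammogram.

    ``target_content_ratio`` is the desired gland area as a fraction of the
    calculation region; 0 produces a gland-free ("unmasked") phantom.
    ``noise_sd`` is the standard deviation of additive Gaussian noise in
    intensity units of the chosen bit depth. Portrait orientation
    (height >= width) is required, as in MLO acquisition.
    """

    height: int = 256
    width: int = 184
    bit_depth: int = 14
    laterality: str = "left"
    target_content_ratio: float = 0.5
    vessel_count: int = 3
    noise_sd: float = 64.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_content_ratio <= 1.0):
            raise ValidationError(
                f"target_content_ratio must be in [0, 1], got {self.target_content_ratio}"
            )
        if self.height < self.width:
            raise ValidationError(
                f"portrait orientation required (height >= width), got {self.height}x{self.width}"
            )
        if self.height < 32 or self.width < 32:
            raise ValidationError("phantom must be at least 32x32")
        if not (8 <= self.bit_depth <= 16):
            raise ValidationError(f"bit_depth must be in [8, 16], got {self.bit_depth}")
        if self.laterality not in ("left", "right"):
            raise ValidationError(f"laterality must be 'left' or 'right', got {self.laterality!r}")
        if self.vessel_count < 0:
            raise ValidationError("vessel_count must be non-negative")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


@dataclass
class PhantomBundle:
    """A phantom image with its complete ground truth."""

    image: Mammogram
    gland_truth: np.ndarray
    calc_region: np.ndarray
    pectoral: np.ndarray
    vessels: np.ndarray
    label: CompositionLabel
    spec: PhantomSpec | None = field(default=None, repr=False)

    @property
    def measured_ratio(self) -> float:
        return content_ratio(self.gland_truth, self.calc_region)


def _breast_geometry(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Breast half-ellipse and pectoral wedge, chest wall at the left edge."""
    H, W = spec.height, spec.width
    y, x = np.mgrid[0:H, 0:W].astype(np.float64)
    cy, ay, ax = 0.48 * H, 0.46 * H, 0.88 * W
    breast = (x / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0
    # pectoral wedge: triangle spanning the top edge and the chest wall
    pect = (x / (0.38 * W) + y / (0.52 * H)) <= 1.0
    return breast, pect & breast


def _draw_vessels(
    rng: np.random.Generator,
    count: int,
    allowed: np.ndarray,
    forbidden: np.ndarray,
) -> np.ndarray:
    """Thin bright curves (quadratic Beziers) inside ``allowed``, carved
    away from ``forbidden`` (the dilated gland)."""
    H, W = allowed.shape
    vessels = np.zeros((H, W), dtype=bool)
    ys, xs = np.nonzero(allowed)
    if ys.size == 0 or count == 0:
        return vessels
    t = np.linspace(0.0, 1.0, 4 * (H + W))[:, None]
    for _ in range(count):
        picks = rng.integers(0, ys.size, size=3)
        p0, p1, p2 = (np.array([ys[i], xs[i]], dtype=np.float64) for i in picks)
        pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2
        rr = np.clip(np.round(pts[:, 0]).astype(int), 0, H - 1)
        cc = np.clip(np.round(pts[:, 1]).astype(int), 0, W - 1)
        curve = np.zeros((H, W), dtype=bool)
        curve[rr, cc] = True
        vessels |= binary_dilation(curve, np.ones((2, 2), dtype=bool))
    return vessels & allowed & ~forbidden


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Render one phantom. Deterministic for a fixed spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    scale = (1 << spec.bit_depth) - 1

    breast, pectoral = _breast_geometry(spec)

    rim_w = max(2, round(0.05 * W))
    interior = binary_erosion(breast, np.ones((2 * rim_w + 1, 2 * rim_w + 1), dtype=bool))
    rim = breast & ~interior
    margin = max(2, round(0.03 * W))
    calc_region = interior & ~binary_dilation(
        pectoral, np.ones((2 * margin + 1, 2 * margin + 1), dtype=bool)
    )
    if not calc_region.any():
        raise ValidationError("degenerate geometry: empty calculation region")

    # gland: smoothed noise field thresholded at the exact in-region quantile
    # so the area fraction hits the target
    ratio = spec.target_content_ratio
    field_sigma = 0.055 * min(H, W)
    g = gaussian_filter(rng.standard_normal((H, W)), sigma=field_sigma)
    if ratio <= 0.0:
        gland = np.zeros((H, W), dtype=bool)
    elif ratio >= 1.0:
        gland = calc_region.copy()
    else:
        q = float(np.quantile(g[calc_region], 1.0 - ratio))
        gland = calc_region & (g >= q)

    vessel_clearance = binary_dilation(gland, np.ones((5, 5), dtype=bool))
    vessels = _draw_vessels(rng, spec.vessel_count, interior, vessel_clearance)

    img = np.full((H, W), _BACKGROUND)
    img[rim] = _RIM
    img[interior] = _FAT
    img[pectoral] = _PECTORAL
    if gland.any():
        gq = float(np.quantile(g[calc_region], 1.0 - ratio)) if ratio < 1.0 else g[calc_region].min()
        span = float(g[gland].max() - gq) or 1.0
        img[gland] = _GLAND_BASE + _GLAND_SPAN * (g[gland] - gq) / span
    img[vessels] = _VESSEL
    img *= scale

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, scale).astype(np.uint16)

    if spec.laterality == "right":  # chest wall on the right edge
        pixels = pixels[:, ::-1].copy()
        gland = gland[:, ::-1].copy()
        calc_region = calc_region[:, ::-1].copy()
        pectoral = pectoral[:, ::-1].copy()
        vessels = vessels[:, ::-1].copy()

    mammo = Mammogram(pixels=pixels, bit_depth=spec.bit_depth, laterality=spec.laterality)
    measured = content_ratio(gland, calc_region)
    return PhantomBundle(
        image=mammo,
        gland_truth=gland,
        calc_region=calc_region,
        pectoral=pectoral,
        vessels=vessels,
        label=classify_composition(measured),
        spec=spec,
    )


def emulate_correction(
    objective_mask: np.ndarray, bundle: PhantomBundle, min_overlap: float = 0.5
) -> np.ndarray:
    """Emulated semi-subjective correction of an objective threshold mask.

    Every 8-connected component of ``objective_mask`` whose overlap with
    the bundle's true gland falls below ``min_overlap`` (as a fraction of
    the component's area) is deleted — the reader strikes out vessels,
    pectoral leakage and other bright non-gland structures as whole
    objects. The result is always a subset of the input mask.
    """
    objective_mask = as_mask(objective_mask)
    check_same_grid(objective_mask, bundle.gland_truth)
    if not (0.0 < min_overlap <= 1.0):
        raise ValidationError(f"min_overlap must be in (0, 1], got {min_overlap}")
    if not objective_mask.any():
        return objective_mask.copy()
    labels, n = label(objective_mask, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return objective_mask.copy()
    comp_area = np.bincount(labels.ravel(), minlength=n + 1)
    gland_area = np.bincount(
        labels.ravel(), weights=bundle.gland_truth.ravel(), minlength=n + 1
    )
    keep = np.zeros(n + 1, dtype=bool)
    nz = comp_area > 0
    keep[nz] = gland_area[nz] / comp_area[nz] >= min_overlap
    keep[0] = False
    return keep[labels]


# ---------------------------------------------------------------------------
# Dataset convenience
# ---------------------------------------------------------------------------

def save_bundle(out_dir: str | Path, stem: str, bundle: PhantomBundle) -> dict:
    """Write image + truth masks as PNGs; return a manifest row."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": f"{stem}_image.png",
        "gland_mask": f"{stem}_gland.png",
        "calc_mask": f"{stem}_calc.png",
        "pectoral_mask": f"{stem}_pectoral.png",
        "vessel_mask": f"{stem}_vessels.png",
    }
    write_image(out_dir / paths["image"], bundle.image)
    write_mask(out_dir / paths["gland_mask"], bundle.gland_truth)
    write_mask(out_dir / paths["calc_mask"], bundle.calc_region)
    write_mask(out_dir / paths["pectoral_mask"], bundle.pectoral)
    write_mask(out_dir / paths["vessel_mask"], bundle.vessels)
    row = dict(paths)
    row.update(
        laterality=bundle.image.laterality,
        bit_depth=bundle.image.bit_depth,
        ratio=f"{bundle.measured_ratio:.6f}",
        category=bundle.label.category,
        seed=bundle.spec.seed if bundle.spec else "",
    )
    return row


def generate_dataset(
    n: int,
    out_dir: str | Path | None = None,
    *,
    height: int = 256,
    width: int = 184,
    ratio_range: tuple[float, float] = (0.05, 0.95),
    unmasked_fraction: float = 0.02,
    vessel_count: int = 3,
    noise_sd: float = 64.0,
    seed: int = 0,
) -> list[PhantomBundle]:
    """Generate ``n`` phantoms with ratios drawn uniformly from
    ``ratio_range``, a small fraction gland-free, alternating laterality.

    When ``out_dir`` is given, images/masks and a ``manifest.csv`` are
    written there.
    """
    rng = np.random.default_rng(seed)
    bundles = []
    rows = []
    for i in range(n):
        unmasked = rng.random() < unmasked_fraction
        ratio = 0.0 if unmasked else float(rng.uniform(*ratio_range))
        spec = PhantomSpec(
            height=height,
            width=width,
            laterality="left" if i % 2 == 0 else "right",
            target_content_ratio=ratio,
            vessel_count=vessel_count,
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        bundle = generate_phantom(spec)
        bundles.append(bundle)
        if out_dir is not None:
            rows.append(save_bundle(out_dir, f"phantom_{i:04d}", bundle))
    if out_dir is not None:
        write_manifest(Path(out_dir) / "manifest.csv", rows)
    return bundles
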
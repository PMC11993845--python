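"""Mammary-gland content ratio and breast-composition classification.

Breast composition is graded from the mammary gland content ratio: the area
of gland-density tissue divided by the area of the region that could contain
gland (the *calculation region*, which excludes the pectoral muscle,
subcutaneous fat and the retromammary gap). Four categories are separated at
10%, 50% and 80% content; "fatty" and "scattered" together form the *fatty
breast* group, "heterogeneous dense" and "extremely dense" the *dense
breast* group (the group with reduced mammographic sensitivity).

Boundary convention: every band is lower-bound inclusive, so a ratio of
exactly 0.50 is "heterogeneous dense" (dense breast) and 0.80 is
"extremely dense". The guideline prose mixes "<50%" and ">50%" for the two
groups, leaving 0.50 formally unassigned; a single inclusive-lower rule,
mirroring the explicit ">=80%" band, resolves it consistently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .images import ValidationError, as_mask, check_same_grid

__all__ = [
    "CATEGORIES",
    "CompositionLabel",
    "content_ratio",
    "classify_composition",
]

#: Category names in increasing order of gland content.
CATEGORIES = ("fatty", "scattered", "heterogeneous_dense", "extremely_dense")

#: Lower band edges for CATEGORIES[1:], as content-ratio fractions.
_CUTOFFS = (0.10, 0.50, 0.80)


@dataclass(frozen=True)
class CompositionLabel:
    """A breast-composition grade.

    Attributes
    ----------
    category : str
        One of :data:`CATEGORIES`.
    grouping : str
        ``"fatty_breast"`` (fatty/scattered) or ``"dense_breast"``
        (heterogeneous/extremely dense).
    ratio : float
        The mammary gland content ratio the grade was derived from.
    """

    category: str
    grouping: str
    ratio: float

    @property
    def category_index(self) -> int:
        return CATEGORIES.index(self.category)


def content_ratio(gland: np.ndarray, calc_region: np.ndarray) -> float:
    """Mammary gland content ratio: ``area(gland ∩ calc) / area(calc)``.

    Parameters
    ----------
    gland : ndarray
        Binary gland-region mask. Pixels outside ``calc_region`` are
        ignored (the numerator is intersected with the denominator first).
    calc_region : ndarray
        Binary calculation-region mask; must be non-empty.
    """
    gland = as_mask(gland)
    calc_region = as_mask(calc_region)
    check_same_grid(gland, calc_region)
    denom = int(calc_region.sum())
    if denom == 0:
        raise ValidationError("calculation region is empty")
    return float((gland & calc_region).sum()) / denom


def classify_composition(ratio: float) -> CompositionLabel:
    """Map a content ratio in ``[0, 1]`` to a composition grade.

    Bands (lower-bound inclusive): ``<0.10`` fatty, ``[0.10, 0.50)``
    scattered, ``[0.50, 0.80)`` heterogeneous dense, ``>=0.80`` extremely
    dense.
    """
    ratio = float(ratio)
    if not (0.0 <= ratio <= 1.0) or not np.isfinite(ratio):
        raise ValidationError(f"content ratio must be in [0, 1], got {ratio}")
    idx = int(np.searchsorted(_CUTOFFS, ratio, side="right"))
    category = CATEGORIES[idx]
    grouping = "fatty_breast" if idx < 2 else "dense_breast"
    return CompositionLabel(category=category, grouping=grouping, ratio=ratio)
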
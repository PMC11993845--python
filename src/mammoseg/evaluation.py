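"""Dice-coefficient evaluation of extracted gland regions.

The extraction accuracy of a predicted gland mask Y against a ground-truth
mask X is the Dice coefficient

    Dice(X, Y) = 2 |X ∩ Y| / (|X| + |Y|),

computed over foreground pixels, in [0, 1]. Gland-free ("unmasked") truth
images are scored by the complement rule: the Dice of the *background*
regions of X and Y over the evaluation domain, so a prediction that is also
empty scores 1. Reports are stratified by breast composition and averaged
across training replicates, with overall means per replicate and pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition import CATEGORIES
from .images import ValidationError, as_mask, check_same_grid

__all__ = [
    "DiceReport",
    "dice",
    "dice_with_unmasked_rule",
    "stratified_report",
    "compare_truth_sources",
]

#: Column order of stratified report tables.
REPORT_COLUMNS = ["all", *CATEGORIES]


def dice(X: np.ndarray, Y: np.ndarray) -> float:
    """Dice coefficient ``2|X∩Y| / (|X|+|Y|)`` of two non-degenerate masks.

    Raises if both masks are empty; that case has no defined foreground
    overlap and is handled by :func:`dice_with_unmasked_rule`.
    """
    X = as_mask(X)
    Y = as_mask(Y)
    check_same_grid(X, Y)
    total = int(X.sum()) + int(Y.sum())
    if total == 0:
        raise ValidationError(
            "both masks are empty; use dice_with_unmasked_rule for gland-free truth"
        )
    return 2.0 * int((X & Y).sum()) / total


def dice_with_unmasked_rule(
    X: np.ndarray, Y: np.ndarray, evaluation_domain: np.ndarray | None = None
) -> tuple[float, bool]:
    """Dice with the gland-free complement rule.

    If the truth mask ``X`` has no foreground (an unmasked image), the
    score is the Dice of the two background regions within
    ``evaluation_domain`` (the full grid when None) and the returned flag
    is True. Otherwise the ordinary foreground Dice and False.
    """
    X = as_mask(X)
    Y = as_mask(Y)
    check_same_grid(X, Y)
    if X.any():
        return dice(X, Y), False
    if evaluation_domain is None:
        domain = np.ones_like(X, dtype=bool)
    else:
        domain = as_mask(evaluation_domain)
        check_same_grid(X, domain)
    return dice(~X & domain, ~Y & domain), True


@dataclass
class DiceReport:
    """Per-image Dice values with per-composition and overall aggregation.

    ``per_image`` has one row per (replicate, image): image id, replicate
    index, dice, category, unmasked flag. Categories absent from the input
    are reported as NaN, not zero.
    """

    per_image: pd.DataFrame
    per_category_mean: dict[str, float] = field(default_factory=dict)
    overall_mean: float = float("nan")
    replicate_means: list[float] = field(default_factory=list)

    def as_row(self) -> pd.Series:
        """Single table row: overall mean then one column per category."""
        data = {"all": self.overall_mean}
        for cat in CATEGORIES:
            data[cat] = self.per_category_mean.get(cat, float("nan"))
        return pd.Series(data)


def stratified_report(
    pairs: list[tuple[np.ndarray, np.ndarray, str]],
    replicates: int = 1,
    evaluation_domain: np.ndarray | None = None,
) -> DiceReport:
    """Score (truth, prediction, category) triples and aggregate.

    ``pairs`` lists all images of all replicates in replicate-major order:
    with ``replicates=r`` the first ``len(pairs)/r`` entries are replicate
    1, and so on. Per-image scores use the unmasked rule; category means
    pool images of a category across replicates; the overall mean pools
    everything.
    """
    if not pairs:
        raise ValidationError("no evaluation pairs supplied")
    if len(pairs) % replicates != 0:
        raise ValidationError(
            f"{len(pairs)} pairs do not divide into {replicates} replicates"
        )
    per_rep = len(pairs) // replicates
    records = []
    for i, (truth, pred, category) in enumerate(pairs):
        if category not in CATEGORIES:
            raise ValidationError(f"unknown composition category {category!r}")
        d, unmasked = dice_with_unmasked_rule(truth, pred, evaluation_domain)
        records.append(
            {
                "image": i % per_rep,
                "replicate": i // per_rep + 1,
                "dice": d,
                "category": category,
                "unmasked": unmasked,
            }
        )
    per_image = pd.DataFrame.from_records(records)
    per_category = {
        cat: float(g["dice"].mean())
        for cat, g in per_image.groupby("category", sort=False)
    }
    replicate_means = [
        float(g["dice"].mean()) for _, g in per_image.groupby("replicate", sort=True)
    ]
    return DiceReport(
        per_image=per_image,
        per_category_mean=per_category,
        overall_mean=float(per_image["dice"].mean()),
        replicate_means=replicate_means,
    )


def compare_truth_sources(
    report_corrected: DiceReport, report_objective: DiceReport
) -> pd.DataFrame:
    """Side-by-side table for corrected-truth vs objective-truth training.

    Both reports must score the same test images (same count and category
    breakdown); rows are the two truth sources, columns the overall mean
    followed by the per-composition means.
    """
    n_c = report_corrected.per_image.groupby("category")["image"].count()
    n_o = report_objective.per_image.groupby("category")["image"].count()
    if not n_c.equals(n_o):
        raise ValidationError(
            "test sets differ between the two reports; comparison is invalid"
        )
    table = pd.DataFrame(
        {
            "semi_subjective_corrected": report_corrected.as_row(),
            "objective_thresholding": report_objective.as_row(),
        }
    ).T
    return table[REPORT_COLUMNS]
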
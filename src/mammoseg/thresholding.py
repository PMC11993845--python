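"""Objective gland-region extraction by histogram thresholding.

The objective (reader-independent) gland mask is produced by thresholding
the intensities inside the calculation region. The threshold rule switches
on the modality of the in-region histogram: a single-peaked histogram is
thresholded by the maximum-entropy (Kapur-Sahoo-Wong) criterion, a
histogram with two or more peaks by discriminant analysis (Otsu's
between-class variance). Pixels at or above the threshold are foreground -
gland tissue is defined as density equal to or greater than the pectoral
muscle reference, so the comparison is inclusive.

The peak-detection rule, bin count and smoothing are not fixed by the
switching rule itself and are exposed as configuration
(:class:`PeakParams`); defaults are 256 uniform bins over the in-region
min-max range, a 5-bin moving average, and a prominence floor of 5% of the
histogram maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .images import Mammogram, ValidationError, as_mask, check_same_grid

__all__ = [
    "Histogram",
    "PeakParams",
    "ThresholdResult",
    "compute_histogram",
    "count_peaks",
    "max_entropy_threshold",
    "otsu_threshold",
    "select_threshold",
    "extract_objective_mask",
]


class EmptyRegionError(RuntimeError):
    """The calculation region contains no pixels (gland-free upstream case)."""


@dataclass(frozen=True)
class Histogram:
    """Intensity histogram of the pixels inside the calculation region.

    ``counts[i]`` is the number of in-region pixels whose intensity falls in
    the *i*-th of ``n_bins`` uniform bins partitioning ``[bin_lo, bin_hi]``
    (the last bin is closed on the right).
    """

    counts: np.ndarray
    bin_lo: float
    bin_hi: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.int64))
        if self.counts.ndim != 1 or self.counts.size < 2:
            raise ValidationError("histogram needs >= 2 bins")
        if np.any(self.counts < 0):
            raise ValidationError("histogram counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(self.bin_lo, self.bin_hi, self.n_bins + 1)


@dataclass(frozen=True)
class PeakParams:
    """Peak-detection configuration: moving-average window (bins) and
    minimum prominence as a fraction of the smoothed histogram maximum."""

    smooth_window: int = 5
    min_prominence: float = 0.05


@dataclass(frozen=True)
class ThresholdResult:
    """Chosen threshold, the method that produced it, and the peak count
    that selected the method (``max_entropy`` iff one peak)."""

    threshold: float
    method: str  # "max_entropy" | "discriminant"
    peak_count: int

    def __post_init__(self) -> None:
        if self.method not in ("max_entropy", "discriminant"):
            raise ValidationError(f"unknown method {self.method!r}")
        if (self.method == "max_entropy") != (self.peak_count == 1):
            raise ValidationError("method must be max_entropy iff peak_count == 1")


def compute_histogram(
    image: Mammogram,
    region: np.ndarray,
    n_bins: int = 256,
    value_range: tuple[float, float] | None = None,
) -> Histogram:
    """Histogram of the pixel values inside ``region``.

    Bins partition ``value_range`` uniformly; by default that is the
    in-region min-max range. Raises :class:`EmptyRegionError` for an
    empty region so callers can branch to the gland-free path rather than
    treat it as bad input.
    """
    region = as_mask(region)
    check_same_grid(image.pixels, region)
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    values = np.asarray(image.pixels)[region]
    if values.size == 0:
        raise EmptyRegionError("region contains no pixels")
    if value_range is None:
        lo, hi = float(values.min()), float(values.max())
    else:
        lo, hi = float(value_range[0]), float(value_range[1])
        if hi <= lo:
            raise ValidationError(f"invalid value range [{lo}, {hi}]")
    if hi == lo:  # constant region: widen to one representable step
        hi = lo + 1.0
    counts, _ = np.histogram(values, bins=n_bins, range=(lo, hi))
    return Histogram(counts=counts, bin_lo=lo, bin_hi=hi)


def count_peaks(hist: Histogram, params: PeakParams = PeakParams()) -> int:
    """Number of local maxima of the smoothed, max-normalised histogram
    with prominence at least ``params.min_prominence``.

    Plateau maxima (including boundary bins after smoothing) count once.
    Any histogram with mass has at least one peak.
    """
    counts = hist.counts.astype(np.float64)
    if counts.sum() == 0:
        raise ValidationError("histogram is empty")
    w = max(1, int(params.smooth_window))
    kernel = np.ones(w) / w
    smoothed = np.convolve(counts, kernel, mode="same")
    smoothed /= smoothed.max()
    # pad with zeros so maxima at the ends are detected with full prominence
    padded = np.concatenate([[0.0], smoothed, [0.0]])
    peaks, _ = find_peaks(padded, prominence=params.min_prominence)
    return max(1, int(peaks.size))


def _class_masses(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative below/above-threshold masses for every cut position t,
    where cut t puts bins [0, t) below and [t, n) above, t in 1..n-1."""
    p = counts.astype(np.float64)
    p /= p.sum()
    below = np.cumsum(p)[:-1]  # mass of bins [0, t) for t = 1..n-1
    above = 1.0 - below
    return below, above


def max_entropy_threshold(hist: Histogram) -> float:
    """Maximum-entropy (Kapur-Sahoo-Wong) threshold.

    Chooses the cut maximising the sum of Shannon entropies of the two
    class-normalised intensity distributions, with the convention
    ``0·log 0 = 0`` and natural logarithms. Candidate cuts are all bin
    boundaries with both classes non-empty; ties break to the smallest
    threshold. Returns the intensity at the chosen bin boundary.
    """
    counts = hist.counts.astype(np.float64)
    if np.count_nonzero(counts) < 2:
        raise ValidationError("max-entropy threshold needs >= 2 nonzero bins")
    p = counts / counts.sum()
    below, above = _class_masses(counts)

    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    cum_plogp = np.cumsum(plogp)[:-1]
    tot_plogp = plogp.sum()

    # H_below(t) = log w0 - S0/w0 ; H_above(t) = log w1 - S1/w1
    valid = (below > 0) & (above > 0)
    H = np.full(below.shape, -np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        h0 = np.log(below) - cum_plogp / below
        h1 = np.log(above) - (tot_plogp - cum_plogp) / above
    H[valid] = (h0 + h1)[valid]
    t = int(np.argmax(H)) + 1  # argmax returns the first (smallest) optimum
    return float(hist.bin_edges[t])


def otsu_threshold(hist: Histogram) -> float:
    """Discriminant-analysis (Otsu) threshold.

    Chooses the cut maximising the between-class variance
    ``w0·w1·(mu0 - mu1)^2``; ties break to the smallest threshold. Returns
    the intensity at the chosen bin boundary.

    The argmax is computed in exact integer arithmetic: with bin indices
    as abscissae (an affine rescaling of intensity, which leaves the
    argmax unchanged) the between-class variance is proportional to
    ``(M0*N1 - M1*N0)^2 / (N0*N1)`` with integer class counts N and
    first moments M, so candidate cuts are compared without round-off.
    """
    counts = [int(c) for c in hist.counts]
    if sum(1 for c in counts if c > 0) < 2:
        raise ValidationError("Otsu threshold needs >= 2 nonzero bins")
    n = len(counts)
    N = sum(counts)
    M = sum(i * c for i, c in enumerate(counts))
    best_t = None
    best_num, best_den = -1, 1  # compare num/den fractions exactly
    N0 = M0 = 0
    for t in range(1, n):
        N0 += counts[t - 1]
        M0 += (t - 1) * counts[t - 1]
        N1 = N - N0
        if N0 == 0 or N1 == 0:
            continue
        num = (M0 * N1 - (M - M0) * N0) ** 2
        den = N0 * N1
        if num * best_den > best_num * den:  # strict: keep smallest optimum
            best_num, best_den, best_t = num, den, t
    return float(hist.bin_edges[best_t])


def select_threshold(
    hist: Histogram, peak_params: PeakParams = PeakParams()
) -> ThresholdResult:
    """Peak-count-switched threshold selection.

    One histogram peak selects the maximum-entropy criterion; two or more
    peaks select discriminant analysis.
    """
    n_peaks = count_peaks(hist, peak_params)
    if n_peaks == 1:
        return ThresholdResult(
            threshold=max_entropy_threshold(hist), method="max_entropy", peak_count=1
        )
    return ThresholdResult(
        threshold=otsu_threshold(hist), method="discriminant", peak_count=n_peaks
    )


def extract_objective_mask(
    image: Mammogram, calc_region: np.ndarray, result: ThresholdResult
) -> np.ndarray:
    """Objective gland mask: in-region pixels with intensity >= threshold.

    The inclusive comparison reflects the definition of gland tissue as
    density equal to or greater than the pectoral-muscle reference. The
    returned mask is a subset of ``calc_region``.
    """
    calc_region = as_mask(calc_region)
    check_same_grid(image.pixels, calc_region)
    return (np.asarray(image.pixels) >= result.threshold) & calc_region
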
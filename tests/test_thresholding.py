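"""Histogram construction, peak counting, and the two threshold criteria.

Both threshold methods are checked exactly against brute-force scans that
evaluate the defining objective (total class entropy / between-class
variance) at every candidate cut.
"""

from fractions import Fraction

import numpy as np
import pytest

from mammoseg.images import Mammogram, ValidationError
from mammoseg.thresholding import (
    EmptyRegionError,
    Histogram,
    PeakParams,
    ThresholdResult,
    compute_histogram,
    count_peaks,
    extract_objective_mask,
    max_entropy_threshold,
    otsu_threshold,
    select_threshold,
)

# ---------------------------------------------------------------------------
# Brute-force oracles: direct evaluation of the defining objective at every
# candidate cut, ties broken to the smallest threshold.
# ---------------------------------------------------------------------------


def brute_force_max_entropy(hist: Histogram) -> float:
    p = hist.counts / hist.counts.sum()
    best_t, best_H = None, -np.inf
    for t in range(1, hist.n_bins):
        w0, w1 = p[:t].sum(), p[t:].sum()
        if w0 <= 0 or w1 <= 0:
            continue
        q0, q1 = p[:t] / w0, p[t:] / w1
        H = -sum(q * np.log(q) for q in q0 if q > 0) - sum(
            q * np.log(q) for q in q1 if q > 0
        )
        if H > best_H:
            best_H, best_t = H, t
    return float(hist.bin_edges[best_t])


def brute_force_otsu(hist: Histogram) -> float:
    """Direct evaluation of w0*w1*(mu0-mu1)^2 per cut, in exact rational
    arithmetic so near-ties are ordered correctly."""
    counts = [int(c) for c in hist.counts]
    total = sum(counts)
    best_t, best_v = None, Fraction(-1)
    for t in range(1, hist.n_bins):
        n0, n1 = sum(counts[:t]), sum(counts[t:])
        if n0 == 0 or n1 == 0:
            continue
        w0, w1 = Fraction(n0, total), Fraction(n1, total)
        mu0 = Fraction(sum(i * c for i, c in enumerate(counts[:t])), n0)
        mu1 = Fraction(sum(i * c for i, c in enumerate(counts) if i >= t), n1)
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return float(hist.bin_edges[best_t])


def random_histograms(n, rng, n_bins=64):
    out = []
    for _ in range(n):
        counts = rng.integers(0, 50, size=n_bins)
        if np.count_nonzero(counts) < 2:
            counts[:2] = 1
        out.append(Histogram(counts=counts, bin_lo=0.0, bin_hi=float(n_bins)))
    return out


def gaussian_counts(centers_sigmas, n_bins=128, amplitude=1000):
    x = np.arange(n_bins)
    counts = np.zeros(n_bins)
    for c, s, a in centers_sigmas:
        counts += a * amplitude * np.exp(-0.5 * ((x - c) / s) ** 2)
    return Histogram(counts=np.round(counts), bin_lo=0.0, bin_hi=float(n_bins))


# ---------------------------------------------------------------------------


class TestComputeHistogram:
    def test_constant_region_single_bin(self):
        img = Mammogram(np.full((8, 8), 1000, dtype=np.uint16), bit_depth=14)
        hist = compute_histogram(img, np.ones((8, 8), bool), n_bins=16)
        assert np.count_nonzero(hist.counts) == 1
        assert hist.counts.sum() == 64

    def test_direct_counting(self):
        px = np.zeros((2, 2), dtype=np.uint16)
        px.ravel()[:] = [1, 1, 3, 3]
        img = Mammogram(px, bit_depth=8)
        hist = compute_histogram(img, np.ones((2, 2), bool), n_bins=4)
        # default range [1, 3]: values 1 -> first bin, 3 -> last bin
        assert hist.counts.tolist() == [2, 0, 0, 2]
        hist = compute_histogram(img, np.ones((2, 2), bool), n_bins=4,
                                 value_range=(0, 4))
        assert hist.counts.tolist() == [0, 2, 0, 2]

    def test_count_conservation(self, rng):
        px = rng.integers(0, 2**14, size=(32, 32)).astype(np.uint16)
        region = rng.random((32, 32)) > 0.4
        hist = compute_histogram(Mammogram(px, bit_depth=14), region)
        assert hist.counts.sum() == region.sum()

    def test_empty_region_distinct_error(self):
        img = Mammogram(np.zeros((4, 4), dtype=np.uint16))
        with pytest.raises(EmptyRegionError):
            compute_histogram(img, np.zeros((4, 4), bool))


class TestCountPeaks:
    def test_unimodal(self):
        assert count_peaks(gaussian_counts([(64, 8, 1)])) == 1

    def test_bimodal_equal_height(self):
        assert count_peaks(gaussian_counts([(30, 5, 1), (100, 5, 1)])) == 2

    def test_minor_bump_below_prominence_floor(self):
        """A secondary bump under the prominence floor does not count."""
        hist = gaussian_counts([(30, 5, 1.0), (100, 4, 0.03)])
        assert count_peaks(hist, PeakParams(min_prominence=0.05)) == 1
        assert count_peaks(hist, PeakParams(min_prominence=0.01)) == 2

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            count_peaks(Histogram(np.zeros(8, dtype=int), 0.0, 8.0))


class TestThresholdOracles:
    def test_max_entropy_matches_brute_force(self, rng):
        for hist in random_histograms(50, rng):
            assert max_entropy_threshold(hist) == brute_force_max_entropy(hist)

    def test_otsu_matches_brute_force(self, rng):
        for hist in random_histograms(50, rng):
            assert otsu_threshold(hist) == brute_force_otsu(hist)

    def test_two_bin_histogram_separates(self):
        counts = np.zeros(32, dtype=int)
        counts[4], counts[20] = 10, 10
        hist = Histogram(counts, 0.0, 32.0)
        for thr in (max_entropy_threshold(hist), otsu_threshold(hist)):
            assert hist.bin_edges[5] <= thr <= hist.bin_edges[20]

    def test_symmetric_histogram_center_cut(self):
        hist = gaussian_counts([(40, 6, 1), (88, 6, 1)])
        assert otsu_threshold(hist) == brute_force_otsu(hist)
        assert abs(otsu_threshold(hist) - 64.0) <= 2.0

    def test_single_nonzero_bin_rejected(self):
        counts = np.zeros(8, dtype=int)
        counts[3] = 5
        hist = Histogram(counts, 0.0, 8.0)
        with pytest.raises(ValidationError):
            otsu_threshold(hist)
        with pytest.raises(ValidationError):
            max_entropy_threshold(hist)


class TestSelectThreshold:
    def test_switching_rule(self):
        uni = gaussian_counts([(64, 8, 1)])
        bi = gaussian_counts([(30, 5, 1), (100, 5, 1)])
        r_uni = select_threshold(uni)
        r_bi = select_threshold(bi)
        assert r_uni.method == "max_entropy" and r_uni.peak_count == 1
        assert r_bi.method == "discriminant" and r_bi.peak_count >= 2
        assert r_uni.threshold == max_entropy_threshold(uni)
        assert r_bi.threshold == otsu_threshold(bi)

    def test_method_is_pure_function_of_peak_count(self, rng):
        for hist in random_histograms(20, rng):
            result = select_threshold(hist)
            assert (result.method == "max_entropy") == (result.peak_count == 1)

    def test_inconsistent_result_rejected(self):
        with pytest.raises(ValidationError):
            ThresholdResult(threshold=1.0, method="max_entropy", peak_count=2)


class TestExtractMask:
    def test_boundary_thresholds(self, rng):
        px = rng.integers(100, 1000, size=(16, 16)).astype(np.uint16)
        img = Mammogram(px, bit_depth=14)
        region = np.ones((16, 16), bool)
        hi = ThresholdResult(float(px.max() + 1), "max_entropy", 1)
        lo = ThresholdResult(float(px.min()), "max_entropy", 1)
        assert not extract_objective_mask(img, region, hi).any()
        assert (extract_objective_mask(img, region, lo) == region).all()

    def test_monotone_mask_nesting(self, rng):
        px = rng.integers(0, 2**14, size=(24, 24)).astype(np.uint16)
        img = Mammogram(px, bit_depth=14)
        region = rng.random((24, 24)) > 0.3
        t1, t2 = 4000.0, 9000.0
        m1 = extract_objective_mask(img, region, ThresholdResult(t1, "max_entropy", 1))
        m2 = extract_objective_mask(img, region, ThresholdResult(t2, "max_entropy", 1))
        assert (m2 <= m1).all()
        assert (m1 <= region).all()

    def test_noise_free_phantom_recovers_bright_truth(self, midrange_bundle):
        """Objective extraction captures gland plus bright vessels."""
        from mammoseg.evaluation import dice

        b = midrange_bundle
        hist = compute_histogram(b.image, b.calc_region)
        mask = extract_objective_mask(b.image, b.calc_region, select_threshold(hist))
        truth = b.gland_truth | (b.vessels & b.calc_region)
        assert dice(mask, truth) >= 0.95
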
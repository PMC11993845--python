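# Methods

This note documents the models, algorithms and numerical choices behind
`mammoseg`, in the order the pipeline applies them.

## Problem setting

Breast composition on a mediolateral-oblique (MLO) mammogram is graded
from the *mammary gland content ratio*: the area of gland-density tissue
divided by the area of the breast region that could contain gland (the
*calculation region*, which excludes the pectoral muscle, subcutaneous fat
and the retromammary gap). Gland tissue is defined as density equal to or
greater than the pectoral-muscle reference. Four categories — fatty,
scattered, heterogeneous dense, extremely dense — are separated at 10%,
50% and 80% content; the upper two form the "dense breast" group.

A purely objective gland mask can be produced by thresholding, but it
wrongly includes vessels and pectoral leakage; a purely subjective reading
is quantitatively irreproducible. The pipeline follows the semi-subjective
protocol: threshold objectively, then delete non-gland structures, and use
the corrected masks as ground truth for a U-Net that learns to extract the
gland region directly.

## Objective thresholding

The histogram of intensities inside the calculation region (default 256
uniform bins over the in-region min–max range) is tested for modality:
counts are smoothed with a moving average (default 5 bins), max-normalised,
and local maxima with prominence ≥ 5% of the maximum are counted
(boundary maxima count via zero padding). One peak selects the
maximum-entropy criterion of Kapur–Sahoo–Wong — maximise
`H_below(t) + H_above(t)`, the Shannon entropies of the two class-normalised
distributions, with `0·log 0 = 0` and natural logarithms; two or more peaks
select discriminant analysis (Otsu) — maximise the between-class variance
`w0·w1·(μ0 − μ1)²`.

Numerics: candidate cuts are all bin boundaries with both classes
non-empty; ties break to the smallest threshold. The Otsu argmax is
evaluated in exact integer arithmetic — with bin indices as abscissae
(an affine change that leaves the argmax invariant) the objective is
proportional to `(M0·N1 − M1·N0)² / (N0·N1)` for integer class counts `N`
and first moments `M` — so near-ties cannot be misordered by round-off.
The entropy criterion is evaluated in floating point (`log w − S/w` per
class); exact entropy ties are a measure-zero event for empirical
histograms. The binary mask keeps in-region pixels with intensity **≥**
the threshold, matching the inclusive gland definition; bin count,
smoothing window, prominence floor and the comparison are configurable
because no part of the switching rule fixes them.

A constant (zero-variance) region yields a single-bin histogram, for which
both criteria are undefined; `compute_histogram` flags an empty region
with a distinct error so gland-free cases can take the unmasked path.

## Phantoms and the emulated reader

No public mammogram corpus with calculation-region truth exists, so every
stage is exercised on phantoms with exact ground truth. Geometry (portrait
frame, default 256×184 at 14 bits): a half-ellipse breast against the
chest-wall edge (side set by laterality); a triangular pectoral wedge in
the upper chest-wall corner; a subcutaneous-fat rim of ~5% of the width
just inside the contour. The calculation region is the breast interior
eroded by the rim, minus a ~3%-width margin around the pectoral wedge —
so `gland ⊆ calc` and `pectoral ∩ calc = ∅` hold by construction.

Intensity plateaus (fractions of full scale): background 0.02, rim 0.30,
fat 0.35, pectoral 0.55, gland 0.62–0.74, vessels 0.72. Gland therefore
always sits at or above the pectoral mean. Optional white Gaussian noise
(default SD 64 at 14 bits, ≈0.4% of range) is added last.

The gland is a smoothed Gaussian noise field (SD 5.5% of the short side)
thresholded **at the exact quantile** of its in-region values that yields
the requested area fraction — the closed form of a bisection on the field
threshold. Mid-range fractions then break into scattered islands, the
regime that is hardest for segmentation. Measured fractions land within
one pixel-quantile of the target (≪ the ±0.02 test band).

Vessels are quadratic Bézier curves through the breast interior, ~2 px
wide, drawn only where they contrast with surrounding fat: pixels within
2 px of gland are carved away, since a vessel overlying dense gland is not
a separable structure for a reader (and the objective mask cannot split
it). This keeps vessel segments at least two background pixels from gland.

`emulate_correction` plays the reader: every 8-connected component of the
objective mask whose gland-overlap fraction is below 0.5 (configurable) is
deleted whole — the reader strikes out structures, not pixels. The result
is always a subset of the input; a gland-free phantom loses everything,
reproducing the unmasked-image path.

What the phantoms do *not* emulate: X-ray physics, tissue texture,
compression artefacts, pathology, and the real delineation of the
calculation region. Passing tests demonstrate that the pipeline's
machinery is correct and that its statistical behaviour (truth-source
ordering, composition stratification) has the expected direction on
controlled data — not clinical performance.

## Preprocessing, orientation, splits

Intensities are rescaled linearly from the source bit range to the target
range (default 14→8 bits, i.e. ×255/16383 — range scaling, not bit
truncation); the portrait frame is padded equally on both lateral edges to
a square (pad widths differ by ≤1 px; pad value 0) and resized to the
network size with nearest-neighbour interpolation. Padding precedes
resizing so the aspect ratio is preserved; both the order and the pad
value are configurable since neither is forced by the pipeline. Masks
take the same pad/resize without the intensity step and remain binary.

Orientation variants: (1) every image chest-wall-left; (2) anatomical
(left breast faces left); (3)/(4) = (1)/(2) plus an independent seeded
horizontal flip per image with probability 0.5 (configurable). Image and
mask always flip together. Missing laterality raises for the anatomical
modes and is inferred from intensity mass (with a warning) for the aligned
modes. Splits use largest-remainder rounding of `n·fractions`, so 670
images at fractions 530/670, 70/670, 70/670 give exactly 530/70/70.

## Segmentation network

The canonical U-Net: per level two 3×3 same-padding convolutions, each
followed by batch normalisation and ReLU; 2×2 max pooling between encoder
levels; 2×2-stride-2 transposed convolutions and skip concatenation in the
decoder; a 1×1 convolution head producing per-pixel foreground logits.
Kernels start at `base_kernels` (64 in the full-scale grid) and double per
level; `depth` counts poolings, so input size must be divisible by
`2^depth`. The grid spans depth {3…7} × learning rate {0.001, 0.0001} ×
batch size {16, 32} — 20 cells, each trained in triplicate with
deterministic per-replicate seeds.

Because no autodiff backend is a dependency, forward and backward passes
are written directly in numpy (float32 NHWC; convolutions as nine
shifted-slice GEMMs; exact argmax gradients through pooling). Gradient
correctness is verified against finite differences in the test suite.

Training choices (all configurable):

* **Loss**: binary cross-entropy summed over the pixels of each image and
  averaged over the batch — the classic fully-convolutional convention,
  under which a quoted learning rate refers to whole-image gradients. A
  soft-Dice loss is available. With a per-pixel-*mean* loss and an
  adaptive optimiser, the short schedules used here (tens of updates)
  bound total parameter movement by `lr × steps` and cannot leave
  initialisation; the image-sum convention gives the stated rates a
  useful effective scale.
* **Optimiser**: SGD with momentum 0.9 (Adam available). The nominal
  learning rate anneals linearly to 10% of its starting value over the
  epochs (a constant schedule is available); the late small steps settle
  the run near a solution instead of oscillating, which stabilises both
  the final model and the best-epoch selection.
* **Initialisation**: He-normal everywhere except the head, which starts
  at exactly zero so training begins from an unbiased probability of 0.5
  at every pixel.
* **Checkpointing**: validation Dice (computed with the unmasked rule)
  after every epoch; the weights of the best epoch are kept. SGD at these
  effective rates is noisy, and best-epoch selection, not the final
  epoch, is the estimator.
* **Binarisation**: probability ≥ 0.5 (configurable).

## Evaluation

`Dice(X, Y) = 2|X∩Y| / (|X|+|Y|)` over foreground pixels, in [0, 1]. For
a gland-free truth mask the complement rule scores the *background*
agreement over the evaluation domain (default: the whole padded frame;
restrictable), so an empty prediction scores 1. Masks are compared at
network resolution. Reports stratify per-image scores by composition
category (absent categories are reported as missing, not zero), pool
across replicates by default, and the corrected-vs-objective comparison
emits the two-row table (overall + per-category means) for models trained
on each truth source and evaluated against corrected truth.

## Desk-scale experiment

The package's canonical end-to-end experiment (also what
`scripts/acceptance.py` runs) uses 100 phantoms of 128×92 px (60 train /
20 validation / 20 test) at network size 128×128, one grid cell — depth 3,
learning rate 1e-4, batch 16 — with 8 base kernels, 20 epochs and three
replicates per truth source. These sizes keep a full double experiment
(six training runs) within roughly a quarter of an hour on one CPU core
while leaving the architecture, the doubling rule and the training
protocol identical to the full-scale design. Larger widths and the full
20-cell grid run unchanged through the same code when more compute is
available.

## Known limitations

* Phantom realism is deliberately minimal (flat plateaus + noise); texture
  confounds of real parenchyma are absent, so absolute Dice values on
  phantoms exceed what clinical data would yield.
* The numpy backend is CPU-bound; full-scale (256×256, base 64, 20-cell
  grid) training is out of desk-scale reach and would want a GPU backend.
* The emulated reader is component-wise and truth-driven; it cannot model
  reader variability or partial deletions.
* Peak counting on noise-free synthetic histograms can be sensitive to the
  prominence floor when one class is a single spike; the floor is exposed
  as configuration.
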
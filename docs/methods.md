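# Methods

This note documents the models, numerical conventions and design choices
behind `psmagtv`, in the spirit of a statistical-software methods appendix.

## Spatial model

All images live on a regular 3D grid with anisotropic spacing in mm
(default 2.34 × 2.34 × 2.78 mm, a typical PET reconstruction matrix for
pelvic PSMA imaging). Voxel indices are 0-based; a voxel is identified with
its centre at `origin + index · spacing`, and every distance is a distance
between voxel centres. Cross-image operations require *compatible* grids
(equal shape and spacing, origins within 1e-6 mm); the package never
resamples — the simulated modalities are inherently co-registered, as they
are on a simultaneous PET/MR acquisition. Connected components default to
26-connectivity (the most permissive 3D neighbourhood).

## Phantom

The phantom emulates a [68Ga]-PSMA pelvic PET acquisition:

| parameter | default | rationale |
|---|---|---|
| grid | 96 × 96 × 48 @ 2.34 × 2.34 × 2.78 mm | PET matrix covering the pelvis |
| prostate | ellipsoid, radii (22, 19, 17) mm | ≈ 30 ml gland |
| lesion(s) | 1 sphere, radius U(5, 8) mm, strictly inside the gland | dominant intraprostatic lesion, ≈ 0.5–2 ml |
| Gleason-3 rim | 1-voxel dilation of the lesion ∩ prostate | grade heterogeneity around high-grade cores |
| uptake (SUV) | background 0.5, benign 2, rim 4, lesion 8, bladder 20 | moderate tumour-to-background typical of [68Ga]-PSMA; renally excreted tracer pools in urine |
| PSF FWHM | 5 mm | scanner intrinsic resolution combined with ~3 mm Gaussian post-filtering |
| noise | σ = 0.25·√(blurred SUV), clipped at 0 | Poisson-like surrogate for OSEM images, ≈ 18 % CoV at SUV 2 |
| bladder | ellipsoid radii (18, 16, 15) mm, hot lumen 8 mm from the prostate surface along the anterior-superior direction | the bladder wall and neck separate the urine pool from prostate tissue; see below |

The noiseless piecewise-constant uptake map is convolved with the Gaussian
PSF (replicate edge padding, which conserves total activity to ≪ 0.5 % for
structures ≥ 3 FWHM from the grid edge), then voxelwise noise is added and
negatives are clipped. With FWHM → 0 and noise 0 the output equals the
piecewise map exactly.

**Bladder standoff.** The hot lumen is placed 8 mm from the prostate
surface. With the lumen directly abutting the gland, PSF spill-in exceeds
the lesion maximum inside the 2-voxel analysis margin in roughly a third of
random geometries, so SUVmax — the anchor for relative thresholds and
component selection — would be a bladder artefact in most cases rather than
the rare failure it is clinically. The 8 mm standoff (anatomically, the
bladder wall plus neck between urine and glandular tissue) keeps the
hot-bladder failure mode present (unremoved bladder voxels inside the crop
still dominate SUVmax) without making spill-in the norm. `bladder_gap_mm`
is configurable, including 0.

**Randomness.** One integer seed feeds independent child streams (geometry,
noise, one per observer) via seed-sequence spawning, so changing the number
of observers never perturbs the phantom, and all outputs are bit-reproducible.

**Observers.** Each simulated observer keeps every lesion voxel with
probability p (default 0.85) and marks every non-lesion voxel of the
decision region (the prostate) with probability 1 − q (default q = 0.99),
independently per voxel. Defaults give a pooled pairwise interobserver Dice
around 0.6–0.7, the moderate agreement reported for experienced
delineators. The voxel-independence assumption makes the error spatially
unstructured — real observers err in connected boundary regions — so STAPLE
sees a somewhat easier problem than in clinical data; an optional
morphological boundary jitter (default off, since it biases the empirical
(p, q) away from their nominal values) can add spatial structure.

## Pre-processing

The "prostate with a 2-pixel margin" trim is interpreted in 3D and applied
twice over: the crop box is the prostate bounding box expanded by the
margin (clipped at the grid), and the eligibility mask is the prostate
dilated by the margin in the chessboard metric. Bladder removal deletes
bladder voxels from the eligibility mask *and* zeroes their SUV, so
window-based operators (the adaptive threshold) and histograms never see
bladder activity. SUVmax for the relative methods is taken over the
eligibility mask of the pre-processed region.

## Segmentation operators

All comparisons are strict (`>`): a cut at or above the regional maximum
legally produces an empty GTV, which is recorded (not raised) and enters
the report as missing FDR/HD95 with zero DSC/coverage/volume.

* **Absolute/relative thresholds.** Relative thresholds delegate to the
  absolute operator at `fraction × SUVmax`, so the two families agree
  bit-for-bit by construction. Default component policy keeps only the
  26-connected component containing the SUVmax voxel (ties broken at the
  lowest lexicographic index); this preserves nesting across the cut ladder
  and anchors the GTV at the hottest focus. `all`/`none` are available.
* **Adaptive threshold.** Processed per axial slice (PET axial resolution
  differs from in-plane): local mean m(x) by box filter over a square
  window of side `2·floor(max(in-plane dims)/16) + 1` with replicate
  padding; tumour iff `SUV > m(x) · (1 + 0.3·(0.5 − S))`, S ∈ [0, 0.5]. The
  mapping makes S = 0.5 exactly "threshold at the local mean" and S = 0 the
  most conservative cut, with masks nested and non-decreasing in S. The
  clinical original used a proprietary toolbox whose formula is unpublished;
  numerical parity with it is explicitly not claimed. Numerics: slices are
  centred on their mean before filtering (a constant slice then yields its
  exact value, keeping the strict comparison empty) and the local mean is
  clamped at 0 (exact for non-negative data; removes −1e-18-type float
  noise on zero background).
* **Multi-level Otsu.** Histogram of the eligibility-mask voxels only, 128
  uniform bins on [0, SUVmax]; exhaustive search over all increasing
  bin-boundary tuples maximizing the between-class variance
  Σ_k ω_k (μ_k − μ)²; the GTV is the top class; realized thresholds are
  reported as bin upper edges in SUV units. Ties (common when empty bins
  separate clusters, making several tuples induce the same partition) are
  broken toward the lowest tuple, with a relative 1e-10 near-tie tolerance
  so that float-identical partitions collapse deterministically; the test
  oracle applies the same rule via independent per-tuple summation.

## STAPLE

Standard binary STAPLE with a fixed prior γ (the mean rater foreground
fraction over the evaluation region unless supplied), initial
p = q = 0.99999, convergence when `max_j (|Δp_j| + |Δq_j|) < 1e-7`, at most
100 iterations. The observed-data log-likelihood is recorded per iteration
and is non-decreasing (EM guarantee; tests allow −1e-9 float slack).
Because specificity estimates are diluted by vast empty background, the EM
runs by default over the bounding box of the union of rater masks dilated
by 5 voxels (`region="full"` overrides). Posterior ties at exactly 0.5 are
included in the consensus. Interobserver agreement is reported as *pooled*
pairwise Dice (intersections and sizes summed over all unordered pairs
before dividing); mean-of-pairwise is provided as an alternative.

## Metrics

Gleason-3 (exclusion) voxels are deleted from the prediction before every
count in DSC and FDR — neither credited nor penalized; coverage and volume
ratio use raw positive counts (exclusion is disjoint from positive by
construction). HD95 uses boundary voxels (≥ 1 six-neighbour outside the
mask, with the grid edge counting as outside), an exact anisotropic
Euclidean distance transform, directed 95th percentiles by linear
interpolation of order statistics, and the max of the two directions. For
speed both masks are cropped to their union bounding box first, which is
exact because all boundary voxels of both masks lie inside the crop.
Empty-prediction conventions: DSC = coverage = volume ratio = 0; FDR and
HD95 missing; missing values are dropped from medians with the count
reported.

## Statistics

Quantiles use linear interpolation at `p·(n−1)` (the common scientific
default). The Wilcoxon signed-rank test drops zero differences, average-
ranks ties in |d|, and reports `W = min(W⁺, W⁻)` with a two-sided p that is
exact for n ≤ 25 tie-free inputs (computed from the full null distribution
of rank sums, identical to enumerating all 2ⁿ sign assignments) and a
normal approximation with tie and continuity corrections otherwise. The
per-method test pairs GTV volumes in ml with the per-case reference volumes
at α = 0.05, two-sided; the rendered table stars rows with *no* significant
volume difference.

## Problem sizes and runtime

The default study runs 20 phantom cases (≈ 450k voxels each) through all 14
method variants in well under a minute on one CPU; oracle tests use volumes
of ≤ 2,000 voxels (Otsu, metrics), ≤ 200 boundary voxels (HD95) and a
50,000-voxel region (STAPLE recovery), sizes at which exhaustive
enumeration is exact and fast.

## What passing tests do and do not show

The phantom's contrast (lesion 8 vs benign 2) and unstructured noise make
absolute/relative thresholding and STAPLE considerably more accurate than
the published clinical experience (e.g. DSC near 1 at SUV > 4, versus ~0.4
against real histopathology): validation here demonstrates correctness of
the operators and the expected *qualitative* ordering — coverage and volume
ratio fall monotonically along the cut ladder, low cuts trade high coverage
for high FDR, the adaptive method at S = 0 over-segments — not clinical
performance. Two known phantom-specific departures: the adaptive method
over-segments by scattering false positives (low coverage) rather than by
inflating a high-coverage region, because at the cropped prostate size its
auto-window is very small (3 px) and the lesion interior is locally flat;
and the Gleason-3 rim absorbs most boundary over-segmentation, pushing FDR
at high cuts to ~0. Registration error between histology and PET — a major
uncertainty in the clinical comparison — is not modelled: reference masks
are emitted directly on the PET grid.
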
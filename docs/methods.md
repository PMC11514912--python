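# Methods

## Geometric model

The blastocyst is modelled as a rigid sphere Ω of centre *O* and diameter
*D*, measured once from the mid-plane image. Views are orthographic: an
in-disk pixel at offset (u, v) µm from *O* back-projects to the unique
camera-facing surface point (u, v, +√(R²−u²−v²)). Orthography is an
idealisation of the real imaging geometry (the microscope refocuses below
the mid-plane until TE cells are sharp), but all quantities measured here
are surface properties, which an orthographic surface view preserves while
keeping the inverse mapping closed-form. Translation and scale between
views are fixed by the holding pipette and the single cropping step, so
the inter-view transformation is a pure rotation about *O*; the embryo is
assumed rigid over the minutes of rotation. Non-spherical (collapsing,
hatching) morphologies are out of scope.

Surface maps use an equirectangular latitude/longitude grid, default
256×512 (a config knob; the pipeline holds its accuracy contract at
128×256 as well). The polar axis is the image vertical, so rotation about
the pipette axis sweeps longitude. Bin areas are exact:
R²·Δλ·(sin φ_top − sin φ_bottom); their sum is 4πR² = πD² to machine
precision for any grid shape.

## Synthetic ground truth

The generator is the study-conditions oracle for the whole pipeline.

* **TE tessellation.** TE generator sites outside a polar cap and a
  cluster of "ICM sites" inside it form one spherical Voronoi partition;
  areas are exact spherical-polygon areas. The ICM region is the union of
  the ICM-site cells, so the partition identity
  Σ TE areas + ICM area = πD² holds exactly, and the stored ICM
  half-angle is the equivalent-cap angle of the realized ICM area (making
  the cap identity exact as well). The cap used for sampling is
  calibrated in a few fixed-point steps so the realized ICM area tracks
  the requested one to within a few percent; the realized value is the
  recorded truth.
* **Cell-size dispersion.** The coefficient of variation of TE areas is
  driven into ±0.05 of the requested target: Lloyd steps (sites toward
  cell centroids) lower the CV, small steps toward the nearest
  neighbouring site raise it; after 200 iterations the best-achieved CV
  is recorded with a warning instead of failing. No distributional form
  for cell areas is claimed in the grading literature; Voronoi cells of
  relaxed/clustered points are the minimal neutral model.
* **Rendering.** Camera-facing hemisphere, Lambertian shading ∝ z/R, dark
  geodesic boundary curves (configurable width and darkness), weak
  per-cell albedo contrast, a per-cell brightness dome, and a
  surface-attached multi-scale speckle field (≈1,500 Gaussian spots,
  σ 1–6 µm, ±25% amplitude) emulating granular cytoplasmic texture — the
  texture feature matching locks onto. The ICM renders as a uniformly
  darkened cap with no internal detail. Masks carry the exact per-pixel
  label (globally unique cell ids); boundary ribbons in masks are
  optional and default off. Default pixel scale is 0.5 µm/px, typical of
  40× embryo microscopy. The default 12-view protocol (30° steps, ±jitter
  if requested) satisfies the imaging guideline of more than 10 views
  with steps under 35°; steps ≥90° are rejected since adjacent
  hemispheres would not overlap.
* **What the renderer does not emulate.** Zona pellucida, blastocoel
  fluid, optical blur and depth-of-field, refraction, debris, or
  non-rigid motion. Passing recovery tests therefore demonstrates the
  correctness of the geometry/registration/measurement chain, not
  robustness to every optical artefact of clinical imaging.
* **Feature tables.** Class-conditional moments default to the published
  euploid/non-euploid cohort values (euploid fraction 0.571; TE count
  141.3±38.5 vs 68.3±27.1, etc.). Diameter and ICM area are truncated
  normals (floors 120 µm and 0), TE count a truncated normal rounded to
  integer (floor 8), size variance a moment-matched lognormal — chosen
  over a normal because the non-euploid class SD (937 at mean 795) forces
  strong right skew. Density is the deterministic ratio
  1000·N/(πD²), reproducing the collinearity present in real data.

## Registration

Local features are skimage SIFT (detection threshold lowered to pick up
speckle detail), matched with a Lowe ratio test (0.75) and cross-check.
Matched keypoints are back-projected to 3D; keypoints within 5° of the
limb are discarded because ∂z/∂r diverges there. RANSAC samples two pairs
per hypothesis and solves the exact two-point rotation via orthonormal
triads; the consensus set is refit by the SVD orthogonal-Procrustes
solution with det = +1 enforced, then refined coarse-to-fine by
tightening the residual gate (2° → 1° → 0.5°), which halves the
accumulated chain drift. Global frames are chained from adjacent-pair
rotations (G₀ = I, G_{i+1} = G_i·P_i⁻¹). On noiseless synthetic
sequences every global rotation lands within 0.5° of truth; with 2%
intensity noise single pairs stay within 2°. RANSAC is seeded from
config; the whole pipeline is deterministic given its seeds.

## Stitching and region extraction

Every in-disk pixel (split 2×2 into sub-pixels to close coverage gaps) is
deposited into its lat/lon bin with weight cos θ (viewing angle). Within
a view the bin is represented by the deposit nearest the bin centre —
using the maximum-weight deposit instead biases boundary bins toward
whichever side faces the camera axis. Across views the bin keeps the
highest-weight representative; ties break to the lower view index, which
also makes re-projection of the same view idempotent. Bins near the two
rotation-axis poles are smaller than a pixel and may stay unobserved;
area-weighted coverage of a 12-view session exceeds 99%, and remaining
holes (plus optional boundary ribbons) are absorbed by an iterative
nearest-neighbour label fill before measurement.

Connected components run on the sphere topology: longitude column 0 is
adjacent to the last column, and all same-label bins in an extreme
latitude row meet at the pole. Two mask conventions are supported and
must not be mixed: with globally unique cell ids (ground truth, external
whole-embryo segmentations) fragments sharing an id are one cell, which
immunises the count and the size SD against hairline stitching seams;
with per-view segmentations ids are view-local, so cell labels collapse
to a generic interior class separated by boundary ribbons and cells are
deduplicated purely by connectivity. A minimum-region floor (10 µm²,
config) suppresses slivers.

## Morphometry

Diameter: rim pixels by gradient thresholding, algebraic Taubin circle
fit, then two rounds of sub-pixel refinement locating the per-ray
intensity minimum of the dark rim by parabolic interpolation (the raw
gradient peak sits on the inner slope of the rim and biases D low by
~1%). Density uses the full sphere surface πD² as denominator — the
definition "cells per 1,000 µm²" admits either the full sphere or the
TE-only area, and the full-sphere choice reproduces the published cohort
means arithmetically (110 cells at D = 183.9 µm gives 1.04 ≈ 1.1); this
is an inference, config-exposed, not a claim about the original
implementation. Size variance is the sample SD (n−1; SPSS convention,
toggleable). ICM area is the spherical surface area of the largest
ICM-labelled region (whether the original study measured spherical or
projected planar ICM area is not stated; spherical area is consistent
with measuring on the 3D surface model, and the choice is flagged here).
Missing ICM is an error distinct from area zero.

On ten random synthetic blastocysts (TE count 60–160, D 150–220 µm, CV
0.2–0.6, ICM 4,000–8,000 µm², twelve noiseless views, truth masks) the
full pipeline recovers all five parameters with maximum relative error
under 6.7% — typically ≤1.5% with the TE count exact; the binding
constraint is the ICM area when the ICM sits near a rotation pole. These
problem sizes were chosen to represent the Day-6 cohort scale while
keeping a desk-scale runtime (~10–20 s per blastocyst on one CPU).

## Segmentation

The learned segmenter of the original study is a separately published
artefact; here a classical, deterministic operator covers the synthetic
reproduction path, and a strict external-mask contract (label-alphabet
mapping, shape validation) ingests masks from any segmenter. The
classical pipeline divides out the geometric Lambert shading, enhances
dark ridges (Sato tubeness), hysteresis-thresholds them into a boundary
skeleton, closes cells by watershed seeded from h-maxima of the interior
distance field, and detects the ICM as the largest dark region passing
size (≥6% of the disk) and compactness (solidity ≥0.7) gates — keyed to
darkness and compactness because the ICM images as a featureless compact
mass. On noiseless renders the boundary skeleton reaches a tolerant
(1-px) Dice ≥0.9 against truth and exact core cell counts; at 2% noise
Dice stays ≥0.8. Per-view segmentation before projection is the default
order; segmenting the stitched intensity map is also possible through
the same operators.

## Statistics

Univariate associations are single-predictor logistic regressions; OR =
exp(β) with Wald 95% CIs (β ± 1.96·SE) and two-tailed Wald p, matching
the SPSS output convention. Perfect separation returns a flagged
infinite-OR sentinel rather than raising. Multivariate selection is
forward stepwise with likelihood-ratio entry/removal (enter 0.05, remove
0.10 — the "Forward: LR" analogue; the source names only "forward
stepwise"), reporting adjusted ORs from the final model and echoing
unselected features as aOR 1.000. A repeated-state guard terminates
entry/removal cycles. The t test defaults to Welch (toggle to pooled);
chi-squared is Pearson without continuity correction; correlation is
product-moment with the t-approximation p. All tests are two-tailed.

## Prediction and evaluation

The rule classifier applies the printed thresholds verbatim: euploid iff
TE count > 94, or size variance ≤ 478 µm² (inclusive) and ICM area >
8007 µm² (exclusive). The thresholds are taken as given constants — the
exact decision-tree hyperparameters behind them are unpublished — and
are config-overridable.

The benchmark harness stratifies an 80/20 split (20% of 226 is 45
specimens), tunes each of the six models over a small documented grid
(≤24 combinations) by mean 5-fold validation AUC (k is unstated in the
source; 5 is the common default), refits on the full training set, and
operates at the ROC threshold closest to (0, 1) with ties toward higher
specificity. Closest-to-(0,1) and Youden's index are both described in
the literature for this step and coincide only sometimes; closest-to-
(0,1) is the default with a Youden alternative available via the same
enumeration. Proportion metrics carry exact Clopper–Pearson 95% CIs
(they reproduce the published intervals for 43/45 and 25/26 exactly);
the AUC is the Mann–Whitney statistic with a DeLong
structural-components variance and logit-transformed CI. DeLong's paired
test, exact-binomial McNemar, and permutation importance (mean AUC drop,
uniform across model types) complete the evaluation. The original
train/test split seed is unknowable, so published point metrics are not
equality targets; the harness reports distributions over seeds, on which
the tree-based models consistently reach high AUC for cohort-style
synthetic tables.

## Numerical and degenerate-input choices

Rotations are validated orthogonal with det = +1 (1e-9); serialized as
quaternions. Zero-variance t tests with equal means return p = 1 by
convention; identical paired scores give DeLong p = 1; constant scores
make the ROC threshold an error (no discrimination). Variance of fewer
than two cell areas is an error; a missing ICM is an error distinct from
area 0. Feature tables reject unknown ploidy strings, missing values and
non-integer TE counts, and normalize ploidy case-insensitively
(euploid = 1; mosaic and aneuploid pool to 0).

## Known limitations

Day-5 or early-stage blastocysts (smaller, partially expanded) are not
modelled. The renderer's idealisations listed above mean classical-
segmentation accuracy on real micrographs will be worse than on synthetic
renders; the external-mask contract exists precisely so a stronger
segmenter can be substituted without touching the measurement chain.
Statistics on synthetic tables validate the machinery and its contracts,
not the clinical effect sizes, which require the original cohort data.
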
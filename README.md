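# blastomorph

Quantitative 3D morphometry of human blastocysts from rotational
multi-view microscopy, and interpretable prediction of euploidy from the
measured parameters.

## The problem

Embryo selection in IVF relies on morphology, but conventional grading is
qualitative and a single 2D image misses most of the trophectoderm (TE):
the blastocyst is a sphere, and cell counts or inner-cell-mass (ICM) size
read off one view depend on orientation. During the preparation stage of
a TE biopsy the embryologist can rotate the blastocyst with a
micropipette, capturing more than 10 overlapping views (steps below 35°)
per full revolution plus one mid-plane image. `blastomorph` turns such a
sequence into five quantitative 3D parameters:

* **blastocyst diameter** *D* (µm) — from a Taubin circle fit to the
  mid-plane rim;
* **TE cell number** *N* — each cell counted once on the stitched sphere;
* **TE cell density** — cells per 1,000 µm², computed as
  `1000·N / (π·D²)`;
* **TE cell size variance** — the standard deviation (n−1) of the
  individual TE cell surface areas (µm²);
* **ICM area** (µm²) — spherical surface area of the segmented ICM.

The pipeline: the mid-plane image fixes the sphere Ω (centre *O*,
diameter *D*); every view is cropped to *D*×*D* around *O*; SIFT features
matched between adjacent views are back-projected through the orthographic
sphere model and a robust two-point RANSAC + orthogonal-Procrustes (Kabsch)
fit yields the inter-view rotation matrices; all views are projected onto
an equirectangular latitude/longitude map of Ω (weight = cosine of the
viewing angle, hard argmax blending); connected regions on the sphere —
longitude wraps, poles identified — give the per-cell areas.

Downstream, the package reproduces the cohort statistics
(univariate logistic odds ratios, forward-stepwise multivariate logistic
regression, Welch/pooled t tests, chi-squared, Pearson correlation) and an
interpretable prediction layer: the printed decision-tree rule

> euploid ⇔ `TE count > 94` **or** (`size variance ≤ 478 µm²` **and**
> `ICM area > 8007 µm²`)

plus a six-model benchmark harness (LR, decision tree, XGBoost, random
forest, SVM, MLP) with stratified 80/20 splits, 5-fold AUC-maximising
tuning, the ROC operating point closest to (0, 1), exact Clopper–Pearson
confidence intervals, DeLong AUC comparison, McNemar accuracy comparison
and permutation feature importance.

A first-class synthetic-data module generates ground-truth blastocysts
(exact spherical-Voronoi TE tessellation with a darkened ICM region),
renders multi-view sequences with known rotations and masks, and simulates
cohort-style feature tables — so every stage is testable end to end
without clinical data.

## Worked example

```python
import numpy as np
from blastomorph import synthgen, morphometry

truth = synthgen.make_truth(n_te_cells=120, diameter_um=184.0,
                            icm_area_um2=5500.0, size_cv_target=0.3, seed=7)
seq = synthgen.render_sequence(truth, n_views=12)
rec = morphometry.measure(seq.images, seq.masks, seq.midplane)
print(f"D = {rec.diameter_um:.1f} um (truth {truth.diameter_um:.1f})")
print(f"N_TE = {rec.te_count} (truth {truth.n_te_cells})")
print(f"density = {rec.te_density:.3f} cells/1000 um^2")
print(f"size SD = {rec.te_size_variance_um2:.1f} um^2 (truth {truth.te_size_variance_um2:.1f})")
print(f"ICM = {rec.icm_area_um2:.0f} um^2 (truth {truth.icm_area_um2:.0f})")
```

prints (exact floats may differ in the last digit across BLAS builds):

```
D = 184.5 um (truth 184.0)
N_TE = 120 (truth 120)
density = 1.122 cells/1000 um^2
size SD = 277.5 um^2 (truth 276.4)
ICM = 5068 um^2 (truth 4960)
```

Every parameter lands within a few percent of the generator's ground
truth; the TE count is exact. The same `measure` call accepts externally
segmented masks (`segmentation.load_external_masks`) or runs the built-in
classical segmenter when no masks are given.

A command-line interface chains the stages:

```bash
blastomorph simulate --n-te-cells 120 --seed 1 --out run/
blastomorph measure run/ --pixel-scale 0.5 --out record.csv
blastomorph analyze features.csv --out analysis.json
blastomorph predict features.csv --out predictions.csv
blastomorph benchmark features.csv --seeds 0,1,2 --out bench.csv
```

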
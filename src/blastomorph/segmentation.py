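"""TE-boundary and ICM segmentation of cropped blastocyst views.

A classical, fully deterministic segmenter: shading flattening, ridge
enhancement of the dark inter-cell boundaries, hysteresis thresholding to
a boundary skeleton, watershed from interior minima to close the cells,
and darkness + compactness detection of the ICM (which images as a
compact fist-like structure without visible cell detail).  An external
mask-ingestion contract lets users plug in masks from any segmenter
(e.g. a neural network) through a label-alphabet mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, morphology, segmentation as sk_seg

from .sphere3d import LABEL_BOUNDARY, LABEL_ICM, LABEL_CELL_START

LABEL_BACKGROUND = 0
CANONICAL_ALPHABET = ("background", "te_boundary", "icm", "cell_interior")


@dataclass
class SegmentationResult:
    """Label mask plus diagnostics for one view."""

    mask: np.ndarray  # 0 bg, 1 boundary, 2 ICM, >=3 cell regions
    icm_found: bool
    warning: str | None = None


def _disk_mask(shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    c = (h - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx - c) ** 2 + (yy - c) ** 2 < (c - 1) ** 2


def segment_classical(
    view: np.ndarray,
    smoothing_sigma: float = 1.0,
    ridge_scale: float = 1.5,
    icm_min_area_frac: float = 0.06,
    boundary_quantile: float = 0.85,
    icm_darkness: float = 0.72,
    icm_min_solidity: float = 0.70,
    seed_h: float = 3.0,
) -> SegmentationResult:
    """Segment TE cell boundaries and the ICM in one cropped view.

    Deterministic pipeline (no RNG): divide out the Lambertian limb
    shading predicted by the sphere geometry, enhance dark inter-cell
    ridges, hysteresis-threshold them into a boundary skeleton, close
    cells by watershed seeded from h-maxima of the interior distance
    field, and label the largest dark compact region exceeding
    ``icm_min_area_frac`` of the disk as the ICM.
    """
    img = np.asarray(view, dtype=float)
    disk = _disk_mask(img.shape)
    if np.ptp(img[disk]) < 1e-6:
        return SegmentationResult(
            mask=np.zeros(img.shape, dtype=np.int32),
            icm_found=False,
            warning="degenerate uniform view",
        )
    h, w = img.shape
    c = (h - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((xx - c) ** 2 + (yy - c) ** 2) / (c - 1) ** 2
    shade = np.sqrt(np.clip(1.0 - r2, 0.04, None))  # Lambertian cos factor
    work = filters.gaussian(img, smoothing_sigma)
    bg = np.quantile(work[~disk], 0.5) if (~disk).any() else 0.0
    flat = np.where(disk, (work - bg) / shade, 0.0)
    flat = flat / max(np.quantile(flat[disk], 0.75), 1e-6)

    # ICM: large dark textureless region (relative darkness threshold)
    dark = (flat < icm_darkness) & disk
    dark = morphology.opening(dark, morphology.disk(4))
    dark = morphology.closing(dark, morphology.disk(4))
    lab, n = ndimage.label(dark)
    icm_mask = np.zeros(img.shape, dtype=bool)
    icm_found = False
    if n:
        from skimage import measure

        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        best = int(np.argmax(sizes)) + 1
        candidate = ndimage.binary_fill_holes(lab == best)
        (props,) = measure.regionprops(candidate.astype(int))
        if (
            candidate.sum() >= icm_min_area_frac * disk.sum()
            and props.solidity >= icm_min_solidity
        ):
            icm_mask = candidate
            icm_found = True

    # dark boundaries -> ridge response of the inverted flattened image
    ridge = filters.sato(1.0 - flat, sigmas=(ridge_scale,), black_ridges=False)
    ridge[~disk | icm_mask] = 0.0
    te = disk & ~icm_mask
    hi = np.quantile(ridge[te], boundary_quantile + 0.5 * (1 - boundary_quantile))
    lo = np.quantile(ridge[te], boundary_quantile)
    boundary = filters.apply_hysteresis_threshold(ridge, lo, hi) & te

    # close cells: watershed of the ridge landscape, one seed per cell
    interior = te & ~boundary
    seed_dist = ndimage.distance_transform_edt(interior)
    seeds = morphology.h_maxima(seed_dist, seed_h)
    markers, _ = ndimage.label(seeds, structure=np.ones((3, 3)))
    ws = sk_seg.watershed(ridge, markers=markers, mask=te, watershed_line=True)

    mask = np.zeros(img.shape, dtype=np.int32)
    cells = ws > 0
    mask[cells] = ws[cells] + LABEL_CELL_START - 1
    mask[(ws == 0) & te] = LABEL_BOUNDARY
    mask[boundary] = LABEL_BOUNDARY
    mask[icm_mask] = LABEL_ICM
    warning = None if icm_found else "no ICM candidate found in this view"
    return SegmentationResult(mask=mask, icm_found=icm_found, warning=warning)


class MaskValidationError(ValueError):
    pass


def normalize_mask(
    raw: np.ndarray,
    alphabet_mapping: dict[int, str],
    expected_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Map an external label mask onto the canonical alphabet.

    ``alphabet_mapping`` sends every raw label value to one of
    ``background``, ``te_boundary``, ``icm`` or ``cell_interior``; distinct
    raw cell values are preserved as distinct cell ids.
    """
    raw = np.asarray(raw)
    if expected_shape is not None and raw.shape != expected_shape:
        raise MaskValidationError(
            f"mask shape {raw.shape} does not match view shape {expected_shape}"
        )
    present = set(np.unique(raw).tolist())
    unmapped = sorted(present - set(alphabet_mapping))
    if unmapped:
        raise MaskValidationError(f"unmapped label values: {unmapped}")
    bad = sorted(set(alphabet_mapping.values()) - set(CANONICAL_ALPHABET))
    if bad:
        raise MaskValidationError(f"unknown alphabet names: {bad}")
    out = np.zeros(raw.shape, dtype=np.int32)
    next_cell = LABEL_CELL_START
    for value in sorted(present):
        kind = alphabet_mapping[int(value)]
        if kind == "background":
            continue
        elif kind == "te_boundary":
            out[raw == value] = LABEL_BOUNDARY
        elif kind == "icm":
            out[raw == value] = LABEL_ICM
        else:  # cell_interior: each raw value becomes its own cell id
            out[raw == value] = next_cell
            next_cell += 1
    return out


def load_external_masks(
    paths: list,
    alphabet_mapping: dict[int, str],
    expected_shapes: list[tuple[int, int]] | None = None,
) -> list[np.ndarray]:
    """Read and validate externally produced label masks."""
    import imageio.v3 as iio

    masks = []
    for i, path in enumerate(paths):
        raw = iio.imread(path)
        shape = expected_shapes[i] if expected_shapes else None
        masks.append(normalize_mask(raw, alphabet_mapping, shape))
    return masks
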
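"""Synthetic blastocyst models, multi-view renders and feature tables.

Ground truth for the whole pipeline: a Day-6 blastocyst is modelled as a
sphere whose surface is partitioned into trophectoderm (TE) cells plus an
inner-cell-mass (ICM) patch.  The partition is a single exact spherical
Voronoi tessellation: TE generator sites lie outside a polar cap, ICM
sites inside it, and the ICM region is the union of the ICM-site cells.
This keeps every area exact (spherical polygon excess) and the partition
identity ``sum(TE areas) + ICM area = pi * D^2`` true to machine
precision.  The stored ICM half-angle is the equivalent-cap angle of the
realized ICM area, so ``A_icm = 2*pi*R^2*(1 - cos(theta))`` holds exactly.

Rendering follows the imaging protocol of rotational multi-view capture:
the embryo is turned about the holding-pipette axis in steps below 35
degrees so that more than 10 overlapping views cover a full revolution;
one extra image is taken in the mid-plane to measure centre and diameter.
Views are orthographic renders of the camera-facing hemisphere with
Lambertian shading, dark geodesic cell boundaries, a dark featureless ICM
("compact, fist-like structure") and weak per-cell albedo texture.

The feature-table simulator draws the five morphological parameters with
class-conditional moments defaulting to the published euploid /
non-euploid cohort values, for testing the statistics and prediction
layers without clinical data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import SphericalVoronoi, cKDTree
from scipy.stats import truncnorm

from .sphere3d import LABEL_CELL_START, LABEL_ICM, rotation_matrix

# ---------------------------------------------------------------------------
# Truth geometry


@dataclass
class TruthModel:
    """Exact ground-truth geometry of one synthetic blastocyst."""

    diameter_um: float
    te_sites: np.ndarray  # (n_te, 3) unit vectors
    te_cell_areas: np.ndarray  # um^2, exact spherical-polygon areas
    icm_sites: np.ndarray  # (m, 3) unit vectors (may be empty)
    icm_axis: np.ndarray  # unit vector
    icm_polar_half_angle: float  # radians, equivalent-cap angle
    icm_area_um2: float
    boundary_darkness: float = 0.35
    shading_gain: float = 1.0
    noise_sd: float = 0.0
    albedo_contrast: float = 0.18
    speckle_spots: int = 1500
    speckle_amp: float = 0.25
    seed: int = 0
    achieved_cv: float = 0.0
    cv_converged: bool = True

    @property
    def radius_um(self) -> float:
        return self.diameter_um / 2.0

    @property
    def n_te_cells(self) -> int:
        return len(self.te_sites)

    @property
    def te_size_variance_um2(self) -> float:
        """Standard deviation (n-1) of the TE cell areas."""
        return float(np.std(self.te_cell_areas, ddof=1))

    @property
    def te_density(self) -> float:
        return 1000.0 * self.n_te_cells / (np.pi * self.diameter_um**2)

    def all_sites(self) -> np.ndarray:
        if len(self.icm_sites):
            return np.vstack([self.te_sites, self.icm_sites])
        return self.te_sites

    def cell_albedos(self) -> np.ndarray:
        rng = np.random.default_rng(self.seed + 104729)
        return 1.0 + rng.uniform(-self.albedo_contrast, self.albedo_contrast, self.n_te_cells)

    def speckle_field(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Surface-attached speckle texture (granular cytoplasmic detail).

        Random Gaussian albedo spots pinned to the surface, giving every
        neighbourhood a distinctive appearance for feature matching.
        Returns (spot unit vectors, amplitudes, angular sigmas in rad).
        """
        rng = np.random.default_rng(self.seed + 224737)
        k = self.speckle_spots
        centers = _sample_sphere(rng, k)
        amps = rng.uniform(0.4, 1.0, k) * np.where(rng.random(k) < 0.5, -1, 1)
        amps = amps * self.speckle_amp
        sigma_um = rng.uniform(1.0, 6.0, k)
        return centers, amps, sigma_um / self.radius_um

    def speckle_texture(self, shape: tuple[int, int] = (512, 1024)) -> np.ndarray:
        """Speckle albedo factor rasterized on a lat/lon grid (cached).

        Each spot only touches the texels within 3 sigma of its centre,
        so building the texture is cheap; renders then sample it by
        nearest texel (texels are finer than image pixels).
        """
        cached = getattr(self, "_speckle_cache", None)
        if cached is not None and cached.shape == shape:
            return cached
        n_lat, n_lon = shape
        phi = -np.pi / 2 + (np.arange(n_lat) + 0.5) * np.pi / n_lat
        lam = -np.pi + (np.arange(n_lon) + 0.5) * 2 * np.pi / n_lon
        cphi, sphi = np.cos(phi), np.sin(phi)
        tex = np.zeros(shape)
        centers, amps, sigmas = self.speckle_field()
        for (cx, cy, cz), amp, sig in zip(centers, amps, sigmas):
            r3 = 3.0 * sig
            phi0 = np.arcsin(np.clip(cy, -1, 1))
            i0 = max(0, int((phi0 - r3 + np.pi / 2) / np.pi * n_lat))
            i1 = min(n_lat, int((phi0 + r3 + np.pi / 2) / np.pi * n_lat) + 1)
            lam0 = np.arctan2(cx, cz)
            cmin = np.cos(np.minimum(np.abs(phi0) + r3, np.pi / 2))
            if cmin < 1e-6 or r3 / cmin >= np.pi:
                j_idx = np.arange(n_lon)
            else:
                half = r3 / cmin
                j0 = int((lam0 - half + np.pi) / (2 * np.pi) * n_lon)
                j1 = int((lam0 + half + np.pi) / (2 * np.pi) * n_lon) + 1
                j_idx = np.arange(j0, j1) % n_lon
            # unit vectors of the texel window (x=cphi*sin(lam), y=sphi, z=cphi*cos(lam))
            sl, cl = np.sin(lam[j_idx]), np.cos(lam[j_idx])
            cosd = (
                cphi[i0:i1, None] * sl[None, :] * cx
                + sphi[i0:i1, None] * cy
                + cphi[i0:i1, None] * cl[None, :] * cz
            )
            d2 = np.clip(2.0 - 2.0 * cosd, 0.0, None)
            win = np.exp(-d2 / (2.0 * sig * sig))
            win[d2 > (r3 * r3)] = 0.0
            tex[np.ix_(np.arange(i0, i1), j_idx)] += amp * win
        self._speckle_cache = tex
        return tex


def _voronoi_areas(sites: np.ndarray) -> np.ndarray:
    """Exact unit-sphere Voronoi cell areas (spherical polygon excess)."""
    sv = SphericalVoronoi(sites, radius=1.0)
    sv.sort_vertices_of_regions()
    return sv.calculate_areas()


def _sample_sphere(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def make_truth(
    n_te_cells: int,
    diameter_um: float,
    icm_area_um2: float,
    size_cv_target: float = 0.3,
    seed: int = 0,
    icm_axis: np.ndarray | None = None,
) -> TruthModel:
    """Build a ground-truth blastocyst surface partition.

    TE sites start uniform outside the ICM cap; relaxation iterations then
    drive the coefficient of variation of TE cell areas into
    ``size_cv_target +/- 0.05`` (Lloyd moves lower the CV, small moves
    toward the nearest neighbouring site raise it).  Gives up after 200
    iterations with a warning, recording the best CV achieved.
    """
    if n_te_cells < 4:
        raise ValueError("n_te_cells must be >= 4")
    if diameter_um <= 0:
        raise ValueError("diameter_um must be positive")
    R = diameter_um / 2.0
    sphere_area = 4.0 * np.pi * R * R
    if icm_area_um2 >= sphere_area / 2.0:
        raise ValueError("icm_area_um2 must be below half the sphere area")
    rng = np.random.default_rng(seed)

    if icm_axis is None:
        icm_axis = np.array([0.0, 0.0, 1.0])
    icm_axis = np.asarray(icm_axis, dtype=float)
    icm_axis = icm_axis / np.linalg.norm(icm_axis)

    icm_frac = max(icm_area_um2, 0.0) / sphere_area
    has_icm = icm_frac > 1e-6
    if has_icm:
        cos_cap = 1.0 - 2.0 * icm_frac  # cap with requested area
        theta_cap = np.arccos(np.clip(cos_cap, -1.0, 1.0))
        a_te = (sphere_area - icm_area_um2) / n_te_cells
        m_icm = max(3, int(round(icm_area_um2 / a_te)))
    else:
        cos_cap, theta_cap, m_icm = 1.0, 0.0, 0

    def sample_sites(cos_bound: float) -> tuple[np.ndarray, np.ndarray]:
        te = np.empty((0, 3))
        while len(te) < n_te_cells:
            cand = _sample_sphere(rng, 4 * n_te_cells)
            cand = cand[cand @ icm_axis < cos_bound] if has_icm else cand
            te = np.vstack([te, cand])
        te = te[:n_te_cells]
        icm = np.empty((0, 3))
        while len(icm) < m_icm:
            cand = _sample_sphere(rng, max(8, 6 * m_icm))
            icm = np.vstack([icm, cand[cand @ icm_axis > cos_bound]])
        return te, icm[:m_icm]

    te, icm = sample_sites(cos_cap)
    if has_icm:
        # calibrate the sampling cap so the realized Voronoi ICM area
        # (rim cells bulge past the cap) matches the requested area
        area_frac = icm_frac
        for _ in range(4):
            realized = _voronoi_areas(np.vstack([te, icm]))[n_te_cells:].sum() / (4 * np.pi)
            if abs(realized - icm_frac) <= 0.03 * icm_frac:
                break
            area_frac = max(area_frac - 0.8 * (realized - icm_frac), icm_frac / 8)
            cos_cap = 1.0 - 2.0 * area_frac
            theta_cap = np.arccos(np.clip(cos_cap, -1.0, 1.0))
            te, icm = sample_sites(cos_cap)

    def clamp_outside_cap(pts: np.ndarray) -> np.ndarray:
        if not has_icm:
            return pts
        d = pts @ icm_axis
        bad = d > cos_cap
        if bad.any():
            # rotate offending sites back to just outside the cap rim
            tang = pts[bad] - np.outer(d[bad], icm_axis)
            tang /= np.linalg.norm(tang, axis=1, keepdims=True)
            theta = theta_cap * 1.02
            pts = pts.copy()
            pts[bad] = np.cos(theta) * icm_axis + np.sin(theta) * tang
        return pts

    def te_area_cv(all_sites: np.ndarray) -> tuple[np.ndarray, float]:
        areas = _voronoi_areas(all_sites)[:n_te_cells]
        mean = areas.mean()
        return areas, float(np.std(areas, ddof=1) / mean)

    areas, cv = te_area_cv(np.vstack([te, icm]) if has_icm else te)
    best = (te.copy(), areas, cv)
    converged = abs(cv - size_cv_target) <= 0.05
    it = 0
    while not converged and it < 200:
        it += 1
        if cv > size_cv_target:
            # Lloyd step: move TE sites toward their cell centroids
            sv = SphericalVoronoi(np.vstack([te, icm]) if has_icm else te, radius=1.0)
            sv.sort_vertices_of_regions()
            for k in range(n_te_cells):
                verts = sv.vertices[sv.regions[k]]
                c = np.vstack([verts, te[k][None]]).mean(axis=0)
                nc = np.linalg.norm(c)
                if nc > 1e-12:
                    te[k] = c / nc
        else:
            # clustering step: nudge each site toward its nearest neighbour
            tree = cKDTree(te)
            _, nn = tree.query(te, k=2)
            step = 0.06
            te = te + step * (te[nn[:, 1]] - te)
            te /= np.linalg.norm(te, axis=1, keepdims=True)
        te = clamp_outside_cap(te)
        areas, cv = te_area_cv(np.vstack([te, icm]) if has_icm else te)
        if abs(cv - size_cv_target) < abs(best[2] - size_cv_target):
            best = (te.copy(), areas, cv)
        converged = abs(cv - size_cv_target) <= 0.05
    if not converged:
        te, areas, cv = best
        warnings.warn(
            f"size_cv_target={size_cv_target} not reached; best CV {cv:.3f}",
            stacklevel=2,
        )

    te_areas_um2 = areas * R * R
    if has_icm:
        all_areas = _voronoi_areas(np.vstack([te, icm])) * R * R
        icm_area = float(all_areas[n_te_cells:].sum())
        half_angle = float(np.arccos(np.clip(1.0 - icm_area / (2 * np.pi * R * R), -1, 1)))
    else:
        icm_area, half_angle = 0.0, 0.0

    return TruthModel(
        diameter_um=diameter_um,
        te_sites=te,
        te_cell_areas=te_areas_um2,
        icm_sites=icm,
        icm_axis=icm_axis,
        icm_polar_half_angle=half_angle,
        icm_area_um2=icm_area,
        seed=seed,
        achieved_cv=cv,
        cv_converged=converged,
    )


# ---------------------------------------------------------------------------
# Rendering


@dataclass
class ViewImage:
    """One grayscale view plus its ground-truth label mask."""

    image: np.ndarray  # float in [0, 1]
    mask: np.ndarray  # int labels (0 bg, 1 boundary, 2 ICM, >=3 cell ids)
    rotation: np.ndarray  # 3x3, view frame -> reference frame


@dataclass
class RenderedSequence:
    """A full rotational imaging session of one synthetic blastocyst."""

    views: list[ViewImage]
    true_rotations: list[np.ndarray]
    truth: TruthModel
    midplane: np.ndarray
    pixel_scale: float

    @property
    def images(self) -> list[np.ndarray]:
        return [v.image for v in self.views]

    @property
    def masks(self) -> list[np.ndarray]:
        return [v.mask for v in self.views]


def render_view(
    truth: TruthModel,
    rotation: np.ndarray,
    pixel_scale: float = 0.5,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    boundary_halfwidth_um: float = 0.9,
    mask_boundary: bool = False,
) -> ViewImage:
    """Orthographic render of the camera-facing hemisphere.

    ``rotation`` maps the view frame to the truth (reference) frame.  The
    mask carries the per-pixel true label; by default it contains pure
    region labels (no boundary ribbon) so that truth-mask morphometry sees
    the exact partition, while the intensity image draws the boundaries as
    dark geodesic curves.
    """
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be positive")
    R = truth.radius_um
    side = int(np.ceil(truth.diameter_um / pixel_scale)) | 1
    c = side // 2
    yy, xx = np.mgrid[0:side, 0:side]
    u = (xx - c) * pixel_scale
    v = (yy - c) * pixel_scale
    rr = u * u + v * v
    inside = rr < R * R
    z = np.sqrt(np.clip(R * R - rr, 0.0, None))
    pts = np.stack([u[inside], v[inside], z[inside]], axis=1) / R
    gpts = pts @ np.asarray(rotation).T

    sites = truth.all_sites()
    tree = cKDTree(sites)
    d, idx = tree.query(gpts, k=2)
    nearest = idx[:, 0]
    is_icm = nearest >= truth.n_te_cells
    # geodesic distance to the bisector between the two nearest sites
    th1 = 2.0 * np.arcsin(np.clip(d[:, 0] / 2.0, 0, 1))
    th2 = 2.0 * np.arcsin(np.clip(d[:, 1] / 2.0, 0, 1))
    bisector_um = (th2 - th1) / 2.0 * R
    second_icm = idx[:, 1] >= truth.n_te_cells
    interior_icm_edge = is_icm & second_icm  # no boundaries drawn inside the ICM
    on_boundary = (bisector_um < boundary_halfwidth_um) & ~interior_icm_edge

    albedos = truth.cell_albedos()
    base = np.where(is_icm, 0.55, albedos[np.minimum(nearest, truth.n_te_cells - 1)])
    # per-cell dome: brighter near the cell centre, giving SIFT blob texture
    r_cell = np.sqrt(truth.te_cell_areas.mean() / np.pi) / R
    dome = 0.82 + 0.18 * np.exp(-(th1**2) / (2 * (0.55 * r_cell) ** 2))
    base = base * np.where(is_icm, 1.0, dome)
    if truth.speckle_spots:
        # speckle only on the TE: the ICM images as a compact structure
        # with no visible internal detail
        tex = truth.speckle_texture()
        n_lat, n_lon = tex.shape
        phi_p = np.arcsin(np.clip(gpts[:, 1], -1.0, 1.0))
        lam_p = np.arctan2(gpts[:, 0], gpts[:, 2])
        ti = np.clip(((phi_p + np.pi / 2) / np.pi * n_lat).astype(int), 0, n_lat - 1)
        tj = ((lam_p + np.pi) / (2 * np.pi) * n_lon).astype(int) % n_lon
        base = base * np.where(is_icm, 1.0, 1.0 + tex[ti, tj])
    shade = truth.shading_gain * (pts[:, 2])  # Lambertian, cos of viewing angle
    vals = 0.12 + 0.75 * base * shade
    depth = np.clip(bisector_um / boundary_halfwidth_um, 0.0, 1.0)
    bfac = truth.boundary_darkness + (1 - truth.boundary_darkness) * depth
    vals = np.where(on_boundary, vals * bfac, vals)

    img = np.full((side, side), 0.05)
    img[inside] = vals
    sd = noise_sd if noise_sd else truth.noise_sd
    if sd > 0:
        rng = rng or np.random.default_rng(truth.seed + 7919)
        img = img + rng.normal(0.0, sd, img.shape)
    img = np.clip(img, 0.0, 1.0)

    labels = np.where(is_icm, LABEL_ICM, nearest + LABEL_CELL_START)
    if mask_boundary:
        labels = np.where(on_boundary, 1, labels)
    mask = np.zeros((side, side), dtype=np.int32)
    mask[inside] = labels
    return ViewImage(image=img, mask=mask, rotation=np.asarray(rotation, dtype=float))


def render_midplane(
    truth: TruthModel,
    pixel_scale: float = 0.5,
    rim_sigma_px: float = 1.2,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Mid-plane image: bright disk with a dark rim of the true diameter."""
    R_px = truth.radius_um / pixel_scale
    side = int(np.ceil(truth.diameter_um / pixel_scale) + 8) | 1
    c = side // 2
    yy, xx = np.mgrid[0:side, 0:side]
    r = np.hypot(xx - c, yy - c)
    img = np.where(r < R_px, 0.75, 0.2)
    rim = np.exp(-((r - R_px) ** 2) / (2 * rim_sigma_px**2))
    img = img * (1 - 0.8 * rim)
    if noise_sd > 0:
        rng = rng or np.random.default_rng(truth.seed + 15013)
        img = np.clip(img + rng.normal(0, noise_sd, img.shape), 0, 1)
    return img


def render_sequence(
    truth: TruthModel,
    n_views: int = 12,
    axis: np.ndarray = (0.0, 1.0, 0.0),
    jitter_deg: float = 0.0,
    seed: int | None = None,
    pixel_scale: float = 0.5,
    noise_sd: float = 0.0,
    mask_boundary: bool = False,
) -> RenderedSequence:
    """Render a full rotational imaging session.

    Views are successive turns of ``360 / n_views`` degrees about ``axis``
    plus uniform jitter in ``+/- jitter_deg``; the default 12-view protocol
    satisfies the imaging guideline of more than 10 views with steps below
    35 degrees.  Steps of 90 degrees or more leave no overlap between
    adjacent camera-facing hemispheres and are rejected.
    """
    if n_views < 2:
        raise ValueError("n_views must be >= 2")
    base_step = 360.0 / n_views
    if base_step + abs(jitter_deg) >= 90.0:
        raise ValueError("rotation step >= 90 deg: adjacent views would not overlap")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    steps = base_step + rng.uniform(-jitter_deg, jitter_deg, n_views - 1)
    angles = np.concatenate([[0.0], np.cumsum(steps)])
    axis = np.asarray(axis, dtype=float)
    rotations = [rotation_matrix(axis, np.radians(a)) for a in angles]
    views = [
        render_view(
            truth,
            rot,
            pixel_scale=pixel_scale,
            noise_sd=noise_sd,
            rng=rng,
            mask_boundary=mask_boundary,
        )
        for rot in rotations
    ]
    mid = render_midplane(truth, pixel_scale=pixel_scale, noise_sd=noise_sd, rng=rng)
    return RenderedSequence(
        views=views,
        true_rotations=rotations,
        truth=truth,
        midplane=mid,
        pixel_scale=pixel_scale,
    )


def visible_cells(truth: TruthModel, rotation: np.ndarray) -> set[int]:
    """Cell ids whose Voronoi site faces the camera (z > 0) in this view.

    Independent visibility oracle used to validate rendered masks.
    """
    sites_view = truth.te_sites @ np.asarray(rotation)  # global -> view: R^T s
    return {i + LABEL_CELL_START for i in np.nonzero(sites_view[:, 2] > 0)[0]}


# ---------------------------------------------------------------------------
# Feature-table simulation

FEATURE_COLUMNS = [
    "diameter_um",
    "te_count",
    "te_density",
    "te_size_variance",
    "icm_area_um2",
]

TABLE_HEADER = ["id"] + FEATURE_COLUMNS + ["ploidy"]


@dataclass(frozen=True)
class ClassParams:
    """Class-conditional (mean, SD) of the five morphological parameters."""

    diameter_um: tuple[float, float]
    te_count: tuple[float, float]
    te_size_variance: tuple[float, float]
    icm_area_um2: tuple[float, float]


# Published cohort moments for the euploid / non-euploid classes.
EUPLOID_PARAMS = ClassParams(
    diameter_um=(190.4, 19.1),
    te_count=(141.3, 38.5),
    te_size_variance=(221.5, 119.2),
    icm_area_um2=(5883.4, 2303.1),
)
NONEUPLOID_PARAMS = ClassParams(
    diameter_um=(175.2, 21.9),
    te_count=(68.3, 27.1),
    te_size_variance=(794.9, 937.0),
    icm_area_um2=(4973.2, 2154.3),
)

DIAMETER_FLOOR_UM = 120.0
TE_COUNT_FLOOR = 8.0
MOSAIC_FRACTION_OF_NONEUPLOID = 28.0 / 97.0  # cohort composition 28 mosaic / 69 aneuploid


def _truncnorm_sample(rng, mean, sd, lower, size):
    a = (lower - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def truncated_normal_mean(mean: float, sd: float, lower: float) -> float:
    """Mean of the truncated normal actually sampled (oracle for tests)."""
    a = (lower - mean) / sd
    return float(truncnorm.mean(a, np.inf, loc=mean, scale=sd))


def _lognormal_sample(rng, mean, sd, size):
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def simulate_feature_table(
    n: int,
    euploid_fraction: float = 0.571,
    class_params: dict[str, ClassParams] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a morphological-parameter table with class structure.

    Per class: diameter and ICM area are truncated normals, TE count a
    truncated normal rounded to integer, size variance a moment-matched
    lognormal (heavy right tail, matching the very skewed non-euploid SD),
    and density is the deterministic ratio ``1000 * count / (pi * D^2)``.
    Non-euploid blastocysts split into mosaic and aneuploid with the
    cohort composition.
    """
    if not 0 < euploid_fraction < 1:
        raise ValueError("euploid_fraction must be in (0, 1)")
    params = class_params or {"euploid": EUPLOID_PARAMS, "non-euploid": NONEUPLOID_PARAMS}
    for cp in params.values():
        for mean, sd in (cp.diameter_um, cp.te_count, cp.te_size_variance, cp.icm_area_um2):
            if sd <= 0:
                raise ValueError("class SDs must be positive")
    rng = np.random.default_rng(seed)
    euploid = rng.random(n) < euploid_fraction
    rows = {c: np.empty(n) for c in FEATURE_COLUMNS}
    for label, sel in (("euploid", euploid), ("non-euploid", ~euploid)):
        cp = params[label]
        k = int(sel.sum())
        if k == 0:
            continue
        d = _truncnorm_sample(rng, *cp.diameter_um, DIAMETER_FLOOR_UM, k)
        cnt = np.rint(_truncnorm_sample(rng, *cp.te_count, TE_COUNT_FLOOR, k))
        rows["diameter_um"][sel] = d
        rows["te_count"][sel] = cnt
        rows["te_density"][sel] = 1000.0 * cnt / (np.pi * d**2)
        rows["te_size_variance"][sel] = _lognormal_sample(rng, *cp.te_size_variance, k)
        rows["icm_area_um2"][sel] = _truncnorm_sample(rng, *cp.icm_area_um2, 0.0, k)
    ploidy = np.where(euploid, "euploid", "aneuploid").astype(object)
    noneu_idx = np.nonzero(~euploid)[0]
    mosaic = noneu_idx[rng.random(len(noneu_idx)) < MOSAIC_FRACTION_OF_NONEUPLOID]
    ploidy[mosaic] = "mosaic"
    table = pd.DataFrame({"id": [f"B{i + 1:04d}" for i in range(n)], **rows})
    table["te_count"] = table["te_count"].astype(int)
    table["ploidy"] = ploidy
    return table[TABLE_HEADER]
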
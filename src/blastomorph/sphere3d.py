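"""Spherical surface geometry for 3D blastocyst reconstruction.

The blastocyst is modelled as a sphere of centre ``O`` and diameter ``D``
measured in the mid-plane image.  Every camera view sees the camera-facing
hemisphere under orthographic projection, so an in-disk pixel back-projects
to a unique surface point.  Multi-view pixels are deposited on an
equirectangular latitude/longitude grid to form the stitched 3D surface
model on which all morphometry is performed.

Coordinate conventions
----------------------
* image: origin top-left, ``x`` right (column), ``y`` down (row), pixels;
* sphere frame: ``x`` right, ``y`` down, ``z`` toward the camera, microns;
* polar axis of the surface grid is ``y`` (the image vertical), so a
  rotation of the embryo about the holding-pipette axis sweeps longitude;
* latitude ``phi`` in ``[-pi/2, pi/2]`` from the equator, longitude
  ``lam`` in ``[-pi, pi)``; all stored angles in radians.

Grid labels: ``0`` unobserved, ``1`` TE boundary, ``2`` ICM, ``>= 3``
individual TE cell ids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

LABEL_UNOBSERVED = 0
LABEL_BOUNDARY = 1
LABEL_ICM = 2
LABEL_CELL_START = 3

_CONN8 = np.ones((3, 3), dtype=bool)


class OutOfSphereError(ValueError):
    """A pixel lies outside the projected disk of the sphere."""


@dataclass(frozen=True)
class BlastocystSphere:
    """The sphere Omega everything is measured on.

    Parameters
    ----------
    center_px : tuple of float
        Centre ``O`` as ``(x, y)`` pixel coordinates in the reference image.
    diameter_um : float
        Diameter ``D`` in microns.
    pixel_scale : float
        Microns per pixel.
    """

    center_px: tuple[float, float]
    diameter_um: float
    pixel_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter_um must be positive")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")

    @property
    def radius_um(self) -> float:
        return self.diameter_um / 2.0

    @property
    def radius_px(self) -> float:
        return self.radius_um / self.pixel_scale


def rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix about ``axis`` by ``angle_rad`` (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def check_rotation(matrix: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    """Validate that ``matrix`` is a proper rotation (orthogonal, det=+1)."""
    M = np.asarray(matrix, dtype=float)
    if M.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if not np.allclose(M.T @ M, np.eye(3), atol=atol):
        raise ValueError("matrix is not orthogonal")
    if not np.isclose(np.linalg.det(M), 1.0, atol=atol):
        raise ValueError("matrix determinant is not +1")
    return M


def rotation_angle_deg(matrix: np.ndarray) -> float:
    """Geodesic rotation angle of ``matrix`` in degrees."""
    c = (np.trace(matrix) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def backproject(pixels: np.ndarray, sphere: BlastocystSphere) -> np.ndarray:
    """Back-project pixel coordinates onto the camera-facing hemisphere.

    Parameters
    ----------
    pixels : (N, 2) or (2,) array
        ``(x, y)`` pixel coordinates.
    sphere : BlastocystSphere

    Returns
    -------
    (N, 3) or (3,) array of surface points ``(u, v, +sqrt(R^2-u^2-v^2))``
    in microns, view frame.
    """
    p = np.atleast_2d(np.asarray(pixels, dtype=float))
    ox, oy = sphere.center_px
    u = (p[:, 0] - ox) * sphere.pixel_scale
    v = (p[:, 1] - oy) * sphere.pixel_scale
    R = sphere.radius_um
    zz = R * R - u * u - v * v
    if np.any(zz < -1e-9 * R * R):
        raise OutOfSphereError("pixel outside the sphere disk")
    z = np.sqrt(np.clip(zz, 0.0, None))
    out = np.stack([u, v, z], axis=1)
    return out[0] if np.ndim(pixels) == 1 else out


def latlon_of(points: np.ndarray, radius_um: float) -> tuple[np.ndarray, np.ndarray]:
    """Latitude/longitude of 3D surface points (polar axis = y)."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    phi = np.arcsin(np.clip(p[:, 1] / radius_um, -1.0, 1.0))
    lam = np.arctan2(p[:, 0], p[:, 2])
    return phi, lam


@dataclass
class SphereLabelMap:
    """Equirectangular label/weight grid holding the stitched surface model."""

    label_grid: np.ndarray
    weight_grid: np.ndarray
    radius_um: float

    def __post_init__(self) -> None:
        self.label_grid = np.asarray(self.label_grid)
        self.weight_grid = np.asarray(self.weight_grid, dtype=float)
        if self.label_grid.shape != self.weight_grid.shape:
            raise ValueError("label and weight grids must share a shape")

    @property
    def n_lat(self) -> int:
        return self.label_grid.shape[0]

    @property
    def n_lon(self) -> int:
        return self.label_grid.shape[1]

    @classmethod
    def empty(cls, n_lat: int, n_lon: int, radius_um: float) -> "SphereLabelMap":
        return cls(
            label_grid=np.zeros((n_lat, n_lon), dtype=np.int32),
            weight_grid=np.zeros((n_lat, n_lon), dtype=float),
            radius_um=radius_um,
        )

    def lat_edges(self) -> np.ndarray:
        return np.linspace(-np.pi / 2, np.pi / 2, self.n_lat + 1)

    def bin_area(self, lat_index: int, lon_index: int) -> float:
        """Exact area of one lat/lon bin: R^2 * dlam * (sin(top) - sin(bot))."""
        if not (0 <= lat_index < self.n_lat and 0 <= lon_index < self.n_lon):
            raise IndexError("bin index out of range")
        return float(self.row_areas()[lat_index])

    def row_areas(self) -> np.ndarray:
        """Area of a single bin in each latitude row (all columns equal)."""
        edges = self.lat_edges()
        dlam = 2.0 * np.pi / self.n_lon
        return self.radius_um**2 * dlam * np.diff(np.sin(edges))

    def area_grid(self) -> np.ndarray:
        return np.broadcast_to(self.row_areas()[:, None], self.label_grid.shape)

    def total_area(self) -> float:
        """Total map area, equal to 4*pi*R^2 (= pi*D^2) for any grid shape."""
        return float(self.n_lon * self.row_areas().sum())

    def area_of(self, mask: np.ndarray) -> float:
        return float((self.area_grid() * mask).sum())

    def bin_index(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Grid indices of 3D surface points."""
        phi, lam = latlon_of(points, self.radius_um)
        i = np.clip(((phi + np.pi / 2) / np.pi * self.n_lat).astype(int), 0, self.n_lat - 1)
        j = ((lam + np.pi) / (2 * np.pi) * self.n_lon).astype(int) % self.n_lon
        return i, j

    def save(self, path) -> None:
        """Serialize as a 2-layer TIFF (labels, weights) + JSON header."""
        import tifffile

        path = str(path)
        stack = np.stack(
            [self.label_grid.astype(np.float32), self.weight_grid.astype(np.float32)]
        )
        tifffile.imwrite(path, stack)
        header = {
            "radius_um": self.radius_um,
            "n_lat": self.n_lat,
            "n_lon": self.n_lon,
            "conventions": "polar axis = image y; lat [-pi/2,pi/2]; lon [-pi,pi); radians",
        }
        with open(path + ".json", "w") as fh:
            json.dump(header, fh, indent=2)

    @classmethod
    def load(cls, path) -> "SphereLabelMap":
        import tifffile

        path = str(path)
        stack = tifffile.imread(path)
        with open(path + ".json") as fh:
            header = json.load(fh)
        return cls(
            label_grid=stack[0].astype(np.int32),
            weight_grid=stack[1].astype(float),
            radius_um=float(header["radius_um"]),
        )


def project_views(
    views: list[np.ndarray],
    masks: list[np.ndarray],
    rotations: list[np.ndarray],
    sphere: BlastocystSphere,
    map_shape: tuple[int, int] = (256, 512),
    supersample: int = 2,
) -> tuple[SphereLabelMap, SphereLabelMap]:
    """Project per-view masks and intensities onto the sphere surface.

    Every in-disk pixel is back-projected, rotated to the global frame with
    its view's rotation (view frame -> global frame) and deposited in its
    lat/lon bin with weight ``w = z_view / R`` (cosine of the viewing
    angle).  Each bin keeps the contribution of highest weight; ties break
    toward the lower view index.  ``supersample`` splits each pixel into
    ``s x s`` sub-pixels to close coverage gaps on the oblique parts of the
    grid.

    Returns
    -------
    (label_map, intensity_map)
        Two :class:`SphereLabelMap` objects sharing weights; the intensity
        map stores image values scaled by 1000 in its integer grid and a
        float copy in ``intensity`` attribute.
    """
    if not (len(views) == len(masks) == len(rotations)):
        raise ValueError("views, masks and rotations must have equal lengths")
    n_lat, n_lon = map_shape
    R = sphere.radius_um
    label_map = SphereLabelMap.empty(n_lat, n_lon, R)
    intensity = np.zeros((n_lat, n_lon), dtype=float)

    for view, mask, rot in zip(views, masks, rotations):
        rot = check_rotation(rot, atol=1e-6)
        h, w = mask.shape
        yy, xx = np.mgrid[0:h, 0:w]
        s = max(1, int(supersample))
        offs = (np.arange(s) + 0.5) / s - 0.5
        pts_list, lab_list, val_list = [], [], []
        for dy in offs:
            for dx in offs:
                px = np.stack([(xx + dx).ravel(), (yy + dy).ravel()], axis=1)
                ox, oy = sphere.center_px
                u = (px[:, 0] - ox) * sphere.pixel_scale
                v = (px[:, 1] - oy) * sphere.pixel_scale
                rr = u * u + v * v
                inside = rr < R * R
                z = np.sqrt(np.clip(R * R - rr[inside], 0.0, None))
                pts_list.append(np.stack([u[inside], v[inside], z], axis=1))
                lab_list.append(mask.ravel()[inside])
                val_list.append(np.asarray(view, dtype=float).ravel()[inside])
        pts = np.concatenate(pts_list)
        labs = np.concatenate(lab_list)
        vals = np.concatenate(val_list)
        wts = pts[:, 2] / R
        gpts = pts @ rot.T  # rotate view frame -> global frame
        gi, gj = label_map.bin_index(gpts)
        flat = gi * n_lon + gj
        # within a view, a bin is represented by the deposit closest to
        # the bin centre (an edge deposit would bias boundary bins)
        edges = label_map.lat_edges()
        phi_c = ((edges[:-1] + edges[1:]) / 2.0)[gi]
        lam_c = -np.pi + (gj + 0.5) * 2 * np.pi / n_lon
        phi_p = np.arcsin(np.clip(gpts[:, 1] / R, -1.0, 1.0))
        lam_p = np.arctan2(gpts[:, 0], gpts[:, 2])
        dlam = np.angle(np.exp(1j * (lam_p - lam_c)))
        center_dist = (phi_p - phi_c) ** 2 + (dlam * np.cos(phi_c)) ** 2
        order = np.argsort(-center_dist, kind="stable")  # nearest written last
        flat_s, wt_s, lab_s, val_s = flat[order], wts[order], labs[order], vals[order]
        vw = np.zeros(n_lat * n_lon)
        vl = np.zeros(n_lat * n_lon, dtype=np.int32)
        vv = np.zeros(n_lat * n_lon)
        vw[flat_s] = wt_s
        vl[flat_s] = lab_s
        vv[flat_s] = val_s
        vw = vw.reshape(n_lat, n_lon)
        # strict > keeps the earlier view on ties (lower view index wins)
        better = vw > label_map.weight_grid
        label_map.weight_grid[better] = vw[better]
        label_map.label_grid[better] = vl.reshape(n_lat, n_lon)[better]
        intensity[better] = vv.reshape(n_lat, n_lon)[better]

    intensity_map = SphereLabelMap(
        label_grid=np.rint(intensity * 1000).astype(np.int32),
        weight_grid=label_map.weight_grid.copy(),
        radius_um=R,
    )
    intensity_map.intensity = intensity
    return label_map, intensity_map


def fill_unlabeled(
    map_: SphereLabelMap,
    fill_labels: tuple[int, ...] = (LABEL_UNOBSERVED,),
    max_iter: int = 200,
) -> SphereLabelMap:
    """Assign bins carrying a fill label to an adjacent labelled region.

    Iteratively copies the first labelled neighbour (fixed E,W,S,N then
    diagonal order; longitude wraps) until no fill-labelled bin remains or
    ``max_iter`` passes elapse.  Used to absorb coverage gaps and optional
    boundary ribbons into the surrounding regions before area measurement.
    """
    grid = map_.label_grid.copy()
    fillset = np.isin(grid, fill_labels)
    shifts = [(0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (1, -1), (-1, 1), (-1, -1)]
    for _ in range(max_iter):
        if not fillset.any():
            break
        new = grid.copy()
        newfill = fillset.copy()
        for di, dj in shifts:
            nb = np.roll(grid, shift=(-di, -dj), axis=(0, 1))
            nbfill = np.roll(fillset, shift=(-di, -dj), axis=(0, 1))
            if di == -1:
                nb = nb.copy()
                nbfill = nbfill.copy()
                nb[0, :] = grid[0, :]
                nbfill[0, :] = True
            elif di == 1:
                nb = nb.copy()
                nbfill = nbfill.copy()
                nb[-1, :] = grid[-1, :]
                nbfill[-1, :] = True
            take = newfill & ~nbfill
            new[take] = nb[take]
            newfill[take] = False
        if np.array_equal(new, grid):
            break
        grid, fillset = new, newfill
    return SphereLabelMap(grid, map_.weight_grid.copy(), map_.radius_um)


@dataclass
class CellRegion:
    """One connected surface region of a single label value."""

    label: int
    area_um2: float
    n_bins: int
    indices: tuple[np.ndarray, np.ndarray] = field(repr=False)

    def centroid_xyz(self, map_: SphereLabelMap) -> np.ndarray:
        edges = map_.lat_edges()
        phi = (edges[:-1] + edges[1:]) / 2.0
        lam = -np.pi + (np.arange(map_.n_lon) + 0.5) * 2 * np.pi / map_.n_lon
        i, j = self.indices
        p, l = phi[i], lam[j]
        v = np.stack([np.cos(p) * np.sin(l), np.sin(p), np.cos(p) * np.cos(l)], axis=1)
        m = v.mean(axis=0)
        return m / np.linalg.norm(m)


def connected_regions(
    map_: SphereLabelMap,
    exclude_labels: tuple[int, ...] = (LABEL_UNOBSERVED, LABEL_BOUNDARY),
) -> list[CellRegion]:
    """Connected components on the sphere topology, one region per component.

    Longitude column 0 is adjacent to column ``n_lon - 1``; all top-row
    bins of equal label are mutually adjacent through the pole (likewise
    the bottom row).  Components are computed per label value, so regions
    on opposite sides of a boundary label are never merged.
    """
    grid = map_.label_grid
    n_lat, n_lon = grid.shape
    area_grid = map_.area_grid()
    regions: list[CellRegion] = []
    for val in np.unique(grid):
        if val in exclude_labels:
            continue
        sel = grid == val
        comp, n = ndimage.label(sel, structure=_CONN8)
        if n == 0:
            continue
        parent = list(range(n + 1))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        def union(a, b):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

        # longitude seam (including diagonal adjacency across it)
        left, right = comp[:, 0], comp[:, -1]
        for di in (-1, 0, 1):
            l = left if di == 0 else np.roll(left, di)
            both = (l > 0) & (right > 0)
            if di != 0:  # rolled rows wrap through lat, forbid that
                both[0 if di == 1 else -1] = False
            for a, b in zip(l[both], right[both]):
                union(int(a), int(b))
        # poles: all same-label bins in the extreme rows meet at the pole
        for row in (comp[0, :], comp[-1, :]):
            ids = np.unique(row[row > 0])
            for other in ids[1:]:
                union(int(ids[0]), int(other))
        roots = np.array([0] + [find(i) for i in range(1, n + 1)])
        comp_r = roots[comp]
        for rid in np.unique(comp_r[comp_r > 0]):
            idx = np.nonzero(comp_r == rid)
            regions.append(
                CellRegion(
                    label=int(val),
                    area_um2=float(area_grid[idx].sum()),
                    n_bins=len(idx[0]),
                    indices=idx,
                )
            )
    return regions
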
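"""Inter-view rotation estimation on the blastocyst sphere.

The transformation between two overlapping views of the rotating
blastocyst is a pure 3D rotation about the sphere centre (the holding
micropipette fixes the centre and the embryo is rigid over the minutes of
rotation).  Each view is cropped to the D x D disk, scale/rotation
invariant local features are detected and matched with a Lowe ratio test,
matched keypoints are back-projected to 3D through the orthographic
sphere model, and the rotation is estimated robustly: RANSAC over exact
two-point rotation hypotheses, then an orthogonal-Procrustes (Kabsch/SVD)
refit on the inliers with det = +1 enforced.

Keypoints within 5 degrees of the limb are discarded: there
``z = sqrt(R^2 - u^2 - v^2)`` has an unbounded gradient and the
back-projection is unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import SIFT, match_descriptors

from .sphere3d import BlastocystSphere, backproject

LIMB_EXCLUSION_DEG = 5.0


class InsufficientOverlapError(RuntimeError):
    pass


class RegistrationFailureError(RuntimeError):
    pass


@dataclass
class MatchSet:
    """Matched surface points between two views, both in microns."""

    points_a: np.ndarray  # (N, 3), view-A frame
    points_b: np.ndarray  # (N, 3), view-B frame
    scores: np.ndarray  # descriptor distances (lower is better)

    def __len__(self) -> int:
        return len(self.points_a)


def crop_to_sphere(image: np.ndarray, sphere: BlastocystSphere) -> np.ndarray:
    """Crop to the D x D square centred on O (side rounded up to odd).

    Pixels outside the sphere disk are set to a background sentinel (0).
    """
    side = int(np.ceil(sphere.diameter_um / sphere.pixel_scale)) | 1
    half = side // 2
    cx = int(round(sphere.center_px[0]))
    cy = int(round(sphere.center_px[1]))
    h, w = image.shape
    if cy - half < 0 or cx - half < 0 or cy + half >= h or cx + half >= w:
        raise ValueError(
            f"sphere disk exceeds image bounds: centre ({cx},{cy}), half-side {half}, "
            f"image {w}x{h}"
        )
    out = np.array(image[cy - half : cy + half + 1, cx - half : cx + half + 1], dtype=float)
    yy, xx = np.mgrid[0:side, 0:side]
    r2 = ((xx - half) ** 2 + (yy - half) ** 2) * sphere.pixel_scale**2
    out[r2 >= sphere.radius_um**2] = 0.0
    return out


def _as_u8(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    if hi <= lo:
        return np.zeros(img.shape, dtype=np.uint8)
    return ((img - lo) / (hi - lo) * 255).astype(np.uint8)


def detect_features(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """SIFT keypoints (row, col) and descriptors of one cropped view."""
    detector = SIFT(c_dog=0.002)
    try:
        detector.detect_and_extract(_as_u8(image))
    except RuntimeError as exc:  # skimage raises when no keypoints found
        raise InsufficientOverlapError(f"feature detection failed: {exc}") from exc
    return detector.keypoints, detector.descriptors


def detect_and_match(
    view_a: np.ndarray,
    view_b: np.ndarray,
    sphere: BlastocystSphere,
    max_ratio: float = 0.75,
) -> MatchSet:
    """SIFT features + Lowe-ratio matching, back-projected to 3D.

    Both views must already be cropped to the sphere disk with O at the
    image centre.  Raises :class:`InsufficientOverlapError` when fewer
    than 4 matches survive.
    """
    return match_features(
        detect_features(view_a), detect_features(view_b), sphere, max_ratio
    )


def match_features(
    features_a: tuple[np.ndarray, np.ndarray],
    features_b: tuple[np.ndarray, np.ndarray],
    sphere: BlastocystSphere,
    max_ratio: float = 0.75,
) -> MatchSet:
    """Match pre-detected features and back-project them to the sphere."""
    keypoints_a, descriptors_a = features_a
    keypoints_b, descriptors_b = features_b
    matches = match_descriptors(
        descriptors_a,
        descriptors_b,
        cross_check=True,
        max_ratio=max_ratio,
    )
    if len(matches) == 0:
        raise InsufficientOverlapError("no descriptor matches between views")
    # skimage keypoints are (row, col) -> pixel (x, y) = (col, row)
    kp_a = keypoints_a[matches[:, 0]][:, ::-1].astype(float)
    kp_b = keypoints_b[matches[:, 1]][:, ::-1].astype(float)
    dist = np.linalg.norm(
        descriptors_a[matches[:, 0]].astype(float)
        - descriptors_b[matches[:, 1]].astype(float),
        axis=1,
    )

    R = sphere.radius_um
    limb_z = R * np.sin(np.radians(LIMB_EXCLUSION_DEG))

    def inside(kp):
        ox, oy = sphere.center_px
        r2 = ((kp[:, 0] - ox) ** 2 + (kp[:, 1] - oy) ** 2) * sphere.pixel_scale**2
        return r2 < R * R

    keep = inside(kp_a) & inside(kp_b)
    kp_a, kp_b, dist = kp_a[keep], kp_b[keep], dist[keep]
    pa = backproject(kp_a, sphere)
    pb = backproject(kp_b, sphere)
    keep = (pa[:, 2] > limb_z) & (pb[:, 2] > limb_z)
    pa, pb, dist = pa[keep], pb[keep], dist[keep]
    if len(pa) < 4:
        raise InsufficientOverlapError(
            f"only {len(pa)} matches survive limb filtering between the view pair"
        )
    return MatchSet(points_a=pa, points_b=pb, scores=dist)


def _two_point_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray | None:
    """Exact rotation taking unit pairs (a1, a2) onto (b1, b2) via triads."""

    def triad(p1, p2):
        u1 = p1 / np.linalg.norm(p1)
        c = np.cross(p1, p2)
        nc = np.linalg.norm(c)
        if nc < 1e-12:
            return None
        u3 = c / nc
        return np.stack([u1, np.cross(u3, u1), u3], axis=1)

    ta, tb = triad(a[0], a[1]), triad(b[0], b[1])
    if ta is None or tb is None:
        return None
    return tb @ ta.T


def kabsch(points_a: np.ndarray, points_b: np.ndarray) -> np.ndarray:
    """Orthogonal-Procrustes rotation A -> B by SVD, det = +1 enforced."""
    H = points_a.T @ points_b
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def estimate_rotation(
    matches: MatchSet,
    threshold_deg: float = 2.0,
    max_iter: int = 500,
    min_inliers: int = 6,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Robust rotation mapping frame A -> frame B from matched 3D points.

    RANSAC draws 2 pairs per hypothesis, solves the exact two-point
    rotation and scores by angular residual; the best consensus set is
    refit with :func:`kabsch`.

    Returns
    -------
    (rotation, inlier_mask)
    """
    n = len(matches)
    if n < 3:
        raise RegistrationFailureError(f"need >= 3 pairs, got {n}")
    a = matches.points_a / np.linalg.norm(matches.points_a, axis=1, keepdims=True)
    b = matches.points_b / np.linalg.norm(matches.points_b, axis=1, keepdims=True)
    thr = np.radians(threshold_deg)
    rng = np.random.default_rng(seed)
    best_mask = None
    best_count = 0
    for _ in range(max_iter):
        i, j = rng.choice(n, size=2, replace=False)
        R = _two_point_rotation(a[[i, j]], b[[i, j]])
        if R is None:
            continue
        resid = np.arccos(np.clip(np.sum((a @ R.T) * b, axis=1), -1.0, 1.0))
        mask = resid <= thr
        if mask.sum() > best_count:
            best_count = int(mask.sum())
            best_mask = mask
    if best_mask is None or best_count < min_inliers:
        raise RegistrationFailureError(
            f"RANSAC found only {best_count} inliers (< {min_inliers})"
        )
    R = kabsch(a[best_mask], b[best_mask])
    # coarse-to-fine refinement: tighten the residual gate so marginal
    # matches stop polluting the least-squares fit
    for gate in (thr, thr / 2.0, thr / 4.0):
        resid = np.arccos(np.clip(np.sum((a @ R.T) * b, axis=1), -1.0, 1.0))
        mask = resid <= gate
        if mask.sum() < min_inliers:
            break
        R = kabsch(a[mask], b[mask])
        best_mask = mask
    return R, best_mask


def chain_rotations(pairwise: list[np.ndarray]) -> list[np.ndarray]:
    """Global rotations G_i (view i -> view 0) from adjacent-pair rotations.

    ``pairwise[i]`` maps view i to view i+1, so ``G_0 = I`` and
    ``G_{i+1} = G_i @ pairwise[i]^-1`` (matrices act on column vectors).
    """
    G = [np.eye(3)]
    for P in pairwise:
        G.append(G[-1] @ np.asarray(P).T)
    return G


def register_sequence(
    images: list[np.ndarray],
    sphere: BlastocystSphere,
    max_ratio: float = 0.75,
    threshold_deg: float = 2.0,
    max_iter: int = 500,
    min_inliers: int = 6,
    seed: int = 0,
) -> tuple[list[np.ndarray], list[dict]]:
    """Register every adjacent view pair and chain to global rotations.

    Images must be cropped (O at centre).  Returns the global rotations
    (view i -> view 0) and per-pair diagnostics.
    """
    pairwise = []
    diagnostics = []
    features = [detect_features(im) for im in images]
    for i in range(len(images) - 1):
        matches = match_features(features[i], features[i + 1], sphere, max_ratio=max_ratio)
        R, inliers = estimate_rotation(
            matches,
            threshold_deg=threshold_deg,
            max_iter=max_iter,
            min_inliers=min_inliers,
            seed=seed + i,
        )
        a = matches.points_a[inliers] / np.linalg.norm(
            matches.points_a[inliers], axis=1, keepdims=True
        )
        b = matches.points_b[inliers] / np.linalg.norm(
            matches.points_b[inliers], axis=1, keepdims=True
        )
        resid = np.degrees(np.arccos(np.clip(np.sum((a @ R.T) * b, axis=1), -1, 1)))
        diagnostics.append(
            {
                "pair": (i, i + 1),
                "n_matches": len(matches),
                "n_inliers": int(inliers.sum()),
                "residual_deg_median": float(np.median(resid)),
            }
        )
        pairwise.append(R)
    return chain_rotations(pairwise), diagnostics
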
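"""Spherical geometry: back-projection, bin areas, stitching, regions."""

import numpy as np
import pytest

from blastomorph import synthgen
from blastomorph.sphere3d import (
    LABEL_ICM,
    BlastocystSphere,
    OutOfSphereError,
    SphereLabelMap,
    backproject,
    connected_regions,
    fill_unlabeled,
    project_views,
    rotation_matrix,
)


@pytest.fixture()
def sphere():
    return BlastocystSphere(center_px=(0.0, 0.0), diameter_um=200.0, pixel_scale=1.0)


class TestBackproject:
    def test_pole(self, sphere):
        assert backproject(np.array([0.0, 0.0]), sphere) == pytest.approx([0, 0, 100])

    def test_limb_point(self, sphere):
        assert backproject(np.array([60.0, 80.0]), sphere) == pytest.approx([60, 80, 0])

    def test_interior_point(self, sphere):
        # z = sqrt(100^2 - 30^2 - 40^2) = sqrt(7500)
        p = backproject(np.array([30.0, 40.0]), sphere)
        assert p == pytest.approx([30, 40, 86.6025], abs=1e-4)

    def test_outside_disk_rejected(self, sphere):
        with pytest.raises(OutOfSphereError):
            backproject(np.array([90.0, 90.0]), sphere)

    def test_norm_invariant(self, sphere, rng):
        r = 99.0 * np.sqrt(rng.random(100))
        th = rng.uniform(0, 2 * np.pi, 100)
        pts = backproject(np.stack([r * np.cos(th), r * np.sin(th)], axis=1), sphere)
        assert np.allclose(np.linalg.norm(pts, axis=1), 100.0, rtol=1e-9)


class TestBinAreas:
    @pytest.mark.parametrize("shape", [(256, 512), (128, 256), (37, 91)])
    def test_total_area_is_sphere_area(self, shape):
        m = SphereLabelMap.empty(*shape, radius_um=92.0)
        assert m.total_area() == pytest.approx(np.pi * 184.0**2, rel=1e-9)

    def test_equatorial_bin_larger_than_polar(self):
        m = SphereLabelMap.empty(64, 128, radius_um=50.0)
        assert m.bin_area(32, 0) > m.bin_area(0, 0)

    def test_hemisphere_area(self):
        m = SphereLabelMap.empty(64, 128, radius_um=50.0)
        rows = m.row_areas()[32:]  # phi in [0, pi/2]
        assert rows.sum() * 128 == pytest.approx(2 * np.pi * 50.0**2, rel=1e-9)


class TestProjection:
    def test_single_view_covers_front_hemisphere(self, truth):
        v = synthgen.render_view(truth, np.eye(3), pixel_scale=0.5)
        side = v.image.shape[0]
        sph = BlastocystSphere(((side - 1) / 2, (side - 1) / 2), truth.diameter_um, 0.5)
        m, _ = project_views([v.image], [v.mask], [np.eye(3)], sph, (128, 256))
        # front hemisphere is longitude (-pi/2, pi/2): columns 64..192;
        # pole rows hold bins smaller than a pixel, so skip them
        front = m.label_grid[10:-10, 70:186]
        back = m.label_grid[:, :58]
        assert (front != 0).mean() > 0.99
        assert (back == 0).all()

    def test_full_sequence_coverage_and_fidelity(self, truth, sequence):
        side = sequence.views[0].image.shape[0]
        sph = BlastocystSphere(((side - 1) / 2, (side - 1) / 2), truth.diameter_um, 0.5)
        m, _ = project_views(
            sequence.images, sequence.masks, sequence.true_rotations, sph, (128, 256)
        )
        observed = m.label_grid != 0
        # area-weighted coverage: pole bins are far smaller than a pixel,
        # so the surface fraction observed is the meaningful measure
        assert m.area_of(observed) / m.total_area() >= 0.99
        assert observed.mean() >= 0.90
        # stitched labels agree with the independent truth of each bin centre
        edges = m.lat_edges()
        phi = (edges[:-1] + edges[1:]) / 2
        lam = -np.pi + (np.arange(m.n_lon) + 0.5) * 2 * np.pi / m.n_lon
        P, L = np.meshgrid(phi, lam, indexing="ij")
        xyz = np.stack(
            [np.cos(P) * np.sin(L), np.sin(P), np.cos(P) * np.cos(L)], axis=-1
        )
        from scipy.spatial import cKDTree

        _, idx = cKDTree(truth.all_sites()).query(xyz[observed])
        expect = np.where(idx >= truth.n_te_cells, LABEL_ICM, idx + 3)
        agree = (m.label_grid[observed] == expect).mean()
        assert agree >= 0.99

    def test_projection_idempotent(self, truth):
        v = synthgen.render_view(truth, np.eye(3), pixel_scale=0.5)
        side = v.image.shape[0]
        sph = BlastocystSphere(((side - 1) / 2, (side - 1) / 2), truth.diameter_um, 0.5)
        once, _ = project_views([v.image], [v.mask], [np.eye(3)], sph, (64, 128))
        twice, _ = project_views(
            [v.image, v.image], [v.mask, v.mask], [np.eye(3), np.eye(3)], sph, (64, 128)
        )
        assert np.array_equal(once.label_grid, twice.label_grid)

    def test_mismatched_lengths_rejected(self, sphere):
        with pytest.raises(ValueError, match="equal lengths"):
            project_views([np.zeros((5, 5))], [], [np.eye(3)], sphere)


def _cap_map(n_lat, n_lon, radius, caps):
    """Label map with spherical caps: caps = [(axis, half_angle, label)]."""
    m = SphereLabelMap.empty(n_lat, n_lon, radius)
    edges = m.lat_edges()
    phi = (edges[:-1] + edges[1:]) / 2
    lam = -np.pi + (np.arange(n_lon) + 0.5) * 2 * np.pi / n_lon
    P, L = np.meshgrid(phi, lam, indexing="ij")
    xyz = np.stack([np.cos(P) * np.sin(L), np.sin(P), np.cos(P) * np.cos(L)], axis=-1)
    for axis, half, label in caps:
        sel = xyz @ np.asarray(axis, float) > np.cos(half)
        m.label_grid[sel] = label
    m.weight_grid[:] = 1.0
    return m


class TestConnectedRegions:
    def test_seam_crossing_region_is_one(self):
        # cap centred on longitude +-180 (the -z axis) crosses the seam
        m = _cap_map(64, 128, 50.0, [([0, 0, -1], 0.4, 5)])
        regions = [r for r in connected_regions(m) if r.label == 5]
        assert len(regions) == 1

    def test_cap_areas_match_closed_form(self):
        R = 80.0
        caps = [([0, 0, 1], 0.5, 5), ([1, 0, 0], 0.3, 6), ([0, 1, 0], 0.35, 7)]
        m = _cap_map(256, 512, R, caps)
        regions = connected_regions(m)
        assert len(regions) == 3
        row_area = 2 * np.pi * R * R / 256 / 2  # one bin-row of area margin
        for axis, half, label in caps:
            (r,) = [q for q in regions if q.label == label]
            exact = 2 * np.pi * R * R * (1 - np.cos(half))
            assert abs(r.area_um2 - exact) < 2 * np.pi * R * np.sin(half) * R * np.pi / 256 + row_area

    def test_component_count_matches_graph_oracle(self, rng):
        """Flood fill on an explicit wraparound adjacency graph agrees."""
        m = SphereLabelMap.empty(36, 72, 10.0)
        m.label_grid[:] = rng.integers(0, 3, size=(36, 72)) * 3  # labels 0, 3, 6
        regions = connected_regions(m)
        # brute-force BFS with the same topology
        import networkx as nx

        G = nx.Graph()
        n_lat, n_lon = 36, 72
        for i in range(n_lat):
            for j in range(n_lon):
                if m.label_grid[i, j] == 0:
                    continue
                G.add_node((i, j))
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ii, jj = i + di, (j + dj) % n_lon
                        if (di, dj) == (0, 0) or not (0 <= ii < n_lat):
                            continue
                        if m.label_grid[ii, jj] == m.label_grid[i, j]:
                            G.add_edge((i, j), (ii, jj))
        for row in (0, n_lat - 1):  # pole adjacency
            for label in (3, 6):
                cols = [j for j in range(n_lon) if m.label_grid[row, j] == label]
                for a, b in zip(cols, cols[1:]):
                    G.add_edge((row, a), (row, b))
        assert len(regions) == nx.number_connected_components(G)


def test_fill_unlabeled_absorbs_holes():
    m = _cap_map(64, 128, 50.0, [([0, 0, 1], 2.0, 5)])
    m.label_grid[10:12, 30:33] = 0  # punch a hole
    filled = fill_unlabeled(m, (0,))
    assert (filled.label_grid != 0).all()
    assert (filled.label_grid[10:12, 30:33] == 5).all()


def test_label_map_roundtrip(tmp_path):
    m = _cap_map(32, 64, 40.0, [([0, 0, 1], 0.7, 5)])
    path = tmp_path / "map.tif"
    m.save(path)
    back = SphereLabelMap.load(path)
    assert np.array_equal(back.label_grid, m.label_grid)
    assert back.radius_um == m.radius_um


def test_rotation_matrix_orthogonal(rng):
    for _ in range(5):
        axis = rng.normal(size=3)
        R = rotation_matrix(axis, rng.uniform(-np.pi, np.pi))
        assert np.allclose(R.T @ R, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)
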
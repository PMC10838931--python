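"""Mesh primitives: icospheres, decimation, geodesic patches, queries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import Delaunay

from opmlesion import (
    TriangleMesh,
    VertexPatch,
    decimate,
    geodesic_disk,
    k_nearest_vertices,
    make_icosphere,
    merge_meshes,
    patch_summary,
)


class TestIcosphere:
    @pytest.mark.parametrize("order", [0, 1, 2, 3, 4])
    def test_subdivision_counts(self, order):
        m = make_icosphere(order, 1.0)
        assert m.n_vertices == 10 * 4**order + 2
        assert m.n_faces == 20 * 4**order
        assert m.is_closed()
        assert m.is_oriented()
        assert m.euler_characteristics() == [2]

    def test_projection_to_sphere(self):
        m = make_icosphere(3, 70.0)
        r = np.linalg.norm(m.vertices, axis=1)
        assert np.allclose(r, 70.0, atol=1e-9 * 70.0)

    def test_normals_unit_outward(self):
        m = make_icosphere(2, 50.0)
        n = m.vertex_normals
        assert np.allclose(np.linalg.norm(n, axis=1), 1.0, atol=1e-6)
        # outward on a sphere: aligned with the radial direction
        rad = m.vertices / np.linalg.norm(m.vertices, axis=1, keepdims=True)
        assert np.all(np.sum(n * rad, axis=1) > 0.99)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            make_icosphere(2, -1.0)
        with pytest.raises(ValueError):
            make_icosphere(9, 1.0)

    def test_two_hemisphere_container(self):
        a = make_icosphere(2, 70.0)
        b = make_icosphere(2, 70.0)
        both = merge_meshes(a, b)
        assert both.n_vertices == 2 * a.n_vertices
        assert both.euler_characteristics() == [2, 2]


class TestDecimate:
    def test_identity_factor(self):
        m = make_icosphere(3, 70.0)
        d = decimate(m, 1.0)
        assert np.array_equal(d.vertices, m.vertices)
        assert np.array_equal(d.faces, m.faces)

    def test_order5_factor10(self):
        """10,242 vertices / 10 -> within +-5% of 1,024, still a closed
        oriented sphere."""
        m = make_icosphere(5, 70.0)
        d = decimate(m, 10.0)
        assert 973 <= d.n_vertices <= 1075
        assert d.is_closed()
        assert d.is_oriented()
        assert d.euler_characteristics() == [2]

    def test_geometry_preserved(self):
        m = make_icosphere(4, 70.0)
        d = decimate(m, 4.0)
        r = np.linalg.norm(d.vertices, axis=1)
        assert abs(r.mean() - 70.0) < 2.0
        assert d.total_area == pytest.approx(m.total_area, rel=0.05)

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            decimate(make_icosphere(2, 1.0), 0.5)


class TestGeodesicDisk:
    def test_full_area_is_whole_mesh(self):
        m = make_icosphere(2, 50.0)
        p = geodesic_disk(m, 0, m.total_area)
        assert len(p) == m.n_vertices

    def test_patch_size_tracks_area(self):
        m = make_icosphere(4, 70.0)
        target = 800.0
        p = geodesic_disk(m, 123, target)
        per_vertex = m.total_area / m.n_vertices
        expected = target / per_vertex
        assert abs(len(p) - expected) <= 0.2 * expected + 1

    def test_monotone_in_area(self):
        m = make_icosphere(3, 70.0)
        small = geodesic_disk(m, 50, 500.0)
        large = geodesic_disk(m, 50, 2000.0)
        assert set(small.indices) <= set(large.indices)

    def test_connected(self):
        m = make_icosphere(3, 70.0)
        p = geodesic_disk(m, 7, 1500.0)
        assert p.is_connected()

    def test_bad_seed(self):
        m = make_icosphere(2, 50.0)
        with pytest.raises(IndexError):
            geodesic_disk(m, m.n_vertices + 5, 10.0)


class TestPatchSummary:
    def test_single_vertex(self):
        m = make_icosphere(2, 50.0)
        p = VertexPatch(m, np.array([11]))
        s = patch_summary(p)
        assert np.allclose(s["mean_position"], m.vertices[11])
        assert s["com_vertex"] == 11
        assert list(s["boundary_vertices"]) == [11]
        assert s["hull_volume_cm3"] == 0.0

    def test_symmetric_cap_com_is_apex(self):
        m = make_icosphere(3, 70.0)
        apex = int(np.argmax(m.vertices[:, 2]))
        p = geodesic_disk(m, apex, 900.0)
        assert p.com_vertex == apex

    def test_boundary_matches_bruteforce(self):
        m = make_icosphere(3, 70.0)
        p = geodesic_disk(m, 200, 2500.0)
        member = set(p.indices.tolist())
        neigh = {v: set() for v in member}
        for a, b in m.edges:
            a, b = int(a), int(b)
            if a in member:
                neigh[a].add(b)
            if b in member:
                neigh[b].add(a)
        brute = sorted(v for v in member if neigh[v] - member)
        assert sorted(p.boundary_vertices.tolist()) == brute

    def test_hull_volume_against_montecarlo(self, rng):
        m = make_icosphere(3, 70.0)
        p = geodesic_disk(m, 99, 3000.0)
        vol = p.hull_volume_cm3() * 1000.0  # mm^3
        pts = m.vertices[p.indices]
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        samples = rng.uniform(lo, hi, size=(40000, 3))
        tri = Delaunay(pts)
        frac = np.mean(tri.find_simplex(samples) >= 0)
        box = np.prod(hi - lo)
        assert vol == pytest.approx(frac * box, rel=0.05)

    def test_empty_patch_rejected(self):
        m = make_icosphere(1, 10.0)
        with pytest.raises(ValueError):
            VertexPatch(m, np.array([], dtype=int))


class TestKNearest:
    def test_exact_vertex(self):
        m = make_icosphere(3, 70.0)
        p = k_nearest_vertices(m, m.vertices[17], 1)
        assert list(p.indices) == [17]

    def test_whole_mesh(self):
        m = make_icosphere(1, 10.0)
        p = k_nearest_vertices(m, [0.0, 0.0, 0.0], m.n_vertices)
        assert len(p) == m.n_vertices

    def test_too_many(self):
        m = make_icosphere(1, 10.0)
        with pytest.raises(ValueError):
            k_nearest_vertices(m, [0, 0, 0], m.n_vertices + 1)

    @settings(max_examples=25, deadline=None)
    @given(
        x=st.floats(-80, 80),
        y=st.floats(-80, 80),
        z=st.floats(-80, 80),
        k=st.integers(1, 100),
    )
    def test_matches_exhaustive_sort(self, x, y, z, k):
        m = make_icosphere(2, 70.0)
        p = k_nearest_vertices(m, [x, y, z], k)
        d = np.linalg.norm(m.vertices - np.array([x, y, z]), axis=1)
        expected = np.lexsort((np.arange(len(d)), d))[:k]
        assert set(p.indices) == set(expected)
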
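"""Low-level geometry kernels: triangle-pair distances, convex GJK,
mesh integrity helpers, polygon routines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rtclear as rc
from rtclear._gjk import gjk_distance
from rtclear._polygon import ear_clip, ensure_ccw, is_simple, signed_area
from rtclear._tridist import (
    point_triangle_distance,
    segment_segment_distance,
    tri_tri_distance,
)
from rtclear.mesh import TriMesh

finite = st.floats(-50.0, 50.0, allow_nan=False, allow_infinity=False)


def _sample_triangle(tri, m=50):
    u = np.linspace(0, 1, m)
    U, V = np.meshgrid(u, u)
    keep = U + V <= 1
    U, V = U[keep], V[keep]
    return tri[0] + np.outer(U, tri[1] - tri[0]) + np.outer(V, tri[2] - tri[0])


class TestTriTriDistance:
    def test_parallel_triangles(self):
        ta = np.array([[[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]])
        tb = ta + np.array([0.0, 0.0, 3.0])
        assert tri_tri_distance(ta, tb)[0] == pytest.approx(3.0, abs=1e-12)

    def test_crossing_triangles_are_zero(self):
        # a large X: boundaries far apart, surfaces crossing
        ta = np.array([[[-5.0, 0, 0], [5, 0, 0], [0, 10, 0]]])
        tb = np.array([[[0.0, 3, -5], [0, 3, 5], [0, 13, 0]]])
        assert tri_tri_distance(ta, tb)[0] == 0.0

    def test_shared_edge_is_zero(self):
        ta = np.array([[[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]])
        tb = np.array([[[0.0, 0, 0], [1, 0, 0], [0, -1, 1]]])
        assert tri_tri_distance(ta, tb)[0] == 0.0

    @settings(max_examples=150, deadline=None)
    @given(st.lists(finite, min_size=18, max_size=18))
    def test_never_above_dense_sampling(self, coords):
        tri = np.asarray(coords).reshape(2, 3, 3)
        ta, tb = tri[0], tri[1]
        # skip degenerate triangles
        if (
            np.linalg.norm(np.cross(ta[1] - ta[0], ta[2] - ta[0])) < 1e-6
            or np.linalg.norm(np.cross(tb[1] - tb[0], tb[2] - tb[0])) < 1e-6
        ):
            return
        d = float(tri_tri_distance(ta[None], tb[None])[0])
        pa, pb = _sample_triangle(ta), _sample_triangle(tb)
        sampled = np.sqrt(((pa[:, None] - pb[None, :]) ** 2).sum(-1)).min()
        assert d <= sampled + 1e-9  # exact min is a lower bound of sampled
        assert sampled - d < 4.0  # and sampling converges toward it

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        ta = rng.normal(size=(20, 3, 3))
        tb = rng.normal(size=(20, 3, 3)) + [1.5, 0, 0]
        assert np.allclose(
            tri_tri_distance(ta, tb), tri_tri_distance(tb, ta), atol=1e-12
        )


class TestSegmentAndPointKernels:
    def test_segment_cases(self):
        p1, q1 = np.array([[0.0, 0, 0]]), np.array([[1.0, 0, 0]])
        # parallel
        assert segment_segment_distance(
            p1, q1, p1 + [0, 2, 0], q1 + [0, 2, 0]
        )[0] == pytest.approx(2.0)
        # skew crossing above
        p2, q2 = np.array([[0.5, -1, 1.0]]), np.array([[0.5, 1, 1.0]])
        assert segment_segment_distance(p1, q1, p2, q2)[0] == pytest.approx(1.0)
        # endpoint-endpoint
        p3, q3 = np.array([[3.0, 4, 0]]), np.array([[5.0, 4, 0]])
        assert segment_segment_distance(p1, q1, p3, q3)[0] == pytest.approx(
            np.hypot(2, 4)
        )

    def test_point_triangle_regions(self):
        tri = np.array([[[0.0, 0, 0], [2, 0, 0], [0, 2, 0]]])
        # above interior
        assert point_triangle_distance(np.array([[0.5, 0.5, 3.0]]), tri)[0] == 3.0
        # beyond a vertex
        assert point_triangle_distance(np.array([[-1.0, -1, 0]]), tri)[
            0
        ] == pytest.approx(np.sqrt(2))
        # beyond an edge
        assert point_triangle_distance(np.array([[1.0, -2.0, 0]]), tri)[
            0
        ] == pytest.approx(2.0)


class TestGJK:
    def test_matches_mesh_distance_on_boxes(self):
        from rtclear.machine import PrimitiveSpec, build_primitive_mesh

        a = build_primitive_mesh(PrimitiveSpec("box", {"size_mm": (40, 60, 80)}))
        b = build_primitive_mesh(
            PrimitiveSpec(
                "box", {"size_mm": (40, 60, 80)}, translation_mm=(55.0, 10.0, -5.0)
            )
        )
        assert gjk_distance(a.vertices, b.vertices) == pytest.approx(15.0, abs=1e-9)

    def test_overlap_returns_zero(self):
        cube = np.array(
            [[x, y, z] for x in (0, 1.0) for y in (0, 1.0) for z in (0, 1.0)]
        )
        assert gjk_distance(cube, cube + 0.5) == 0.0

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_on_random_hulls(self, seed):
        from conftest import random_convex_mesh
        from rtclear.metrics import brute_force_min_distance

        rng = np.random.default_rng(seed)
        a = random_convex_mesh(rng, n_points=12, offset=rng.uniform(-50, 50, 3))
        b = random_convex_mesh(rng, n_points=12, offset=rng.uniform(-50, 50, 3))
        g = gjk_distance(a.vertices, b.vertices)
        bf = brute_force_min_distance(a, b)
        assert g == pytest.approx(bf, abs=1e-7)

    def test_transform_support_equals_transformed_vertices(self):
        from rtclear.kinematics import couch_transform

        rng = np.random.default_rng(8)
        a = rng.normal(size=(20, 3)) * 10 + [40, 0, 0]
        b = rng.normal(size=(20, 3)) * 10
        t = couch_transform(73.0, (5.0, -8.0, 2.0))
        d1 = gjk_distance(a, b, t.rotation, t.translation)
        d2 = gjk_distance(a, t.apply(b))
        assert d1 == pytest.approx(d2, abs=1e-9)


class TestTriMesh:
    def test_watertight_detects_missing_face(self):
        from rtclear.machine import PrimitiveSpec, build_primitive_mesh

        box = build_primitive_mesh(PrimitiveSpec("box", {"size_mm": (10, 10, 10)}))
        assert box.is_watertight()
        holed = TriMesh(box.vertices, box.triangles[:-1])
        assert not holed.is_watertight()

    def test_watertight_detects_inconsistent_winding(self):
        from rtclear.machine import PrimitiveSpec, build_primitive_mesh

        box = build_primitive_mesh(PrimitiveSpec("box", {"size_mm": (10, 10, 10)}))
        tris = box.triangles.copy()
        tris[0] = tris[0][::-1]
        assert not TriMesh(box.vertices, tris).is_watertight()

    def test_signed_volume_sign_flips_with_orientation(self):
        from rtclear.machine import PrimitiveSpec, build_primitive_mesh

        box = build_primitive_mesh(PrimitiveSpec("box", {"size_mm": (10, 20, 30)}))
        flipped = TriMesh(box.vertices, box.triangles[:, ::-1])
        assert box.signed_volume() == pytest.approx(6000.0)
        assert flipped.signed_volume() == pytest.approx(-6000.0)

    def test_volume_against_trimesh_library(self, body_mesh):
        tm = body_mesh.to_trimesh()
        assert tm.is_watertight
        assert body_mesh.signed_volume() == pytest.approx(tm.volume, rel=1e-9)

    def test_subdivision_preserves_surface_and_volume(self, body_mesh):
        sub = body_mesh.subdivided(20.0)
        assert sub.n_triangles > body_mesh.n_triangles
        assert sub.signed_volume() == pytest.approx(
            body_mesh.signed_volume(), rel=1e-12
        )
        tc = sub.triangle_corners()
        edges = np.linalg.norm(np.roll(tc, -1, axis=1) - tc, axis=2)
        assert edges.max() <= 20.0 + 1e-9

    def test_export_import_round_trip(self, tmp_path, body_mesh):
        path = tmp_path / "body.stl"
        body_mesh.export(path)
        back = TriMesh.load(path)
        assert back.n_triangles == body_mesh.n_triangles
        assert back.signed_volume() == pytest.approx(
            body_mesh.signed_volume(), rel=1e-6
        )


class TestPolygonHelpers:
    def test_signed_area_orientation(self):
        sq = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        assert signed_area(sq) == pytest.approx(1.0)
        assert signed_area(sq[::-1]) == pytest.approx(-1.0)
        assert signed_area(ensure_ccw(sq[::-1])) == pytest.approx(1.0)

    def test_simplicity_scan(self):
        bow = np.array([[0.0, 0], [1, 1], [1, 0], [0, 1]])
        assert not is_simple(bow)
        assert is_simple(np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]]))

    def test_ear_clip_nonconvex_area_preserved(self):
        # L-shaped (non-convex) outline
        poly = np.array(
            [[0.0, 0], [4, 0], [4, 1], [1, 1], [1, 3], [0, 3]], dtype=float
        )
        tris = ear_clip(poly)
        assert len(tris) == len(poly) - 2
        area = 0.0
        for i, j, k in tris:
            a, b, c = poly[i], poly[j], poly[k]
            area += 0.5 * ((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))
        assert area == pytest.approx(signed_area(poly))

    def test_ear_clip_rejects_degenerate(self):
        with pytest.raises(ValueError):
            ear_clip(np.array([[0.0, 0], [1, 0], [2, 0]]))
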
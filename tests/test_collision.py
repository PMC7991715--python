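"""Proximity engine: exactness vs the brute-force oracle, margin semantics,
sweeps, boundary angles, trigger events."""

import numpy as np
import pytest

import rtclear as rc
from rtclear import (
    CollisionChecker,
    MachineState,
    TriMesh,
    boundary_gantry_angles,
    collides,
    min_distance,
    paper_grid_couch_angles,
    paper_grid_gantry_angles,
    sweep_map,
    trajectory_events,
)
from rtclear.collision import PairClearance, CollisionResult
from rtclear.errors import RTClearError
from rtclear.machine import PrimitiveSpec, assemble_scene, build_primitive_mesh
from rtclear.metrics import brute_force_min_distance

from conftest import random_convex_mesh


def box(size, offset=(0.0, 0.0, 0.0)):
    return build_primitive_mesh(
        PrimitiveSpec("box", {"size_mm": tuple(size)}, translation_mm=tuple(offset))
    )


class TestMinDistance:
    def test_axis_aligned_gap_exact(self):
        a = box((100, 200, 300))
        b = box((100, 200, 300), offset=(107.0, 0.0, 0.0))
        assert min_distance(a, b) == pytest.approx(7.0, abs=1e-9)

    def test_overlap_is_zero(self):
        assert min_distance(box((100,) * 3), box((100,) * 3, offset=(50, 0, 0))) == 0.0

    def test_touching_is_zero(self):
        assert min_distance(box((100,) * 3), box((100,) * 3, offset=(100, 0, 0))) == 0.0

    def test_matches_brute_force_on_random_pairs(self):
        # the acceptance-grade oracle equivalence check, 100 random pairs
        rng = np.random.default_rng(42)
        for _ in range(100):
            a = random_convex_mesh(rng, offset=rng.uniform(-60, 60, 3))
            b = random_convex_mesh(rng, offset=rng.uniform(-60, 60, 3))
            assert a.n_triangles <= 200 and b.n_triangles <= 200
            assert min_distance(a, b) == pytest.approx(
                brute_force_min_distance(a, b), abs=1e-9
            )

    def test_rotational_invariance(self):
        from rtclear.kinematics import gantry_transform

        rng = np.random.default_rng(1)
        a = random_convex_mesh(rng, offset=(40, 0, 0))
        b = random_convex_mesh(rng, offset=(-40, 10, 5))
        d0 = min_distance(a, b)
        t = gantry_transform(123.4)
        assert min_distance(a.transformed(t), b.transformed(t)) == pytest.approx(
            d0, abs=1e-9
        )

    def test_empty_mesh_rejected(self):
        a = box((10, 10, 10))
        empty = TriMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(RTClearError):
            min_distance(a, empty)


class TestCollides:
    def _result(self, clearance, margin=30.0):
        p = PairClearance("a", "b", clearance, margin)
        return CollisionResult(p.colliding, [p], clearance)

    def test_boundary_counts_as_collision(self):
        assert self._result(30.0).colliding  # equality -> collision
        assert not self._result(30.0001).colliding
        assert self._result(0.0).colliding

    def test_margin_monotone(self):
        for clearance in (0.0, 10.0, 29.0, 30.0, 31.0, 100.0):
            for m1 in (0.0, 10.0, 30.0):
                for m2 in (m1, m1 + 10.0):
                    c1 = PairClearance("a", "b", clearance, m1).colliding
                    c2 = PairClearance("a", "b", clearance, m2).colliding
                    assert (not c1) or c2  # colliding at m1 => colliding at m2

    def test_scene_result_lists_every_pair(self, machine_a):
        scene = assemble_scene(machine_a, MachineState(120.0, 330.0, (0, 0, -30.0)))
        res = collides(scene, machine_a)
        # 3 gantry comps x (plate, base, rotator)
        assert len(res.per_pair) == 9
        assert res.min_clearance_mm == pytest.approx(
            min(p.clearance_mm for p in res.per_pair)
        )
        guard_pairs = [p for p in res.per_pair if "touch_guard" in (p.label_a, p.label_b)]
        assert all(p.margin_mm == 0.0 for p in guard_pairs)


class TestCheckerConsistency:
    def test_cells_match_independent_evaluations(self, machine_a, checker_a):
        rng = np.random.default_rng(4)
        couch = [0.0, 330.0]
        gantry = [90.0, 130.0, 200.0]
        positions = [(0.0, 0.0, -650.0), (0.0, 0.0, -30.0)]
        cmap = sweep_map(
            machine_a,
            couch_angles_deg=couch,
            gantry_angles_deg=gantry,
            positions_mm=positions,
            checker=checker_a,
        )
        for i, ca in enumerate(couch):
            for j, ga in enumerate(gantry):
                for k, pos in enumerate(positions):
                    c, mall, _, _ = checker_a.evaluate(MachineState(ga, ca, pos))
                    assert cmap.colliding[i, j, k] == c
                    assert cmap.min_clearance_mm[i, j, k] == pytest.approx(mall)

    def test_checker_matches_brute_force_at_states(self, machine_a, checker_a):
        rng = np.random.default_rng(3)
        for _ in range(5):
            st = MachineState(
                float(rng.integers(0, 36) * 10),
                float(rng.choice([0.0, 40.0, 90.0, 300.0, 330.0])),
                (0.0, 0.0, float(rng.choice([-650.0, -330.0, -30.0]))),
            )
            _, mall, _, _ = checker_a.evaluate(st)
            scene = {m.label: m for m in assemble_scene(machine_a, st)}
            best = min(
                brute_force_min_distance(scene[a].mesh, scene[b].mesh, 10_000_000)
                for a in ("gantry_gun", "touch_guard", "gantry_arm")
                for b in ("couch_plate", "couch_base", "couch_rotator")
            )
            if best <= 150.0:  # sweeps refine exactly below the cap
                assert mall == pytest.approx(best, abs=1e-6)
            else:
                assert mall >= best - 1e-6


class TestSweepMap:
    def test_grid_shape_and_paper_cell_count(self, machine_a, machine_b):
        couch = paper_grid_couch_angles()
        gantry = paper_grid_gantry_angles()
        assert len(couch) == 19 and len(gantry) == 36
        positions = np.zeros((10, 3))
        total = len(couch) * len(gantry) * len(positions) * 2  # two machines
        assert total == 13_680

    def test_all_clear_when_couch_far_below(self, machine_a, checker_a):
        # at the lowest height and couch 0 the vertical-ish gantry arc is clear
        cmap = sweep_map(
            machine_a,
            couch_angles_deg=[0.0],
            gantry_angles_deg=[0.0, 10.0, 350.0],
            positions_mm=[(0.0, 0.0, -650.0)],
            checker=checker_a,
        )
        assert not cmap.colliding.any()
        assert (cmap.min_clearance_mm > machine_a.default_margin_mm).all()

    def test_machine_only_sweep_straddles_margin(self, machine_a, checker_a):
        cmap = sweep_map(
            machine_a,
            positions_mm=[(0.0, 0.0, -650.0), (0.0, 0.0, -30.0)],
            checker=checker_a,
        )
        assert cmap.colliding.any() and (~cmap.colliding).any()

    def test_margin_monotonicity_cellwise(self, machine_a, checker_a):
        cmap = sweep_map(
            machine_a,
            couch_angles_deg=[0.0, 40.0, 330.0],
            gantry_angles_deg=np.arange(0, 360, 30.0),
            positions_mm=[(0.0, 0.0, -330.0), (0.0, 0.0, -30.0)],
            checker=checker_a,
        )
        tighter = cmap.colliding_at_margin(20.0)
        default = cmap.colliding_at_margin(30.0)
        wider = cmap.colliding_at_margin(60.0)
        assert np.array_equal(default, cmap.colliding)
        assert not (tighter & ~default).any()  # subset at smaller margin
        assert not (default & ~wider).any()

    def test_empty_grid_rejected(self, machine_a, checker_a):
        with pytest.raises(RTClearError):
            sweep_map(machine_a, couch_angles_deg=[], checker=checker_a)

    def test_heatmap_rendering(self, tmp_path, machine_a, checker_a):
        cmap = sweep_map(
            machine_a,
            couch_angles_deg=[0.0, 330.0],
            gantry_angles_deg=np.arange(0.0, 360.0, 60.0),
            positions_mm=[(0.0, 0.0, -100.0)],
            checker=checker_a,
        )
        out = tmp_path / "map.png"
        cmap.to_heatmap(out)
        assert out.stat().st_size > 1000

    def test_csv_row_count(self, tmp_path, machine_a, checker_a):
        cmap = sweep_map(
            machine_a,
            couch_angles_deg=[0.0, 90.0],
            gantry_angles_deg=[0.0, 120.0, 240.0],
            positions_mm=[(0.0, 0.0, -100.0)],
            checker=checker_a,
        )
        path = tmp_path / "map.csv"
        cmap.to_csv(path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 + 6


class TestBoundaryAngles:
    def test_clear_rotation_returns_none(self, machine_a, checker_a):
        # couch 0 at a mid treatment height: the full rotation stays clear
        # (the head passes under the plate with room to spare)
        assert (
            boundary_gantry_angles(checker_a, 0.0, (0, 0, -100.0), "ccw", 10.0)
            is None
        )

    def test_boundary_matches_fine_scan(self, machine_a, checker_a):
        # 10-degree answer never lies beyond the 1-degree scan's answer
        pos = (0.0, 0.0, -30.0)
        for direction in ("ccw", "cw"):
            coarse = boundary_gantry_angles(checker_a, 330.0, pos, direction, 10.0)
            fine = boundary_gantry_angles(checker_a, 330.0, pos, direction, 1.0)
            assert coarse is not None and fine is not None
            assert fine <= coarse  # first collision can only appear earlier
            assert coarse - fine < 10.0

    def test_quantized_to_step(self, machine_a, checker_a):
        b = boundary_gantry_angles(checker_a, 330.0, (0, 0, -30.0), "ccw", 7.0)
        assert b is not None and b % 7.0 == pytest.approx(0.0)


class TestTrajectoryEvents:
    def test_single_colliding_arc_events(self, machine_a, checker_a):
        path = list(np.arange(0.0, 360.0, 10.0))
        events = trajectory_events(checker_a, 330.0, (0.0, 0.0, -30.0), path)
        by_pair = {}
        for e in events:
            by_pair.setdefault(e.pair, []).append(e)
        assert events, "expected at least one colliding arc"
        for pair, evs in by_pair.items():
            kinds = [e.kind for e in evs]
            assert kinds[0] == "enter"
            # between enter and exit only stays; ordering by index
            idx = [e.index for e in evs]
            assert idx == sorted(idx)
            for prev_e, e in zip(evs, evs[1:]):
                if e.kind == "enter":
                    assert prev_e.kind == "exit"
                if e.kind == "stay":
                    assert prev_e.kind in ("enter", "stay")

    def test_fully_clear_path_has_no_events(self, machine_a, checker_a):
        path = [0.0, 10.0, 20.0, 350.0]
        assert (
            trajectory_events(checker_a, 0.0, (0.0, 0.0, -650.0), path) == []
        )

    def test_colliding_from_first_sample(self, machine_a, checker_a):
        # start inside a colliding arc: enter at index 0, stays after
        pos = (0.0, 0.0, -30.0)
        start = boundary_gantry_angles(checker_a, 330.0, pos, "ccw", 10.0)
        path = [start, start + 2.0, start + 4.0]
        events = trajectory_events(checker_a, 330.0, pos, path)
        first = [e for e in events if e.index == 0]
        assert first and all(e.kind == "enter" for e in first)

    def test_short_path_rejected(self, machine_a, checker_a):
        with pytest.raises(RTClearError):
            trajectory_events(checker_a, 0.0, (0, 0, 0.0), [10.0])
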
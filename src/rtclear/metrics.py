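"""Validation harness: confusion statistics, the brute-force distance oracle,
and the digital-twin experiment.

The original validation compared software predictions against physical
on-site measurements.  That truth source is not available to a desk-scale
artifact, so the harness reinterprets it as a *digital twin*: the production
(coarse) predictor is scored against a fine in-silico oracle — full-slice
patient mesh, finer machine tessellation, spot-verified distances — on the
same configuration grid.  Published rates serve as floors for this twin
experiment, not as numbers to reproduce exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tridist import tri_tri_distance
from .collision import (
    CollisionChecker,
    CollisionMap,
    boundary_gantry_angles,
    paper_grid_couch_angles,
    paper_grid_gantry_angles,
    sweep_map,
)
from .errors import RTClearError
from .kinematics import MachineState, PlacedPatient, place_patient
from .mesh import TriMesh

__all__ = [
    "ConfusionSummary",
    "confusion_summary",
    "brute_force_min_distance",
    "TwinConfig",
    "ValidationCase",
    "TwinResult",
    "digital_twin_validation",
    "COARSE_CONFIG",
    "FINE_CONFIG",
]


# --------------------------------------------------------------------------
# confusion statistics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionSummary:
    """Confusion counts and rates; positive = collision.

    Rates with a zero denominator are ``None`` (never silently 0 or 1).
    """

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float | None:
        return (self.tp + self.tn) / self.total if self.total else None

    @property
    def tpr(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def tnr(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "tpr": self.tpr,
            "tnr": self.tnr,
        }

    def __add__(self, other: "ConfusionSummary") -> "ConfusionSummary":
        return ConfusionSummary(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


def confusion_summary(pred: CollisionMap, truth: CollisionMap) -> ConfusionSummary:
    """Score a predicted collision map against a ground-truth map.

    A false negative is a cell predicted clear where the truth collides —
    the dangerous direction.
    """
    same = (
        np.array_equal(pred.couch_angles_deg, truth.couch_angles_deg)
        and np.array_equal(pred.gantry_angles_deg, truth.gantry_angles_deg)
        and np.allclose(pred.positions_mm, truth.positions_mm)
    )
    if not same:
        raise RTClearError("prediction and truth maps use different grids")
    p = pred.colliding
    t = truth.colliding
    return ConfusionSummary(
        tp=int(np.count_nonzero(p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


# --------------------------------------------------------------------------
# brute-force oracle
# --------------------------------------------------------------------------

def brute_force_min_distance(
    a: TriMesh, b: TriMesh, triangle_pair_budget: int = 2_000_000
) -> float:
    """Exhaustive exact minimum over all triangle pairs.

    The independent oracle for the accelerated engine: no spatial pruning at
    all, every pair evaluated.  Raises when the pair count exceeds the budget.
    """
    na, nb = a.n_triangles, b.n_triangles
    if na == 0 or nb == 0:
        raise RTClearError("brute force requires two non-empty meshes")
    if na * nb > triangle_pair_budget:
        raise RTClearError(
            f"{na} x {nb} triangle pairs exceed budget {triangle_pair_budget}"
        )
    ca = a.triangle_corners()
    cb = b.triangle_corners()
    best = np.inf
    chunk = max(1, 200_000 // nb)
    for s in range(0, na, chunk):
        block = ca[s : s + chunk]  # (c, 3, 3)
        d = tri_tri_distance(block[:, None, :, :], cb[None, :, :, :])
        best = min(best, float(d.min()))
        if best == 0.0:
            return 0.0
    return best


# --------------------------------------------------------------------------
# digital twin
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TwinConfig:
    """One predictor configuration for the twin experiment.

    The production (coarse) default subsamples the patient slices and uses
    the machines' stored tessellation; the fine oracle uses every CT slice,
    denser rings, finer machine tessellation, and spot-verifies its distance
    queries against the brute-force oracle.
    """

    machine_segments: int | None = None  # None = as stored in the spec file
    patient_slice_step: int = 3
    patient_ring_points: int = 64
    boundary_step_deg: float = 1.0
    brute_verify: bool = False
    verify_samples: int = 5
    verify_budget: int = 2_000_000


COARSE_CONFIG = TwinConfig()
FINE_CONFIG = TwinConfig(
    machine_segments=96,
    patient_slice_step=1,
    patient_ring_points=128,
    brute_verify=True,
)


@dataclass
class ValidationCase:
    """Inputs of one twin experiment: an optional patient and the grids."""

    stack: object | None = None  # ContourStack; None = empty couch
    couch_angles_deg: np.ndarray = field(default_factory=paper_grid_couch_angles)
    gantry_angles_deg: np.ndarray = field(default_factory=paper_grid_gantry_angles)
    #: couch positions as plate-top heights (mm relative to the isocenter
    #: plane); converted per machine/patient to vertical shifts
    plate_top_heights_mm: tuple = (-650.0, -100.0, -200.0)
    #: plate-top height used for the boundary-angle comparison
    boundary_height_mm: float = -100.0
    #: whether to run the boundary-angle comparison at all
    compare_boundaries: bool = True
    seed: int = 0


@dataclass
class TwinResult:
    summary: ConfusionSummary
    max_boundary_error_deg: float
    boundary_angles: list  # (couch_deg, direction, coarse, fine)
    coarse_map: CollisionMap
    fine_map: CollisionMap


def _patient_for_config(case: ValidationCase, cfg: TwinConfig):
    if case.stack is None:
        return None
    from .loft import loft_collider

    stack = case.stack
    meshes = [
        loft_collider(
            stack,
            label,
            n_points=cfg.patient_ring_points,
            slice_step=cfg.patient_slice_step,
        )
        for label in stack.labels()
    ]
    merged = TriMesh.concatenate(meshes)
    return place_patient(merged, stack.isocenter_mm, stack.plate_height_mm)


def _positions_for(case: ValidationCase, couch_top_mm: float) -> np.ndarray:
    return np.array(
        [(0.0, 0.0, h - couch_top_mm) for h in case.plate_top_heights_mm]
    )


def _spot_verify(checker: CollisionChecker, case, cfg: TwinConfig) -> None:
    """Cross-check a seeded sample of states against the brute-force oracle."""
    rng = np.random.default_rng(case.seed + 12345)
    couch_top = checker.couch_top_mm
    positions = _positions_for(case, couch_top)
    for _ in range(cfg.verify_samples):
        ca = float(rng.choice(case.couch_angles_deg))
        ga = float(rng.choice(case.gantry_angles_deg))
        pos = positions[rng.integers(len(positions))]
        state = MachineState(ga, ca, tuple(pos))
        res = checker.result(state)
        closest = min(res.per_pair, key=lambda p: p.clearance_mm)
        ma = checker._meshes[closest.label_a]
        mb = checker._meshes[closest.label_b]
        if ma.n_triangles * mb.n_triangles > cfg.verify_budget:
            continue
        pair = next(
            p
            for p in checker.pairs
            if (p.a_label, p.b_label) == (closest.label_a, closest.label_b)
        )
        ta = checker._group_transform(pair.a_group, state)
        tb = checker._group_transform(pair.b_group, state)
        d_bf = brute_force_min_distance(
            ma.transformed(ta), mb.transformed(tb), cfg.verify_budget
        )
        if abs(d_bf - closest.clearance_mm) > 1e-6:
            raise RTClearError(
                f"accelerated distance {closest.clearance_mm} != brute force "
                f"{d_bf} at state {state}"
            )


def digital_twin_validation(
    spec,
    case: ValidationCase,
    coarse_config: TwinConfig = COARSE_CONFIG,
    fine_config: TwinConfig = FINE_CONFIG,
) -> TwinResult:
    """Score the production predictor against the fine in-silico oracle.

    Truth = the fine configuration's sweep; prediction = the coarse sweep on
    the same grid points.  Also reports the maximum absolute difference in
    the collision-boundary gantry angle over all couch angles and both
    rotation directions (``None`` boundaries — full rotation clear — count as
    360 deg, so a defined/undefined mismatch is visible, not hidden).
    """
    checkers = {}
    maps = {}
    for name, cfg in (("coarse", coarse_config), ("fine", fine_config)):
        patient = _patient_for_config(case, cfg)
        checker = CollisionChecker(
            spec, patient, machine_segments=cfg.machine_segments
        )
        if cfg.brute_verify:
            _spot_verify(checker, case, cfg)
        positions = _positions_for(case, checker.couch_top_mm)
        maps[name] = sweep_map(
            spec,
            couch_angles_deg=case.couch_angles_deg,
            gantry_angles_deg=case.gantry_angles_deg,
            positions_mm=positions,
            checker=checker,
        )
        checkers[name] = checker

    summary = confusion_summary(maps["coarse"], maps["fine"])

    boundary_rows = []
    max_err = 0.0
    couch_angles = (
        np.asarray(case.couch_angles_deg, dtype=float)
        if case.compare_boundaries
        else np.array([])
    )
    for ca in couch_angles:
        for direction in ("ccw", "cw"):
            angles = {}
            for name, cfg in (("coarse", coarse_config), ("fine", fine_config)):
                pos = (
                    0.0,
                    0.0,
                    case.boundary_height_mm - checkers[name].couch_top_mm,
                )
                angles[name] = boundary_gantry_angles(
                    checkers[name],
                    ca,
                    pos,
                    direction=direction,
                    step_deg=cfg.boundary_step_deg,
                )
            a = 360.0 if angles["coarse"] is None else angles["coarse"]
            b = 360.0 if angles["fine"] is None else angles["fine"]
            max_err = max(max_err, abs(a - b))
            boundary_rows.append((float(ca), direction, angles["coarse"], angles["fine"]))

    return TwinResult(
        summary=summary,
        max_boundary_error_deg=max_err,
        boundary_angles=boundary_rows,
        coarse_map=maps["coarse"],
        fine_map=maps["fine"],
    )
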
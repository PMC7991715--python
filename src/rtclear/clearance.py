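"""Minimal-shift search: clear a colliding setup by moving the isocenter.

Clinically the fix for a predicted collision (the prone-breast scenario) is a
small isocenter shift, applied on the machine as the equal-and-opposite couch
translation.  The search is grid-based — shifts are applied in discrete
steps, as they are on a real couch — over one or more directions, and returns
the smallest-magnitude shift for which *every* planned beam is collision-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .collision import CollisionChecker
from .errors import RTClearError
from .kinematics import MachineState

__all__ = ["ShiftSolution", "ShiftSearchReport", "find_min_shift", "DIRECTIONS"]

#: named unit directions in the couch frame (lateral, longitudinal, vertical)
DIRECTIONS = {
    "down": (0.0, 0.0, -1.0),
    "up": (0.0, 0.0, 1.0),
    "left": (-1.0, 0.0, 0.0),
    "right": (1.0, 0.0, 0.0),
    "in": (0.0, 1.0, 0.0),
    "out": (0.0, -1.0, 0.0),
}


@dataclass
class ShiftSolution:
    """A couch shift that renders all beams collision-free."""

    shift_mm: tuple[float, float, float]
    clearance_after_mm: float  # min clearance over all beams after the shift
    per_beam_clearance_mm: list[float]
    evaluated_count: int

    @property
    def magnitude_mm(self) -> float:
        return float(np.linalg.norm(self.shift_mm))

    @property
    def isocenter_shift_mm(self) -> tuple[float, float, float]:
        """The same correction expressed as an isocenter move within the
        patient (equal and opposite to the couch shift)."""
        return tuple(-v if v != 0 else 0.0 for v in self.shift_mm)


@dataclass
class ShiftSearchReport:
    solution: ShiftSolution | None
    #: largest-clearance candidate tried (diagnostics when no solution found)
    best_shift_mm: tuple[float, float, float]
    best_clearance_mm: float
    evaluated_count: int


def find_min_shift(
    spec,
    patient,
    beams: list[MachineState],
    directions=((0.0, 0.0, -1.0),),
    step_mm: float = 5.0,
    max_mm: float = 100.0,
    couch_top_mm: float | None = None,
    machine_segments: int | None = None,
    checker: CollisionChecker | None = None,
) -> ShiftSearchReport:
    """Search shifts ``k * step_mm * direction`` for the minimal clearing one.

    Candidates are tried in order of increasing magnitude; among equal
    magnitudes the direction listed first wins.  If nothing within ``max_mm``
    clears every beam, ``solution`` is None and the best (largest minimum
    clearance) candidate is reported for diagnostics.
    """
    if step_mm <= 0:
        raise RTClearError("step_mm must be > 0")
    if max_mm < step_mm:
        raise RTClearError("max_mm must be >= step_mm")
    if not beams:
        raise RTClearError("need at least one planned beam")
    dirs = [np.asarray(d, dtype=float) for d in directions]
    for d in dirs:
        n = np.linalg.norm(d)
        if n == 0:
            raise RTClearError("zero direction vector")
        d /= n

    if checker is None:
        checker = CollisionChecker(
            spec, patient, couch_top_mm, machine_segments=machine_segments
        )

    def try_shift(shift: np.ndarray):
        clearances = []
        ok = True
        for beam in beams:
            state = MachineState(
                beam.gantry_angle_deg,
                beam.couch_angle_deg,
                tuple(np.asarray(beam.couch_shift_mm) + shift),
            )
            colliding, min_all, _, _ = checker.evaluate(state)
            clearances.append(min_all)
            ok = ok and not colliding
        return ok, clearances

    evaluated = 0
    best_shift, best_clear = (0.0, 0.0, 0.0), -np.inf
    n_steps = int(np.floor(max_mm / step_mm + 1e-9))
    for k in range(0, n_steps + 1):
        mags = [np.zeros(3)] if k == 0 else [k * step_mm * d for d in dirs]
        for shift in mags:
            ok, clearances = try_shift(shift)
            evaluated += 1
            worst = float(min(clearances))
            shift_t = tuple(float(v) for v in shift)
            if worst > best_clear:
                best_clear, best_shift = worst, shift_t
            if ok:
                return ShiftSearchReport(
                    solution=ShiftSolution(
                        shift_mm=shift_t,
                        clearance_after_mm=worst,
                        per_beam_clearance_mm=[float(c) for c in clearances],
                        evaluated_count=evaluated,
                    ),
                    best_shift_mm=shift_t,
                    best_clearance_mm=worst,
                    evaluated_count=evaluated,
                )
    return ShiftSearchReport(
        solution=None,
        best_shift_mm=best_shift,
        best_clearance_mm=best_clear,
        evaluated_count=evaluated,
    )
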
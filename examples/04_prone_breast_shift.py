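"""Resolve a predicted collision by searching the minimal couch shift.

Recreates the prone-breast scenario: a board raises the torso, posterior-
oblique beams then violate the safety zone in the high setup position, and
the search reports the smallest downward shift that clears every beam.
"""

from rtclear import (
    MachineState,
    TriMesh,
    contour_pipeline,
    find_min_shift,
    fixture_machine,
    loft_collider,
    make_prone_breast_case,
    place_patient,
)
from rtclear.clearance import DIRECTIONS

spec = fixture_machine("machine_a")
vol = make_prone_breast_case(seed=7)
stack = contour_pipeline(vol)
merged = TriMesh.concatenate(
    [loft_collider(stack, label) for label in stack.labels()]
)
patient = place_patient(merged, stack.isocenter_mm, stack.plate_height_mm)

# the collision was encountered in the HIGH setup position: plate top 30 mm
# above the isocenter plane, which puts the board-raised torso inside the
# head's safety zone for near-vertical beams
beams = [MachineState(g, 0.0) for g in (350.0, 0.0, 10.0)]
report = find_min_shift(
    spec,
    patient,
    beams,
    directions=[DIRECTIONS["down"]],
    step_mm=5.0,
    max_mm=100.0,
    couch_top_mm=30.0,
)

print(f"colliders on the couch: {', '.join(stack.labels())}")
print(f"states evaluated:       {report.evaluated_count}")
if report.solution:
    s = report.solution
    print(f"minimal couch shift:    {s.shift_mm} mm "
          f"(isocenter moves {s.isocenter_shift_mm} mm within the patient)")
    print(f"clearance after shift:  {s.clearance_after_mm:.1f} mm "
          f"(per beam: {[f'{c:.1f}' for c in s.per_beam_clearance_mm]})")
else:
    print(f"no clearing shift found; best candidate {report.best_shift_mm} mm "
          f"reaches {report.best_clearance_mm:.1f} mm clearance")
# A zero shift means the setup is already clear; otherwise the shift is the
# smallest grid multiple that takes every planned beam out of the 30-mm zone.
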
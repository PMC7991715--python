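"""Map the noncolliding configuration space of a fixture machine.

Sweeps the clinical grid (couch 0-90 and 270-350, gantry 0-350, both in
10-degree steps) at three plate heights with the phantom on the couch, and
prints the collision map of the middle height as an ASCII matrix.
"""

from rtclear import (
    PhantomParams,
    contour_pipeline,
    fixture_machine,
    loft_collider,
    make_phantom_ct,
    place_patient,
    sweep_map,
)

spec = fixture_machine("machine_a")
vol = make_phantom_ct(PhantomParams(noise_seed=7))
stack = contour_pipeline(vol)
patient = place_patient(
    loft_collider(stack, "body"), stack.isocenter_mm, stack.plate_height_mm
)

heights = (-650.0, -100.0, -200.0)  # plate-top heights relative to isocenter
positions = [(0.0, 0.0, h - patient.couch_top_mm) for h in heights]
cmap = sweep_map(spec, patient, positions_mm=positions)

n_col = int(cmap.colliding.sum())
print(f"{spec.name}: {cmap.n_cells} cells, {n_col} colliding "
      f"({100 * n_col / cmap.n_cells:.0f}%), margin {cmap.default_margin_mm:.0f} mm")
k = 1  # the -100 mm height
print(f"\ncollision matrix at plate height {heights[k]:.0f} mm "
      "('#' = collision within the safety zone):")
header = "".join(f"{int(g):4d}" for g in cmap.gantry_angles_deg[::3])
print("  couch\\gantry" + header)
for i, ca in enumerate(cmap.couch_angles_deg):
    row = "".join(
        "   #" if cmap.colliding[i, j, k] else "   ."
        for j in range(0, len(cmap.gantry_angles_deg), 3)
    )
    print(f"    {int(ca):5d}    " + row)
# Clear cells are configurations a planner may use; '#' cells would bring
# some machine part (or the phantom) within 30 mm of the gantry.
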
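# Coordinate conventions

All modules share a single normative set of frames.  Distances are
millimetres, angles degrees.

## Room frame

Right-handed, IEC-61217-like:

- origin at the treatment **isocenter**;
- **+Z** vertical, up;
- **+Y** horizontal, from the isocenter toward the gantry stand;
- **+X** completes the frame (toward the patient's left for a
  head-first-supine patient whose head points at the gantry).

## Gantry

The gantry assembly rotates about **+Y** through the isocenter.

- 0 deg: accelerator head directly **above** the isocenter (beam pointing
  down).
- Increasing angle moves the head toward **+X**: the head reference point
  `(0, 0, +d)` maps to `(+d, 0, 0)` at 90 deg.
- Angles are normalized to `[0, 360)`; 360 deg equals 0 deg exactly.

## Couch

The couch rotates about **+Z** through the isocenter, counterclockwise
positive viewed from above, so the clinical range "0-90 counterclockwise and
270-350 clockwise" reads directly as angles 0-90 and 270-350.

Couch translations `(lateral, longitudinal, vertical)` are applied **in the
couch frame, before the rotation**:

```
p_room = R_z(couch_angle) @ (p_couch + shift + [0, 0, couch_top])
```

- couch 0 deg: the couch long axis points toward the gantry (+Y), the plate
  tip extending past the isocenter toward the stand.
- The couch local frame puts the **plate-top surface at Z = 0**;
  `couch_top` is the plate-top height (room frame) at zero couch state.
  Machine files declare a default (`plate_top_zero_mm`); an isocentric
  patient setup uses `couch_top = -(iso_v - plate_height)` so the patient's
  isocenter lands exactly on the room isocenter at zero state.
- The floor turntable (`couch_rotating` group) rotates with the couch angle
  but does not translate; plate, pedestal and patient
  (`couch_translating` / `patient`) both translate and rotate.

## CT frame

A CT volume is indexed `[slice, row, col]`:

- `x` = columns, lateral, mm;
- `v` = rows, **vertical up**, mm (DICOM files store rows top-down; the
  loader flips them);
- `z` = slice position, longitudinal, mm, strictly increasing.

Vectors such as the isocenter are `(x, v, z)`.  Patient placement maps CT to
couch coordinates by the proper rotation `X = -x, Y = z, Z = v` (axis
relabel composed with a 180-deg turn about the slice axis), followed by the
plate alignment `Z -= plate_height`; rigid by construction.
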
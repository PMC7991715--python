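# Generic C-arm accelerator fixture "A".
# Dimensions are plausible, not vendor-exact; frame conventions in
# docs/COORDINATES.md (origin at isocenter, +Z up, +Y toward gantry stand).
schema_version: 1
name: machine_a
isocenter_clearance_mm: 400.0    # gantry-head face to isocenter
default_margin_mm: 30.0          # 3-cm safety zone
plate_top_zero_mm: 0.0           # plate-top height at zero couch state
couch_height_range_mm: [-650.0, 50.0]
couch_shift_ranges_mm:
  lateral: [-250.0, 250.0]
  longitudinal: [-1000.0, 1000.0]
  vertical: [-700.0, 200.0]
couch_angle_range_deg: [0.0, 360.0]
gantry_angle_range_deg: [0.0, 360.0]
collision_pairs:
  - [gantry_rotating, couch_translating]
  - [gantry_rotating, couch_rotating]
  - [gantry_rotating, patient]
margin_overrides:
  touch_guard: 0.0               # the guard IS the safety buffer
components:
  - label: gantry_gun
    group: gantry_rotating
    primitives:
      - shape: cylinder          # head: face at z=400, extends to z=850
        radius_mm: 250.0
        height_mm: 450.0
        segments: 48
        pose: {translation_mm: [0.0, 0.0, 625.0]}
  - label: touch_guard
    group: gantry_rotating
    primitives:
      - shape: cylinder          # collar around the head face, z 400..460
        radius_mm: 270.0
        height_mm: 60.0
        segments: 48
        pose: {translation_mm: [0.0, 0.0, 430.0]}
  - label: gantry_arm
    group: gantry_rotating
    primitives:
      - shape: box               # cantilever from head toward the stand
        size_mm: [500.0, 600.0, 500.0]
        pose: {translation_mm: [0.0, 300.0, 1100.0]}
  - label: gantry_wall
    group: static
    primitives:
      - shape: box               # vertical stand behind the isocenter
        size_mm: [2600.0, 600.0, 2800.0]
        pose: {translation_mm: [0.0, 1200.0, 100.0]}
  - label: couch_plate
    group: couch_translating
    primitives:
      - shape: box               # top surface at z=0, tip 700 mm past iso
        size_mm: [500.0, 2200.0, 70.0]
        pose: {translation_mm: [0.0, -400.0, -35.0]}
  - label: couch_base
    group: couch_translating
    primitives:
      - shape: box               # support column under the rear plate
        size_mm: [700.0, 1100.0, 1200.0]
        pose: {translation_mm: [0.0, -900.0, -700.0]}
  - label: couch_rotator
    group: couch_rotating
    primitives:
      - shape: extruded_polygon  # floor turntable (regular octagon)
        vertices_mm:
          - [500.0, 0.0]
          - [353.5534, 353.5534]
          - [0.0, 500.0]
          - [-353.5534, 353.5534]
          - [-500.0, 0.0]
          - [-353.5534, -353.5534]
          - [0.0, -500.0]
          - [353.5534, -353.5534]
        length_mm: 150.0
        pose: {translation_mm: [0.0, 0.0, -2025.0]}
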
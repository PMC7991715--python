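# Generic C-arm accelerator fixture "B": larger head diameter, smaller
# face-to-isocenter clearance and a wider couch than fixture "A".
schema_version: 1
name: machine_b
isocenter_clearance_mm: 360.0
default_margin_mm: 30.0
plate_top_zero_mm: 0.0
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
  touch_guard: 0.0
components:
  - label: gantry_gun
    group: gantry_rotating
    primitives:
      - shape: cylinder          # face at z=360, extends to z=810
        radius_mm: 300.0
        height_mm: 450.0
        segments: 48
        pose: {translation_mm: [0.0, 0.0, 585.0]}
  - label: touch_guard
    group: gantry_rotating
    primitives:
      - shape: cylinder          # collar z 360..420
        radius_mm: 320.0
        height_mm: 60.0
        segments: 48
        pose: {translation_mm: [0.0, 0.0, 390.0]}
  - label: gantry_arm
    group: gantry_rotating
    primitives:
      - shape: box
        size_mm: [560.0, 600.0, 500.0]
        pose: {translation_mm: [0.0, 300.0, 1060.0]}
  - label: gantry_wall
    group: static
    primitives:
      - shape: box
        size_mm: [2600.0, 600.0, 2800.0]
        pose: {translation_mm: [0.0, 1200.0, 100.0]}
  - label: couch_plate
    group: couch_translating
    primitives:
      - shape: box               # wider plate than fixture A
        size_mm: [530.0, 2200.0, 70.0]
        pose: {translation_mm: [0.0, -400.0, -35.0]}
  - label: couch_base
    group: couch_translating
    primitives:
      - shape: box
        size_mm: [700.0, 1100.0, 1200.0]
        pose: {translation_mm: [0.0, -900.0, -700.0]}
  - label: couch_rotator
    group: couch_rotating
    primitives:
      - shape: extruded_polygon
        vertices_mm:
          - [520.0, 0.0]
          - [367.6955, 367.6955]
          - [0.0, 520.0]
          - [-367.6955, 367.6955]
          - [-520.0, 0.0]
          - [-367.6955, -367.6955]
          - [0.0, -520.0]
          - [367.6955, -367.6955]
        length_mm: 150.0
        pose: {translation_mm: [0.0, 0.0, -2025.0]}
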
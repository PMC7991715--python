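# Machine description file (schema version 1)

A machine is one YAML (or JSON) mapping.  Two generic fixtures ship with the
package (`rtclear/data/machine_a.yaml`, `machine_b.yaml`); vendor machines
are described by editing dimensions measured from manuals or on site.

## Top level

| key | type | meaning |
|---|---|---|
| `schema_version` | int | currently `1` |
| `name` | str | machine identifier used in reports |
| `isocenter_clearance_mm` | float > 0 | gantry-head face to isocenter |
| `default_margin_mm` | float >= 0 | safety-zone clearance (default 30) |
| `plate_top_zero_mm` | float | plate-top height at zero couch state |
| `couch_height_range_mm` | [lo, hi] | reachable plate-top heights |
| `couch_shift_ranges_mm` | {lateral, longitudinal, vertical: [lo, hi]} | travel limits |
| `couch_angle_range_deg` | [lo, hi] | couch rotation range |
| `gantry_angle_range_deg` | [lo, hi] | must cover 360 degrees |
| `collision_pairs` | list of [group, group] | monitored kinematic-group pairs |
| `margin_overrides` | {component label: margin} | e.g. `touch_guard: 0` |
| `components` | list | see below |

Kinematic groups: `gantry_rotating`, `couch_rotating` (floor turntable:
rotates, never translates), `couch_translating`, `static`; collision pairs
may also name `patient`.

Required component labels: `gantry_gun`, `gantry_arm`, `gantry_wall`,
`touch_guard`, `couch_plate`, `couch_rotator`, `couch_base`.  The touch
guard is the machine's own contact buffer, so its pairs are conventionally
checked at margin 0 via `margin_overrides`.

## Components and primitives

```yaml
components:
  - label: gantry_gun
    group: gantry_rotating
    primitives:
      - shape: cylinder          # box | cylinder | truncated_cone | extruded_polygon
        radius_mm: 250.0
        height_mm: 450.0
        segments: 48             # tessellation for curved shapes (>= 8)
        pose:
          translation_mm: [0, 0, 625]
          rotation_deg: [0, 0, 0]   # intrinsic x-y-z Euler, applied R_z R_y R_x
```

Per-shape dimensions:

- `box`: `size_mm: [x, y, z]`
- `cylinder`: `radius_mm`, `height_mm` (axis along local Z, centered)
- `truncated_cone`: `r_bottom_mm`, `r_top_mm` (0 for an apex), `height_mm`
- `extruded_polygon`: `vertices_mm` (simple 2D polygon, >= 3 vertices),
  `length_mm` (extrusion along local Z, centered)

All dimensions must be positive; validation errors name the offending field
path and component.  Every primitive is a convex solid, which the collision
engine exploits; meshes built from them are watertight and outward-oriented
at any tessellation.
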
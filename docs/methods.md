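# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `rtclear`, in the order the pipeline runs.

## Machine model

An accelerator is described parametrically (docs/machine_schema.md) as
labelled components — gantry gun, gantry arm, gantry wall, touch guard,
couch plate, couch rotator, couch base — each a list of convex solid
primitives (box, cylinder, truncated cone, extruded polygon) with a rigid
pose, grouped kinematically: `gantry_rotating` parts rotate about the
horizontal axis through the isocenter, `couch_translating` parts ride the
couch shifts and rotation, `couch_rotating` parts (the floor turntable)
rotate only, `static` parts never move.  Frames and sign conventions are in
docs/COORDINATES.md and are the single normative choice shared by all
modules.

The two shipped fixtures are *generic*: vendor-exact dimensions are
proprietary, so the fixtures use plausible C-arm dimensions, differing in
head diameter (500 vs 600 mm), face-to-isocenter clearance (400 vs 360 mm)
and couch width (500 vs 530 mm).  The method, not the vendor data, is the
point; a site models its own machine by editing one YAML file against
manual/on-site measurements.

Gantry-vs-couch-base and gantry-vs-turntable contacts are monitored along
with gantry-vs-plate and gantry-vs-patient; whether base contacts "count"
is site policy, so the monitored set is the `collision_pairs` list in the
machine file rather than a hard-coded rule.

## CT contouring

The external-surface pipeline is deliberately the simple, operator-
controlled chain used clinically for collision purposes:

1. linear intensity window to 8-bit grayscale (defaults −500..+300 HU,
   clamped, rounded half-up);
2. threshold (default at −300 HU — between lung/bag densities and soft
   tissue);
3. grayscale morphological closing with an elliptical structuring element
   (default radius 2 px) — the smoothing step;
4. removal of everything at or below the couch-plate top (the CT plate is
   not a collider — the treatment couch replaces it — and a body resting on
   the plate would otherwise merge with it);
5. per-slice connected components, minimum polygon area 400 mm²,
   outer-boundary tracing, cross-slice tracking by maximal pixel overlap
   (ties by centroid distance).  The largest-volume track is the `body`;
   the rest become `accessory_k` in descending volume.

Window, threshold, closing radius and minimum area are exposed because they
are operator choices, not constants of the method.  The isocenter and the
plate height are manual inputs by design; no auto-centering is attempted.

Contours are traced with marching squares on the binary mask at level 0.5,
i.e. polygon vertices sit at half-pixel crossings.  This is still "pixel
resolution, no smoothing" — the closing is the only smoothing — but it
halves the area bias of tracing through pixel centers, which matters for
the analytic volume checks below.  Contours are stored counter-clockwise,
simple, first point not repeated.

A case round-trips through a single RT-Structure-Set-style DICOM file (one
closed-planar ROI per collider, a point ROI for the isocenter, a marker ROI
for the plate height; docs/rtstruct_dialect.md) with 1e-3 mm point fidelity.

## Contour lofting

Each collider's slice contours become a watertight triangle mesh by:
arc-length resampling to a common ring size (default 128 points);
start-index correspondence between adjacent rings by minimizing the sum of
squared distances after centroid alignment (tolerant of couch drift between
slices; ties break to the smallest offset); optional linearly interpolated
intermediate rings (enough that the axial step is at most 5 mm, the scale
of CT slice spacing); triangle strips between consecutive rings; ear-clipped
end caps (handles non-convex outlines; identical rings loft to exact
prisms).  A collider whose slice sequence has gaps — branching anatomy,
accessories that end mid-stack — is lofted as separately capped watertight
pieces rather than attempting surface merging: conservative, and correct
for distance queries.

## Collision engine

Margins are implemented as distance thresholds (clearance ≤ margin ⇒
collision), *not* by inflating meshes: exact, and free of Minkowski-sum
artifacts.  The default margin is 30 mm (the 3-cm safety zone); the touch
guard is checked at margin 0 because it is itself the physical buffer.
Boundary equality counts as a collision — the conservative direction for
patient safety.

Distances are exact surface-to-surface minima, computed by two routes:

- **Machine–machine pairs**: every component is a union of convex
  primitives, so the pair distance is the minimum of GJK distances between
  primitive vertex polytopes.  GJK on polytopes terminates at the exact
  distance (verified against the exhaustive triangle oracle to 5e-13 mm
  across random states); overlap returns 0.  A degenerate-simplex guard
  prevents flat tetrahedra from being mistaken for enclosures.
- **Patient pairs** (the only non-convex collider): a best-first triangle
  engine.  Per-vertex lower bounds (distance to the other mesh's box) order
  a chunked k-d-tree vertex query; the bound is tightened by exact
  evaluation around the nearest features (which also detects deep
  interpenetration immediately via the edge-through-face test); candidate
  triangle pairs are then enumerated within the certified band, filtered by
  sphere and axis-aligned-box bounds, and evaluated best-first with the
  exact 15-feature triangle-pair kernel until no remaining pair can matter.
  Internally triangles are split to ≤25–60 mm edges (geometry unchanged) so
  the bounds are tight.

Sweep evaluations refine clearances exactly up to 150 mm; beyond that —
five times any margin of interest — the vertex-sampled upper bound is
reported instead of spending time on exhaustive certification.  Collision
flags, near-margin clearances, and every re-thresholding up to 150 mm are
exact; the public `min_distance`/`collides` functions always refine fully.

Sweeps cache all acceleration structures per machine/patient and transform
only the moving side of each pair per state, so cells are independent,
deterministic, and order-independent.  Trigger-style event streams
(enter/stay/exit per pair along a sampled gantry path) are discrete — no
continuous-time root finding; the step is the caller's choice.

Default grids mirror clinical validation practice: couch 0–90 and 270–350
in 10-degree steps (19 angles), gantry 0–350 in 10-degree steps (36), and
couch heights as plate-top positions relative to the isocenter plane.

## Clearance search

A colliding plan is rescued by the smallest couch shift (equal-and-opposite
isocenter move) for which every planned beam is collision-free.  The search
is grid-based — default 5-mm steps along the couch-down direction, up to
100 mm — because shifts are applied on the machine in discrete millimetres
and a single directional shift is the clinically reported correction.
Candidates are tried in order of increasing magnitude (ties: direction
listed first); if nothing clears within the budget, the largest-clearance
candidate is reported for diagnostics.

## Synthetic phantom

The generator emulates a torso-like QA phantom with analytic ground truth:
an elliptical-cylinder body (semi-axes 170 × 110 mm, length 290 mm, HU
30 ± 15 with seeded Gaussian noise) resting on a flat couch plate (HU 200,
top at −110 mm), air at −1000 HU, optionally a 12-mm immobilization-shell
ring at −650 HU hugging the body, and a prone-board variant (120-mm board,
HU 150) that raises the torso and reproduces reduced posterior-oblique
clearance.  Grids default to 256×256 pixels at 2 mm and 60 slices at 5 mm.
Voxels are integer HU, so a written DICOM series reloads bit-identically.

Choices worth noting:

- The shell's HU (−650) is below the default body threshold; shell cases
  are contoured with a lower cut (−700 HU, window −800..300), which merges
  the touching body+shell into one collider — exactly what matters for
  collision geometry.
- The board keeps a 12-mm air gap to the body (a cushion, in practice) so
  component tracking keeps board and body distinct; the gap must exceed
  the closing diameter or the smoothing would bridge it.
- The phantom is geometric, not anthropomorphic, so every pipeline stage
  can be audited against closed forms (ellipse area, π·a·b·L volume,
  tangency angles).  Passing tests therefore certify the *machinery* —
  segmentation fidelity at sharp boundaries, mesh exactness, distance
  correctness — not performance on real anatomy: real CTs add partial
  volume effects, HU texture, limbs and branching topology the phantom
  does not model.

## Digital-twin validation

The original validation target for software of this kind is physical:
prediction vs on-site measurement.  A desk-scale artifact has no machine,
so the harness *reinterprets* the experiment as a digital twin: the
production configuration (stored machine tessellation, every 3rd CT slice,
64-point rings) is scored against a fine in-silico oracle (96-segment
tessellation, all slices, 128-point rings, distances spot-verified against
the exhaustive triangle-pair oracle on a seeded sample of states within a
2-million-pair budget) on identical grids.  Published accuracy figures for
this class of software (high 90s) are treated as floors for the twin
experiment and the 5-degree boundary-angle agreement as a cap — they are
not numbers the twin could or should reproduce exactly, since the physical
truth source (and its vendor geometry) is unavailable.

Disagreements concentrate where they should: cells whose fine-model
clearance lies within the coarse model's facet error (~1 mm) of the margin.
Confusion rates with zero denominators are reported as absent, never 0 or 1.
Boundary angles are compared at 1-degree steps in both rotation directions
at the −100 mm plate height (a typical treatment height); a boundary that
exists in one configuration but not the other enters the comparison as 360
degrees, so defined/undefined mismatches are visible rather than hidden.

## Numerical details

- Rigid transforms are validated orthonormal with det +1; compositions stay
  within 1e-9 over the sweep ranges.
- Angle arithmetic is degrees end-to-end (radians only inside kernels);
  angles normalize to [0, 360).
- Half-up rounding in the intensity transform is computed as
  `floor(x*255/(hi-lo) + 0.5)` with the multiply first, so exact midpoints
  land deterministically.
- Ear clipping falls back to clipping the least-reflex corner on
  near-degenerate outlines so it always terminates; degenerate (zero-area)
  polygons are rejected.
- Empty masks are legal segmentation outputs; an empty *stack* (no collider
  anywhere) is an error.

## Problem sizes

Default experiment sizes were chosen so a full validation runs in minutes
on one CPU: 60-slice phantoms, ≤5k-triangle machine meshes, 13,680-cell
empty-couch grids (19 couch × 36 gantry × 10 heights × 2 machines), 2052
cells per phantom sweep, and 1-degree boundary scans.  All are parameters,
not constants.

## Known limitations

- Devices not visible in the simulation CT (monitors, breath-control
  hardware, imaging arms) are not modelled and therefore not predicted.
- No multileaf-collimator or collimator-rotation geometry; no 6-DOF couch
  pitch/roll.
- Motion between sampled states is not interpolated (no swept-volume
  checks); choose the step accordingly.
- Surface semantics: distances are between surfaces, so a solid entirely
  containing another (impossible for the shipped fixtures) would read as
  clear; partial overlap always reads 0.
- The digital twin validates internal consistency of coarse vs fine
  modelling, not agreement with any physical machine.
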
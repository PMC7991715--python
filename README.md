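# rtclear

CT-based collision prediction for external-beam radiotherapy.

Noncoplanar beam arrangements (couch angle away from zero) can bring the
rotating accelerator head into contact with the treatment couch or the
patient.  `rtclear` predicts, before planning, which gantry/couch
configurations are deliverable: it reads a simulation CT, extracts the
external surfaces of everything on the couch (body, immobilization
shell/vacuum bag, accessories), lofts them into watertight triangle meshes,
combines them with a parametric polygonal model of the accelerator, and
sweeps the configuration space with margin-aware exact distance queries.
It also proposes the minimal isocenter/couch shift that clears a colliding
setup — the classic prone-breast rescue.

It is written for medical physicists and planners who want a
vendor-independent, scriptable collision check, and for tool builders who
need the pieces (contour extraction, contour lofting, proximity engine,
validation harness) as a library.

## Method

A configuration `(gantry angle g, couch angle c, couch shift s)` **collides**
when, for any monitored component pair `(A, B)`,

```
dist(A(g), B(c, s)) <= margin(A, B)
```

with `dist` the exact Euclidean surface-to-surface minimum distance,
`margin` the safety zone (30 mm default — the machine's touch guard, itself
a physical buffer, is checked at margin 0), and the boundary counting as a
collision.  Machine components are convex primitives, so machine-machine
distances are computed by GJK on the primitive polytopes; patient pairs run
through a best-first triangle engine (k-d-tree bounds + exact
triangle-pair kernel) that matches an exhaustive all-pairs oracle to 1e-9 mm.

Patient surfaces come from the CT by intensity windowing, thresholding,
grayscale-morphology closing, per-slice contour tracing, and lofting
(arc-length resampling, least-squares start-index correspondence, linear
inter-slice interpolation, ear-clipped end caps).  The isocenter and plate
height are manual inputs, as in clinical practice.

Prediction quality is scored as in validation studies of such software: a
confusion matrix (positive = collision) over the clinical grid — couch
0–90 and 270–350 in 10-degree steps, gantry 0–350 in 10-degree steps,
several couch heights — with

```
accuracy = (TP + TN) / (TP + TN + FP + FN),  TPR = TP / (TP + FN),  TNR = TN / (TN + FP)
```

Here the ground truth is a fine in-silico oracle (all CT slices, denser
rings, finer machine tessellation, spot-verified distances) and the
prediction is the production configuration; see `docs/methods.md`.

## Worked example

```
$ python examples/03_sweep_collision_map.py
machine_a: 2052 cells, 813 colliding (40%), margin 30 mm

collision matrix at plate height -100 mm ('#' = collision within the safety zone):
  couch\gantry   0  30  60  90 120 150 180 210 240 270 300 330
        0       .   .   .   .   .   .   .   .   .   .   .   .
       10       .   .   .   .   .   .   .   .   .   .   .   .
       20       .   .   .   .   #   #   .   .   #   .   .   .
       30       .   .   .   #   #   #   .   .   #   #   .   .
       ...
      350       .   .   .   .   .   .   .   .   .   .   .   .
```

Each row is a couch angle, each column a gantry angle; `.` cells are
deliverable, `#` cells would bring a machine part (or the phantom) within
30 mm of the gantry.  The other examples show contouring
(`01_contour_phantom.py`), mesh auditing against closed-form volumes
(`02_loft_and_measure.py`), the prone-breast minimal-shift search
(`04_prone_breast_shift.py`) and the digital-twin confusion matrix
(`05_digital_twin_validation.py`).

The same pipeline is scriptable from a shell:

```
rtclear synth --preset phantom --seed 7 --out ct/
rtclear contour --in ct/ --isocenter 0 0 0 --plate-height -110 --out case.dcm
rtclear sweep --machine src/rtclear/data/machine_a.yaml --contours case.dcm --out map.csv
rtclear validate --machine src/rtclear/data/machine_a.yaml --out report.json
```

## Repository layout

- `src/rtclear/` — the library (machine model, CT contouring, lofting,
  kinematics, collision engine, clearance search, metrics, synthetic data,
  CLI)
- `src/rtclear/data/` — two generic fixture machine descriptions
- `docs/` — methods note, coordinate conventions, machine file schema,
  structure-file dialect
- `examples/` — one short narrative script per capability
- `tests/` — pytest suite (unit, property and acceptance tests)
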
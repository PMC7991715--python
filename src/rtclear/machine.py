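"""Parametric linac machine descriptions and polygonal component meshes.

A machine is described in a human-editable YAML/JSON file (see
``rtclear/data/machine_a.yaml`` and ``docs/machine_schema.md``) as a set of
labelled components, each a list of solid primitives (box, cylinder,
truncated cone, extruded polygon) with a rigid pose in the component frame.
Components belong to kinematic groups: ``gantry_rotating`` parts turn with
the gantry, ``couch_translating`` parts ride the couch shifts and rotation,
``couch_rotating`` parts (the floor turntable) rotate but do not translate,
and ``static`` parts never move.

The two shipped fixture machines are *generic*: vendor-exact dimensions are
proprietary, so the fixtures use plausible C-arm dimensions that differ in
head diameter, face-to-isocenter clearance and couch width.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._polygon import ear_clip, is_simple, signed_area
from .errors import MachineSpecError, TravelLimitError
from .kinematics import MachineState, RigidTransform, couch_transform, gantry_transform
from .mesh import TriMesh

__all__ = [
    "PrimitiveSpec",
    "ComponentSpec",
    "MachineSpec",
    "SceneMesh",
    "load_machine_spec",
    "build_primitive_mesh",
    "build_component_meshes",
    "assemble_scene",
    "REQUIRED_COMPONENTS",
    "KINEMATIC_GROUPS",
]

KINEMATIC_GROUPS = ("gantry_rotating", "couch_rotating", "couch_translating", "static")
#: groups a collision pair may reference (``patient`` is the collider mesh
#: placed on the couch, which rides like a translating couch part)
PAIR_GROUPS = KINEMATIC_GROUPS + ("patient",)
SHAPES = ("box", "cylinder", "truncated_cone", "extruded_polygon")
REQUIRED_COMPONENTS = (
    "gantry_gun",
    "gantry_arm",
    "gantry_wall",
    "touch_guard",
    "couch_plate",
    "couch_rotator",
    "couch_base",
)

DEFAULT_MARGIN_MM = 30.0  # the 3-cm safety zone


def _euler_xyz(deg) -> np.ndarray:
    rx, ry, rz = (math.radians(float(v)) for v in deg)
    cx, sx = math.cos(rx), math.sin(rx)
    cy, sy = math.cos(ry), math.sin(ry)
    cz, sz = math.cos(rz), math.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


@dataclass(frozen=True)
class PrimitiveSpec:
    """One solid primitive in a component's local frame.

    ``dimensions`` is per-shape: box ``size_mm=(x,y,z)``; cylinder
    ``radius_mm, height_mm``; truncated_cone ``r_bottom_mm, r_top_mm,
    height_mm``; extruded_polygon ``vertices_mm`` ((N,2) list) and
    ``length_mm``.  ``tessellation`` is the segment count for curved shapes.
    """

    shape: str
    dimensions: dict
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tessellation: int = 48

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise MachineSpecError(f"unknown shape {self.shape!r} (allowed: {SHAPES})")
        if self.tessellation < 8:
            raise MachineSpecError("tessellation must be >= 8")

    def pose(self) -> RigidTransform:
        return RigidTransform(_euler_xyz(self.rotation_deg), self.translation_mm)


@dataclass(frozen=True)
class ComponentSpec:
    label: str
    group: str
    primitives: tuple[PrimitiveSpec, ...]


@dataclass(frozen=True)
class MachineSpec:
    """Validated parametric description of one accelerator."""

    name: str
    components: tuple[ComponentSpec, ...]
    isocenter_clearance_mm: float
    couch_height_range_mm: tuple[float, float]
    couch_shift_ranges_mm: dict  # lateral / longitudinal / vertical -> (lo, hi)
    couch_angle_range_deg: tuple[float, float] = (0.0, 360.0)
    gantry_angle_range_deg: tuple[float, float] = (0.0, 360.0)
    collision_pairs: tuple[tuple[str, str], ...] = ()
    default_margin_mm: float = DEFAULT_MARGIN_MM
    #: per-component-label margin override; the touch guard IS the safety
    #: buffer, so its pairs are checked at margin 0
    margin_overrides: dict = field(default_factory=dict)
    #: couch plate-top height (mm, isocenter frame) at zero couch state
    plate_top_zero_mm: float = 0.0

    def component(self, label: str) -> ComponentSpec:
        for c in self.components:
            if c.label == label:
                return c
        raise KeyError(label)

    def pair_margin_mm(self, label_a: str, label_b: str) -> float:
        """Effective clearance margin for one component pair.

        A component-level override (e.g. touch_guard -> 0) wins over the
        machine default; with overrides on both sides the smaller applies.
        """
        ov = [
            float(self.margin_overrides[l])
            for l in (label_a, label_b)
            if l in self.margin_overrides
        ]
        return min(ov) if ov else float(self.default_margin_mm)


@dataclass
class SceneMesh:
    """A mesh placed in the room frame, tagged with its kinematic group."""

    label: str
    group: str
    mesh: TriMesh


# --------------------------------------------------------------------------
# loading / validation
# --------------------------------------------------------------------------

def _err(path: str, msg: str) -> MachineSpecError:
    return MachineSpecError(f"{path}: {msg}")


def _positive(value, path: str) -> float:
    v = float(value)
    if not v > 0:
        raise _err(path, f"dimension must be > 0, got {v}")
    return v


def _parse_primitive(d: dict, path: str) -> PrimitiveSpec:
    shape = d.get("shape")
    if shape not in SHAPES:
        raise _err(f"{path}.shape", f"unknown shape {shape!r}")
    dims: dict = {}
    if shape == "box":
        size = d.get("size_mm")
        if size is None or len(size) != 3:
            raise _err(f"{path}.size_mm", "box needs size_mm = [x, y, z]")
        dims["size_mm"] = tuple(_positive(s, f"{path}.size_mm") for s in size)
    elif shape == "cylinder":
        dims["radius_mm"] = _positive(d.get("radius_mm", 0), f"{path}.radius_mm")
        dims["height_mm"] = _positive(d.get("height_mm", 0), f"{path}.height_mm")
    elif shape == "truncated_cone":
        dims["r_bottom_mm"] = _positive(d.get("r_bottom_mm", 0), f"{path}.r_bottom_mm")
        r_top = float(d.get("r_top_mm", 0))
        if r_top < 0:
            raise _err(f"{path}.r_top_mm", "must be >= 0")
        dims["r_top_mm"] = r_top
        dims["height_mm"] = _positive(d.get("height_mm", 0), f"{path}.height_mm")
    else:  # extruded_polygon
        verts = np.asarray(d.get("vertices_mm", []), dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
            raise _err(f"{path}.vertices_mm", "need >= 3 [x, y] vertices")
        if not is_simple(verts):
            raise _err(f"{path}.vertices_mm", "polygon is self-intersecting")
        dims["vertices_mm"] = verts
        dims["length_mm"] = _positive(d.get("length_mm", 0), f"{path}.length_mm")
    pose = d.get("pose", {}) or {}
    return PrimitiveSpec(
        shape=shape,
        dimensions=dims,
        translation_mm=tuple(float(v) for v in pose.get("translation_mm", (0, 0, 0))),
        rotation_deg=tuple(float(v) for v in pose.get("rotation_deg", (0, 0, 0))),
        tessellation=int(d.get("segments", 48)),
    )


def machine_spec_from_dict(doc: dict, source: str = "<dict>") -> MachineSpec:
    comps = []
    for i, cd in enumerate(doc.get("components", [])):
        path = f"components[{i}]"
        label = cd.get("label")
        if not label:
            raise _err(f"{path}.label", "missing component label")
        group = cd.get("group")
        if group not in KINEMATIC_GROUPS:
            raise _err(
                f"{path}.group",
                f"unknown kinematic group {group!r} for component {label!r}",
            )
        prims = tuple(
            _parse_primitive(pd, f"{path}.primitives[{j}] (component {label!r})")
            for j, pd in enumerate(cd.get("primitives", []))
        )
        if not prims:
            raise _err(f"{path}.primitives", f"component {label!r} has no primitives")
        comps.append(ComponentSpec(label, group, prims))

    labels = {c.label for c in comps}
    missing = [l for l in REQUIRED_COMPONENTS if l not in labels]
    if missing:
        raise _err("components", f"missing required component(s): {missing}")

    pairs = []
    for k, pair in enumerate(doc.get("collision_pairs", [])):
        if len(pair) != 2 or any(g not in PAIR_GROUPS for g in pair):
            raise _err(f"collision_pairs[{k}]", f"unknown group in pair {pair!r}")
        pairs.append((pair[0], pair[1]))
    if not pairs:
        raise _err("collision_pairs", "must list at least one monitored group pair")

    g_range = tuple(float(v) for v in doc.get("gantry_angle_range_deg", (0, 360)))
    if g_range[1] - g_range[0] < 360.0:
        raise _err("gantry_angle_range_deg", "gantry range must cover 360 degrees")

    margin = float(doc.get("default_margin_mm", DEFAULT_MARGIN_MM))
    overrides = {k: float(v) for k, v in (doc.get("margin_overrides") or {}).items()}
    if margin < 0 or any(v < 0 for v in overrides.values()):
        raise _err("default_margin_mm", "margins must be >= 0")
    for k in overrides:
        if k not in labels:
            raise _err(f"margin_overrides.{k}", "override names unknown component")

    shift_ranges = {
        axis: tuple(float(v) for v in rng)
        for axis, rng in (doc.get("couch_shift_ranges_mm") or {}).items()
    }
    for axis in ("lateral", "longitudinal", "vertical"):
        shift_ranges.setdefault(axis, (-500.0, 500.0))

    try:
        clearance = _positive(
            doc.get("isocenter_clearance_mm", 0), "isocenter_clearance_mm"
        )
    except (TypeError, ValueError):
        raise _err("isocenter_clearance_mm", "required positive number")

    return MachineSpec(
        name=str(doc.get("name", Path(source).stem)),
        components=tuple(comps),
        isocenter_clearance_mm=clearance,
        couch_height_range_mm=tuple(
            float(v) for v in doc.get("couch_height_range_mm", (-650, 50))
        ),
        couch_shift_ranges_mm=shift_ranges,
        couch_angle_range_deg=tuple(
            float(v) for v in doc.get("couch_angle_range_deg", (0, 360))
        ),
        gantry_angle_range_deg=g_range,
        collision_pairs=tuple(pairs),
        default_margin_mm=margin,
        margin_overrides=overrides,
        plate_top_zero_mm=float(doc.get("plate_top_zero_mm", 0.0)),
    )


def load_machine_spec(path) -> MachineSpec:
    """Load and validate a machine-description YAML/JSON file."""
    p = Path(path)
    if not p.exists():
        raise MachineSpecError(f"machine file not found: {p}")
    text = p.read_text()
    doc = json.loads(text) if p.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise MachineSpecError(f"{p}: not a mapping")
    return machine_spec_from_dict(doc, source=str(p))


# --------------------------------------------------------------------------
# primitive meshes
# --------------------------------------------------------------------------

def _box_mesh(size) -> TriMesh:
    sx, sy, sz = (s / 2.0 for s in size)
    v = np.array(
        [
            [-sx, -sy, -sz], [sx, -sy, -sz], [sx, sy, -sz], [-sx, sy, -sz],
            [-sx, -sy, sz], [sx, -sy, sz], [sx, sy, sz], [-sx, sy, sz],
        ]
    )
    f = np.array(
        [
            [0, 2, 1], [0, 3, 2],  # bottom (z-)
            [4, 5, 6], [4, 6, 7],  # top (z+)
            [0, 1, 5], [0, 5, 4],  # y-
            [2, 3, 7], [2, 7, 6],  # y+
            [1, 2, 6], [1, 6, 5],  # x+
            [3, 0, 4], [3, 4, 7],  # x-
        ]
    )
    return TriMesh(v, f)


def _ring(radius: float, z: float, n: int) -> np.ndarray:
    a = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([radius * np.cos(a), radius * np.sin(a), np.full(n, z)])


def _lateral_faces(n: int, bottom0: int, top0: int) -> np.ndarray:
    i = np.arange(n)
    j = (i + 1) % n
    lower = np.column_stack([bottom0 + i, bottom0 + j, top0 + j])
    upper = np.column_stack([bottom0 + i, top0 + j, top0 + i])
    return np.vstack([lower, upper])


def _cylinder_mesh(r_bottom: float, r_top: float, height: float, n: int) -> TriMesh:
    h2 = height / 2.0
    if r_top <= 1e-9:  # cone with apex
        vb = _ring(r_bottom, -h2, n)
        apex = np.array([[0.0, 0.0, h2]])
        cb = np.array([[0.0, 0.0, -h2]])
        verts = np.vstack([vb, apex, cb])
        i = np.arange(n)
        j = (i + 1) % n
        side = np.column_stack([i, j, np.full(n, n)])
        bottom = np.column_stack([j, i, np.full(n, n + 1)])
        return TriMesh(verts, np.vstack([side, bottom]))
    vb = _ring(r_bottom, -h2, n)
    vt = _ring(r_top, h2, n)
    cb = np.array([[0.0, 0.0, -h2]])
    ct = np.array([[0.0, 0.0, h2]])
    verts = np.vstack([vb, vt, cb, ct])
    i = np.arange(n)
    j = (i + 1) % n
    side = _lateral_faces(n, 0, n)
    bottom = np.column_stack([j, i, np.full(n, 2 * n)])
    top = np.column_stack([n + i, n + j, np.full(n, 2 * n + 1)])
    return TriMesh(verts, np.vstack([side, bottom, top]))


def _extrusion_mesh(vertices2d: np.ndarray, length: float) -> TriMesh:
    poly = np.asarray(vertices2d, dtype=float)
    if abs(signed_area(poly)) < 1e-12:
        raise MachineSpecError("degenerate polygon (zero area)")
    if signed_area(poly) < 0:
        poly = poly[::-1].copy()
    n = len(poly)
    h2 = length / 2.0
    vb = np.column_stack([poly, np.full(n, -h2)])
    vt = np.column_stack([poly, np.full(n, h2)])
    verts = np.vstack([vb, vt])
    side = _lateral_faces(n, 0, n)
    cap = ear_clip(poly)  # CCW in-plane
    top = cap + n  # CCW seen from +z -> outward up
    bottom = cap[:, ::-1]  # reversed -> outward down
    return TriMesh(verts, np.vstack([side, bottom, top]))


def build_primitive_mesh(p: PrimitiveSpec, segments: int | None = None) -> TriMesh:
    """Build the watertight, outward-oriented mesh of one primitive.

    ``segments`` overrides the stored tessellation (used to build coarse vs
    fine variants of the same machine).
    """
    n = int(segments if segments is not None else p.tessellation)
    if n < 8:
        raise MachineSpecError("tessellation must be >= 8")
    d = p.dimensions
    if p.shape == "box":
        mesh = _box_mesh(d["size_mm"])
    elif p.shape == "cylinder":
        mesh = _cylinder_mesh(d["radius_mm"], d["radius_mm"], d["height_mm"], n)
    elif p.shape == "truncated_cone":
        mesh = _cylinder_mesh(d["r_bottom_mm"], d["r_top_mm"], d["height_mm"], n)
    else:
        mesh = _extrusion_mesh(d["vertices_mm"], d["length_mm"])
    return mesh.transformed(p.pose())


def build_component_meshes(
    spec: MachineSpec, segments: int | None = None
) -> dict[str, TriMesh]:
    """Meshes of every component in its own frame, keyed by label."""
    return {
        c.label: TriMesh.concatenate(
            [build_primitive_mesh(p, segments) for p in c.primitives]
        )
        for c in spec.components
    }


# --------------------------------------------------------------------------
# scene assembly
# --------------------------------------------------------------------------

def _check_limits(spec: MachineSpec, state: MachineState, couch_top_mm: float) -> None:
    lat, lon, ver = state.couch_shift_mm
    for axis, val in (("lateral", lat), ("longitudinal", lon)):
        lo, hi = spec.couch_shift_ranges_mm[axis]
        if not lo <= val <= hi:
            raise TravelLimitError(
                f"couch {axis} shift {val} mm outside [{lo}, {hi}] mm"
            )
    lo, hi = spec.couch_height_range_mm
    top = couch_top_mm + ver
    if not lo - 1e-9 <= top <= hi + 1e-9:
        raise TravelLimitError(
            f"couch plate-top height {top} mm outside [{lo}, {hi}] mm (vertical axis)"
        )


def assemble_scene(
    spec: MachineSpec,
    state: MachineState,
    patient: TriMesh | None = None,
    couch_top_mm: float | None = None,
    override_limits: bool = False,
    component_meshes: dict[str, TriMesh] | None = None,
) -> list[SceneMesh]:
    """Place every component (and the optional patient) in the room frame.

    ``couch_top_mm`` is the plate-top height at zero couch state; it defaults
    to the patient's isocentric setup height when a
    :class:`~rtclear.kinematics.PlacedPatient` is supplied, otherwise to
    ``spec.plate_top_zero_mm``.  The patient rides the couch like a
    translating couch part.
    """
    patient_mesh = None
    if patient is not None:
        if hasattr(patient, "mesh"):  # PlacedPatient
            patient_mesh = patient.mesh
            if couch_top_mm is None:
                couch_top_mm = patient.couch_top_mm
        else:
            patient_mesh = patient
    if couch_top_mm is None:
        couch_top_mm = spec.plate_top_zero_mm
    if not override_limits:
        _check_limits(spec, state, couch_top_mm)

    meshes = component_meshes or build_component_meshes(spec)
    tg = gantry_transform(state.gantry_angle_deg)
    shift = np.asarray(state.couch_shift_mm, dtype=float)
    tc_translating = couch_transform(
        state.couch_angle_deg, shift + np.array([0.0, 0.0, couch_top_mm])
    )
    tc_rotating = couch_transform(state.couch_angle_deg, (0.0, 0.0, 0.0))

    out: list[SceneMesh] = []
    for comp in spec.components:
        m = meshes[comp.label]
        if comp.group == "gantry_rotating":
            m = m.transformed(tg, frame="room")
        elif comp.group == "couch_translating":
            m = m.transformed(tc_translating, frame="room")
        elif comp.group == "couch_rotating":
            m = m.transformed(tc_rotating, frame="room")
        else:  # static
            m = TriMesh(m.vertices.copy(), m.triangles.copy(), "room")
        out.append(SceneMesh(comp.label, comp.group, m))
    if patient_mesh is not None:
        out.append(
            SceneMesh(
                "patient",
                "patient",
                patient_mesh.transformed(tc_translating, frame="room"),
            )
        )
    return out
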
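"""Room coordinate frame and rigid kinematics of the gantry/couch assembly.

Room frame (IEC-61217-like, the single convention shared by every module):

* right-handed, origin at the treatment isocenter;
* ``+Z`` vertical up;
* ``+Y`` horizontal, from the isocenter toward the gantry stand;
* ``+X`` completes the frame (toward the patient's left for a
  head-first-supine patient lying with the head toward the gantry).

The gantry rotates about ``+Y``: at 0 deg the accelerator head sits directly
above the isocenter, and a head reference point ``(0, 0, +d)`` maps to
``(+d, 0, 0)`` at 90 deg.  The couch rotates about ``+Z``, counterclockwise
positive seen from above; couch translations are applied in the couch frame
*before* the couch rotation.  Angles are degrees throughout the public API.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RigidTransform",
    "MachineState",
    "PlacedPatient",
    "gantry_transform",
    "couch_transform",
    "place_patient",
    "isocentric_couch_top",
    "normalize_angle_deg",
]


def normalize_angle_deg(angle: float) -> float:
    """Normalize an angle to the half-open interval [0, 360)."""
    a = float(angle) % 360.0
    # -1e-14 % 360 == 360.0 in floating point; fold that back to 0.
    return 0.0 if a == 360.0 else a


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``p -> R @ p + t`` (millimetres)."""

    rotation: np.ndarray  # (3, 3) orthonormal, det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValueError("rotation determinant is not +1 (improper transform)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotation(cls, R: np.ndarray) -> "RigidTransform":
        return cls(np.asarray(R, dtype=float), np.zeros(3))

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(t, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) array (or a single 3-vector) of points."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self o other`` (``other`` applied first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)


@dataclass(frozen=True)
class MachineState:
    """One gantry/couch configuration.

    ``couch_shift_mm`` is (lateral, longitudinal, vertical) in the couch
    frame, applied before the couch rotation.
    """

    gantry_angle_deg: float = 0.0
    couch_angle_deg: float = 0.0
    couch_shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "gantry_angle_deg", normalize_angle_deg(self.gantry_angle_deg)
        )
        object.__setattr__(
            self, "couch_angle_deg", normalize_angle_deg(self.couch_angle_deg)
        )
        s = tuple(float(v) for v in self.couch_shift_mm)
        if len(s) != 3 or not all(np.isfinite(s)):
            raise ValueError("couch_shift_mm must be 3 finite values")
        object.__setattr__(self, "couch_shift_mm", s)


def _rot_y(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_z(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def gantry_transform(angle_deg: float) -> RigidTransform:
    """Rigid transform of the rotating gantry assembly.

    Rotation about the horizontal ``+Y`` axis through the isocenter.  0 deg is
    the identity (head above the isocenter); at 90 deg the point ``(0,0,d)``
    maps to ``(d,0,0)``.
    """
    return RigidTransform.from_rotation(_rot_y(normalize_angle_deg(angle_deg)))


def couch_transform(angle_deg: float, shift_mm=(0.0, 0.0, 0.0)) -> RigidTransform:
    """Rigid transform of the couch assembly.

    The translation ``shift_mm = (lateral, longitudinal, vertical)`` is applied
    in the couch frame, then the whole assembly rotates by ``angle_deg`` about
    the vertical axis through the isocenter (CCW positive from above).
    """
    Rz = _rot_z(normalize_angle_deg(angle_deg))
    t = np.asarray(shift_mm, dtype=float)
    return RigidTransform(Rz, Rz @ t)


# --------------------------------------------------------------------------
# patient placement
# --------------------------------------------------------------------------

#: CT frame axes are (x lateral, v vertical-up, z slice/longitudinal); the
#: couch frame is (X lateral, Y toward gantry, Z up) with the plate-top
#: surface at Z = 0.  A head-first patient maps by the proper rotation
#: X = -x, Y = z, Z = v (180 deg about the slice axis composed with the
#: axis relabel), so rigidity is preserved exactly.
_CT_TO_COUCH = np.array([[-1.0, 0.0, 0.0], [0.0, 0.0, 1.0], [0.0, 1.0, 0.0]])


def isocentric_couch_top(isocenter_mm, ct_plate_height_mm: float) -> float:
    """Plate-top height (room frame, zero couch state) that brings the
    patient's CT-marked isocenter onto the room isocenter."""
    return -(float(isocenter_mm[1]) - float(ct_plate_height_mm))


@dataclass(frozen=True)
class PlacedPatient:
    """A patient/collider mesh in the couch frame plus its setup height.

    ``couch_top_mm`` is the plate-top height at zero couch state that puts
    the patient's isocenter on the room isocenter (isocentric setup).
    """

    mesh: object  # TriMesh in couch frame (plate top = Z 0)
    couch_top_mm: float


def place_patient(
    mesh,
    isocenter_mm,
    ct_plate_height_mm: float,
    couch_top_mm: float | None = None,
) -> PlacedPatient:
    """Rigidly place a CT-derived collider mesh on the treatment couch.

    ``mesh`` is a TriMesh in CT coordinates (x, v, z) or a ContourStack's
    lofted mesh; ``isocenter_mm`` the manually defined isocenter in the same
    coordinates; ``ct_plate_height_mm`` the vertical coordinate of the CT
    couch-plate top.  The result lives in the couch frame with the CT plate
    plane on the machine plate top (Z = 0), so the vertical offset between
    patient and couch is preserved from CT.  With the returned (or supplied)
    ``couch_top_mm`` used as the setup height, the patient isocenter sits on
    the room isocenter at zero couch state.
    """
    import warnings

    iso = np.asarray(isocenter_mm, dtype=float).reshape(3)
    verts = np.asarray(mesh.vertices, dtype=float)
    lo, hi = verts.min(axis=0), verts.max(axis=0)
    if np.any(iso < lo) or np.any(iso > hi):
        warnings.warn(
            "isocenter lies outside the patient mesh bounding box", stacklevel=2
        )
    offset = np.array([iso[0], 0.0, iso[2]])  # keep CT vertical, center x/z
    local = (verts - offset) @ _CT_TO_COUCH.T
    local[:, 2] -= float(ct_plate_height_mm)
    if couch_top_mm is None:
        couch_top_mm = isocentric_couch_top(iso, ct_plate_height_mm)
    from .mesh import TriMesh

    return PlacedPatient(
        TriMesh(local, np.asarray(mesh.triangles).copy(), frame="couch"),
        float(couch_top_mm),
    )
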
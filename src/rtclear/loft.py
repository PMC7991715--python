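"""Planar-contour lofting: ContourStack -> watertight collider TriMesh.

The surface between two adjacent slices is built by resampling both contours
to the same point count by arc length, aligning their start indices by a
least-squares correspondence search, optionally inserting linearly
interpolated intermediate rings, connecting consecutive rings with triangle
strips, and capping the first and last rings by ear-clipping triangulation.
"""

from __future__ import annotations

import numpy as np

from ._polygon import ear_clip, signed_area
from .contour import SliceContour
from .errors import MeshBuildError
from .mesh import TriMesh

__all__ = [
    "resample_contour",
    "correspondence_offset",
    "interpolate_contours",
    "loft_stack",
    "loft_collider",
]

DEFAULT_RING_POINTS = 128
#: default axial step target (mm) used to pick interpolation substeps;
#: mirrors the scale of CT slice spacing
DEFAULT_MAX_AXIAL_STEP_MM = 5.0


def resample_contour(c: SliceContour, n: int) -> SliceContour:
    """Resample a closed contour to ``n`` points equally spaced by arc length.

    The first output point is the input start point; orientation (CCW) is
    preserved.
    """
    if n < 3:
        raise MeshBuildError("need n >= 3 resample points")
    pts = c.points
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    total = float(seg.sum())
    if total <= 0:
        raise MeshBuildError("degenerate (zero-perimeter) contour")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    target = np.arange(n) * total / n
    x = np.interp(target, s, closed[:, 0])
    y = np.interp(target, s, closed[:, 1])
    return SliceContour(c.z_mm, np.column_stack([x, y]), c.label)


def correspondence_offset(ca: SliceContour, cb: SliceContour) -> int:
    """Start-index offset aligning two equally-sampled contours.

    Returns the ``k`` minimizing ``sum_i |A_i - B_{(i+k) mod n}|^2`` after
    centroid alignment (so a couch-position drift between slices does not
    bias the match); ties break toward the smallest ``k``.
    """
    a = ca.points
    b = cb.points
    if len(a) != len(b):
        raise MeshBuildError("contours must have equal point counts")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    n = len(a)
    # cost(k) = const - 2 * sum_i a_i . b_{i+k}
    costs = np.array([-2.0 * np.sum(a * np.roll(b, -k, axis=0)) for k in range(n)])
    return int(np.argmin(costs))


def interpolate_contours(
    ca: SliceContour, cb: SliceContour, z: float
) -> SliceContour:
    """Pointwise linear blend of two aligned contours at slice position z."""
    if len(ca.points) != len(cb.points):
        raise MeshBuildError("contours must have equal point counts")
    z1, z2 = ca.z_mm, cb.z_mm
    if not (min(z1, z2) - 1e-9 <= z <= max(z1, z2) + 1e-9):
        raise MeshBuildError(f"z={z} outside [{z1}, {z2}]")
    w = 0.0 if z2 == z1 else (z - z1) / (z2 - z1)
    pts = (1.0 - w) * ca.points + w * cb.points
    return SliceContour(z, pts, ca.label)


def _cap_triangles(ring_pts: np.ndarray, base: int, n: int, outward_up: bool):
    """Triangulate one ring as an end cap, indices offset by ``base``."""
    try:
        tris = ear_clip(ring_pts)
    except ValueError as e:
        raise MeshBuildError(f"cannot cap end ring: {e}") from e
    tris = tris + base
    return tris if outward_up else tris[:, ::-1]


def loft_stack(
    contours: list[SliceContour],
    interp_substeps: int | None = None,
    n_points: int = DEFAULT_RING_POINTS,
) -> TriMesh:
    """Loft one collider's slice contours into a watertight solid.

    ``interp_substeps`` inserts that many interpolated rings in every
    adjacent-slice gap (default: enough for an axial step <= 5 mm).  End rings
    are exactly the first/last input contours (resampled), so increasing the
    substeps never moves the end caps.
    """
    contours = sorted(contours, key=lambda c: c.z_mm)
    if len(contours) < 2:
        raise MeshBuildError("a collider needs >= 2 slices to loft")

    rings = [resample_contour(c, n_points) for c in contours]
    # propagate start-index alignment down the stack
    aligned = [rings[0]]
    for r in rings[1:]:
        k = correspondence_offset(aligned[-1], r)
        aligned.append(
            SliceContour(r.z_mm, np.roll(r.points, -k, axis=0), r.label)
        )

    if interp_substeps is None:
        dz = float(np.median(np.diff([r.z_mm for r in aligned])))
        interp_substeps = max(0, int(np.ceil(dz / DEFAULT_MAX_AXIAL_STEP_MM)) - 1)

    dense: list[SliceContour] = [aligned[0]]
    for a, b in zip(aligned, aligned[1:]):
        for s in range(1, interp_substeps + 1):
            z = a.z_mm + (b.z_mm - a.z_mm) * s / (interp_substeps + 1)
            dense.append(interpolate_contours(a, b, z))
        dense.append(b)

    n = n_points
    verts = np.concatenate(
        [
            np.column_stack([r.points[:, 0], np.full(n, r.z_mm), r.points[:, 1]])
            for r in dense
        ]
    )
    # NOTE: vertex layout is (x, z_slice, v); callers treat the mesh as living
    # in CT coordinates (x, v, z) -- reorder to (x, v, z):
    verts = verts[:, [0, 2, 1]]

    i = np.arange(n)
    j = (i + 1) % n
    tris = []
    for r in range(len(dense) - 1):
        b0, b1 = r * n, (r + 1) * n
        # rings are CCW in (x, v) seen from +z; outward side winding:
        tris.append(np.column_stack([b0 + i, b0 + j, b1 + j]))
        tris.append(np.column_stack([b0 + i, b1 + j, b1 + i]))
    tris = np.vstack(tris)

    cap_lo = _cap_triangles(dense[0].points, 0, n, outward_up=False)
    cap_hi = _cap_triangles(dense[-1].points, (len(dense) - 1) * n, n, outward_up=True)
    mesh = TriMesh(verts, np.vstack([tris, cap_lo, cap_hi]), frame="component")
    if mesh.signed_volume() < 0:  # safety: flip to outward orientation
        mesh = TriMesh(verts, mesh.triangles[:, ::-1], frame="component")
    return mesh


def loft_collider(
    stack,
    label: str,
    interp_substeps: int | None = None,
    n_points: int = DEFAULT_RING_POINTS,
    slice_step: int = 1,
) -> TriMesh:
    """Loft one labelled collider from a ContourStack.

    ``slice_step`` subsamples the slices (production/coarse configurations);
    the first and last slices are always kept.  Gaps in the slice sequence
    (branching colliders vanishing mid-stack) split the collider into
    separately lofted, individually watertight pieces.
    """
    cs = stack.for_label(label)
    if slice_step > 1 and len(cs) > 2:
        keep = list(range(0, len(cs), slice_step))
        if keep[-1] != len(cs) - 1:
            keep.append(len(cs) - 1)
        cs = [cs[i] for i in keep]
    if len(cs) < 2:
        raise MeshBuildError(f"collider {label!r} has a single slice")

    zs = np.array([c.z_mm for c in cs])
    dz = np.diff(zs)
    gap = 1.5 * np.median(dz) if len(dz) else np.inf
    runs, start = [], 0
    for k, d in enumerate(dz):
        if d > gap * (slice_step if slice_step > 1 else 1):
            runs.append(cs[start : k + 1])
            start = k + 1
    runs.append(cs[start:])
    pieces = [
        loft_stack(run, interp_substeps, n_points) for run in runs if len(run) >= 2
    ]
    if not pieces:
        raise MeshBuildError(f"collider {label!r} has no loftable slice run")
    return TriMesh.concatenate(pieces)
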
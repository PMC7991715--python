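"""GJK distance between convex polytopes.

Machine components are convex primitives (boxes, cylinders, cones, convex
extrusions), so their pairwise distance can be computed exactly on the
primitive vertex polytopes with the Gilbert-Johnson-Keerthi algorithm
instead of triangle-pair queries.  Returns the distance between the convex
hulls: identical to the triangulated-surface distance for disjoint solids,
and 0 for touching or overlapping ones.

The simplex closest-point routine follows Ericson's Voronoi-region case
analysis for segment/triangle/tetrahedron.
"""

from __future__ import annotations

import numpy as np

__all__ = ["gjk_distance"]

_MAX_ITER = 128
_REL_TOL = 1e-12


def _closest_segment(a, b):
    ab = b - a
    t = -np.dot(a, ab)
    denom = np.dot(ab, ab)
    if denom <= 0.0 or t <= 0.0:
        return a, [0]
    if t >= denom:
        return b, [1]
    return a + (t / denom) * ab, [0, 1]


def _closest_triangle(a, b, c):
    ab = b - a
    ac = c - a
    ap = -a
    d1 = np.dot(ab, ap)
    d2 = np.dot(ac, ap)
    if d1 <= 0.0 and d2 <= 0.0:
        return a, [0]
    bp = -b
    d3 = np.dot(ab, bp)
    d4 = np.dot(ac, bp)
    if d3 >= 0.0 and d4 <= d3:
        return b, [1]
    cp = -c
    d5 = np.dot(ab, cp)
    d6 = np.dot(ac, cp)
    if d6 >= 0.0 and d5 <= d6:
        return c, [2]
    vc = d1 * d4 - d3 * d2
    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
        v = d1 / (d1 - d3)
        return a + v * ab, [0, 1]
    vb = d5 * d2 - d1 * d6
    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
        w = d2 / (d2 - d6)
        return a + w * ac, [0, 2]
    va = d3 * d6 - d5 * d4
    if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return b + w * (c - b), [1, 2]
    denom = va + vb + vc
    v = vb / denom
    w = vc / denom
    return a + ab * v + ac * w, [0, 1, 2]


def _closest_tetra(W):
    a, b, c, d = W
    scale = max(float(np.abs(p).max()) for p in W) + 1e-30

    def strictly_same_side(p0, p1, p2, p3) -> bool:
        # origin strictly on the same side of plane (p0,p1,p2) as p3, with
        # the tetra non-degenerate across that face (a flat tetra has no
        # interior; its closest point lies on a face)
        n = np.cross(p1 - p0, p2 - p0)
        nn = float(np.linalg.norm(n))
        if nn <= 1e-12 * scale * scale:
            return False
        h_origin = float(np.dot(n, -p0)) / nn
        h_apex = float(np.dot(n, p3 - p0)) / nn
        if abs(h_apex) <= 1e-9 * scale:
            return False
        return h_origin * h_apex >= 0.0

    inside = (
        strictly_same_side(a, b, c, d)
        and strictly_same_side(a, b, d, c)
        and strictly_same_side(a, c, d, b)
        and strictly_same_side(b, c, d, a)
    )
    if inside:
        return np.zeros(3), [0, 1, 2, 3]
    best = None
    for idx in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)):
        v, feat = _closest_triangle(W[idx[0]], W[idx[1]], W[idx[2]])
        n2 = np.dot(v, v)
        if best is None or n2 < best[0]:
            best = (n2, v, [idx[i] for i in feat])
    return best[1], best[2]


def _closest_on_simplex(W: list):
    if len(W) == 1:
        return W[0], [0]
    if len(W) == 2:
        return _closest_segment(W[0], W[1])
    if len(W) == 3:
        return _closest_triangle(W[0], W[1], W[2])
    return _closest_tetra(W)


def gjk_distance(
    a_verts: np.ndarray,
    b_verts: np.ndarray,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
) -> float:
    """Distance between conv(a_verts) and the rigidly placed conv(b_verts).

    ``rotation``/``translation`` place B in A's frame; supports of the
    transformed polytope are taken without materializing the transform.
    """
    A = np.ascontiguousarray(a_verts, dtype=float)
    B = np.ascontiguousarray(b_verts, dtype=float)
    if rotation is None:
        R = np.eye(3)
    else:
        R = np.asarray(rotation, dtype=float)
    t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)

    def support(d):
        # max over A of a.d  minus  min over (R b + t) of b.d
        ia = int(np.argmax(A @ d))
        ib = int(np.argmax(B @ (-(R.T @ d))))
        return A[ia] - (R @ B[ib] + t)

    v = support(np.array([1.0, 0.0, 0.0]))
    W: list = [v]
    dist2 = np.dot(v, v)
    for _ in range(_MAX_ITER):
        if dist2 <= 1e-20:
            return 0.0
        w = support(-v)
        # optimality: no support point improves on the current estimate
        # (v.w lower-bounds |v*| |v|, so equality within tolerance is proof)
        if dist2 - np.dot(v, w) <= _REL_TOL * dist2:
            return float(np.sqrt(dist2))
        # w already a simplex vertex: the same proof, found the hard way
        if any(np.array_equal(w, x) for x in W):
            return float(np.sqrt(dist2))
        W.append(w)
        v, feat = _closest_on_simplex(W)
        W = [W[i] for i in feat]
        if len(W) == 4:  # origin enclosed by the tetrahedron
            return 0.0
        new_dist2 = np.dot(v, v)
        if new_dist2 >= dist2:  # numerical stall: keep the best estimate
            return float(np.sqrt(min(new_dist2, dist2)))
        dist2 = new_dist2
    return float(np.sqrt(dist2))
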
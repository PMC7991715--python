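"""Exact distance primitives between triangles, segments and points.

Vectorized closed-form kernels (Ericson-style region tests) used by both the
accelerated proximity engine and the exhaustive brute-force oracle.  The
minimum distance between two triangles is attained either between a vertex of
one and the face of the other, between a pair of edges, or is exactly zero
when the surfaces intersect; the kernel evaluates all 15 feature distances
and the 6 edge-through-face crossing tests.

All inputs are float arrays broadcast over a leading batch axis K.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def _dot(a, b):
    return np.einsum("...i,...i->...", a, b)


def closest_point_on_triangle(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle ``tri[k]`` (K,3,3) to each point ``p[k]``."""
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = _dot(ab, ap)
    d2 = _dot(ac, ap)
    bp = p - b
    d3 = _dot(ab, bp)
    d4 = _dot(ac, bp)
    cp = p - c
    d5 = _dot(ab, cp)
    d6 = _dot(ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    # interior (default) answer
    denom = va + vb + vc
    denom = np.where(np.abs(denom) < _EPS, _EPS, denom)
    v = vb / denom
    w = vc / denom
    out = a + ab * v[..., None] + ac * w[..., None]

    # edge BC region
    d43 = d4 - d3
    d56 = d5 - d6
    dd = d43 + d56
    wbc = d43 / np.where(np.abs(dd) < _EPS, _EPS, dd)
    m = (va <= 0) & (d43 >= 0) & (d56 >= 0)
    out = np.where(m[..., None], b + (c - b) * np.clip(wbc, 0.0, 1.0)[..., None], out)

    # edge AC region
    wac = d2 / np.where(np.abs(d2 - d6) < _EPS, _EPS, d2 - d6)
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out = np.where(m[..., None], a + ac * np.clip(wac, 0.0, 1.0)[..., None], out)

    # edge AB region
    vab = d1 / np.where(np.abs(d1 - d3) < _EPS, _EPS, d1 - d3)
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out = np.where(m[..., None], a + ab * np.clip(vab, 0.0, 1.0)[..., None], out)

    # vertex regions (checked last: they win over edge/face answers)
    out = np.where(((d6 >= 0) & (d5 <= d6))[..., None], c, out)
    out = np.where(((d3 >= 0) & (d4 <= d3))[..., None], b, out)
    out = np.where(((d1 <= 0) & (d2 <= 0))[..., None], a, out)
    return out


def point_triangle_distance(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    q = closest_point_on_triangle(p, tri)
    return np.linalg.norm(p - q, axis=-1)


def segment_segment_distance(p1, q1, p2, q2) -> np.ndarray:
    """Minimum distance between segments [p1,q1] and [p2,q2], batched."""
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = _dot(d1, d1)
    e = _dot(d2, d2)
    f = _dot(d2, r)
    c = _dot(d1, r)
    b = _dot(d1, d2)
    denom = a * e - b * b

    s = np.where(denom > _EPS, np.clip((b * f - c * e) / np.where(denom > _EPS, denom, 1.0), 0.0, 1.0), 0.0)
    t = np.where(e > _EPS, (b * s + f) / np.where(e > _EPS, e, 1.0), 0.0)
    t_cl = np.clip(t, 0.0, 1.0)
    recl = t != t_cl
    a_safe = np.where(a > _EPS, a, 1.0)
    s = np.where(recl, np.clip((b * t_cl - c) / a_safe, 0.0, 1.0), s)
    s = np.where(a > _EPS, s, 0.0)
    diff = (p1 + s[..., None] * d1) - (p2 + t_cl[..., None] * d2)
    return np.linalg.norm(diff, axis=-1)


def _segment_pierces_triangle(p, q, tri) -> np.ndarray:
    """True where the open segment crosses the triangle's interior plane patch."""
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    n = np.cross(b - a, c - a)
    sp = _dot(p - a, n)
    sq = _dot(q - a, n)
    crossing = sp * sq < 0.0
    denom = sp - sq
    denom = np.where(np.abs(denom) < _EPS, _EPS, denom)
    u = sp / denom
    x = p + u[..., None] * (q - p)
    # barycentric inside test for x
    v0 = b - a
    v1 = c - a
    v2 = x - a
    d00 = _dot(v0, v0)
    d01 = _dot(v0, v1)
    d11 = _dot(v1, v1)
    d20 = _dot(v2, v0)
    d21 = _dot(v2, v1)
    det = d00 * d11 - d01 * d01
    det = np.where(np.abs(det) < _EPS, _EPS, det)
    v = (d11 * d20 - d01 * d21) / det
    w = (d00 * d21 - d01 * d20) / det
    inside = (v >= 0.0) & (w >= 0.0) & (v + w <= 1.0)
    return crossing & inside


def tri_tri_distance(
    ta: np.ndarray, tb: np.ndarray, pierce_mask: np.ndarray | None = None
) -> np.ndarray:
    """Exact minimum distance between triangle batches (K,3,3) vs (K,3,3).

    ``pierce_mask`` optionally restricts the edge-through-face intersection
    test to a subset of pairs — callers may pass the pairs whose bounding
    volumes overlap, since disjoint bounds cannot intersect.
    """
    ta = np.asarray(ta, dtype=float)
    tb = np.asarray(tb, dtype=float)
    K = np.broadcast_shapes(ta.shape[:-2], tb.shape[:-2])
    ta = np.broadcast_to(ta, K + (3, 3))
    tb = np.broadcast_to(tb, K + (3, 3))

    best = np.full(K, np.inf)
    # 6 vertex-vs-face distances
    for i in range(3):
        best = np.minimum(best, point_triangle_distance(ta[..., i, :], tb))
        best = np.minimum(best, point_triangle_distance(tb[..., i, :], ta))
    # 9 edge-vs-edge distances
    for i in range(3):
        p1, q1 = ta[..., i, :], ta[..., (i + 1) % 3, :]
        for j in range(3):
            p2, q2 = tb[..., j, :], tb[..., (j + 1) % 3, :]
            best = np.minimum(best, segment_segment_distance(p1, q1, p2, q2))
    # surface intersection => distance exactly 0
    if pierce_mask is None:
        sa, sb = ta, tb
        scatter = None
    else:
        scatter = np.nonzero(np.broadcast_to(pierce_mask, K))
        sa, sb = ta[scatter], tb[scatter]
    if len(sa):
        pierced = np.zeros(sa.shape[:-2], dtype=bool)
        for i in range(3):
            pierced |= _segment_pierces_triangle(
                sa[..., i, :], sa[..., (i + 1) % 3, :], sb
            )
            pierced |= _segment_pierces_triangle(
                sb[..., i, :], sb[..., (i + 1) % 3, :], sa
            )
        if scatter is None:
            best = np.where(pierced, 0.0, best)
        else:
            hit = np.zeros(K, dtype=bool)
            hit[scatter] = pierced
            best = np.where(hit, 0.0, best)
    return best
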
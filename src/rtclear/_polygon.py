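"""2D closed-polygon helpers: orientation, simplicity, ear-clipping.

Polygons are (N, 2) float arrays of consecutive vertices, closed implicitly
(the last vertex connects back to the first, without repetition).
"""

from __future__ import annotations

import numpy as np

__all__ = ["signed_area", "ensure_ccw", "is_simple", "ear_clip"]


def signed_area(poly: np.ndarray) -> float:
    """Shoelace area; positive for counter-clockwise orientation."""
    p = np.asarray(poly, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def ensure_ccw(poly: np.ndarray) -> np.ndarray:
    p = np.asarray(poly, dtype=float)
    return p if signed_area(p) >= 0 else p[::-1].copy()


def _segments_properly_intersect(p1, p2, p3, p4) -> bool:
    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1 = orient(p3, p4, p1)
    d2 = orient(p3, p4, p2)
    d3 = orient(p1, p2, p3)
    d4 = orient(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def is_simple(poly: np.ndarray) -> bool:
    """True when no two non-adjacent edges properly intersect (O(n^2) scan)."""
    p = np.asarray(poly, dtype=float)
    n = len(p)
    if n < 3:
        return False
    for i in range(n):
        a1, a2 = p[i], p[(i + 1) % n]
        for j in range(i + 1, n):
            if j == i or (j + 1) % n == i or (i + 1) % n == j:
                continue
            if _segments_properly_intersect(a1, a2, p[j], p[(j + 1) % n]):
                return False
    return True


def _point_in_tri(pt, a, b, c, eps=1e-12) -> bool:
    d1 = (b[0] - a[0]) * (pt[1] - a[1]) - (b[1] - a[1]) * (pt[0] - a[0])
    d2 = (c[0] - b[0]) * (pt[1] - b[1]) - (c[1] - b[1]) * (pt[0] - b[0])
    d3 = (a[0] - c[0]) * (pt[1] - c[1]) - (a[1] - c[1]) * (pt[0] - c[0])
    return d1 >= -eps and d2 >= -eps and d3 >= -eps


def ear_clip(poly: np.ndarray) -> np.ndarray:
    """Triangulate a simple polygon by ear clipping.

    Accepts CW or CCW input; returns (M, 3) indices into the *input* vertex
    order with CCW winding in the polygon plane.  Handles non-convex outlines
    (body cross-sections); degenerate (zero-area) polygons raise ValueError.
    """
    p = np.asarray(poly, dtype=float)
    n = len(p)
    if n < 3:
        raise ValueError("polygon needs at least 3 vertices")
    area = signed_area(p)
    if abs(area) < 1e-12:
        raise ValueError("degenerate polygon (zero area)")
    order = list(range(n)) if area > 0 else list(range(n - 1, -1, -1))

    tris: list[tuple[int, int, int]] = []
    scale = max(np.ptp(p[:, 0]), np.ptp(p[:, 1]))
    eps = 1e-12 * scale * scale

    guard = 0
    while len(order) > 3:
        guard += 1
        if guard > 4 * n * n:
            raise ValueError("ear clipping failed (polygon may be non-simple)")
        m = len(order)
        clipped = False
        for k in range(m):
            i0, i1, i2 = order[k - 1], order[k], order[(k + 1) % m]
            a, b, c = p[i0], p[i1], p[i2]
            cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if cross <= eps:  # reflex or collinear corner: not an ear
                continue
            ok = True
            for j in order:
                if j in (i0, i1, i2):
                    continue
                if _point_in_tri(p[j], a, b, c):
                    ok = False
                    break
            if ok:
                tris.append((i0, i1, i2))
                order.pop(k)
                clipped = True
                break
        if not clipped:
            # fall back: clip the least-reflex corner to stay terminating on
            # near-degenerate outlines
            k = 0
            i0, i1, i2 = order[k - 1], order[k], order[(k + 1) % m]
            tris.append((i0, i1, i2))
            order.pop(k)
    tris.append((order[0], order[1], order[2]))
    return np.asarray(tris, dtype=np.int64)
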
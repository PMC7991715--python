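"""Triangle-mesh container shared by every geometry stage.

A collider, machine component or lofted patient surface is a plain indexed
triangle surface: a set of vertices and a set of triangles.  The container is
deliberately minimal; heavy mesh machinery (I/O formats, repair) is delegated
to :mod:`trimesh` where needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TriMesh"]


@dataclass
class TriMesh:
    """Indexed triangle surface in millimetres.

    ``frame`` names the coordinate frame the vertices live in
    (``component``, ``couch`` or ``room``).
    """

    vertices: np.ndarray  # (N, 3) float
    triangles: np.ndarray  # (M, 3) int
    frame: str = "component"

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=float))
        t = np.ascontiguousarray(np.asarray(self.triangles, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be an (N, 3) array")
        if t.ndim != 2 or t.shape[1] != 3:
            raise ValueError("triangles must be an (M, 3) index array")
        if not np.all(np.isfinite(v)):
            raise ValueError("vertex coordinates must be finite")
        if t.size and (t.min() < 0 or t.max() >= len(v)):
            raise ValueError("triangle indices out of range")
        self.vertices = v
        self.triangles = t

    # ------------------------------------------------------------------ basic
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_corners(self) -> np.ndarray:
        """Return triangle corner coordinates as an (M, 3, 3) array."""
        return self.vertices[self.triangles]

    def transformed(self, transform, frame: str | None = None) -> "TriMesh":
        """Return a copy with vertices mapped through a RigidTransform."""
        return TriMesh(
            transform.apply(self.vertices), self.triangles.copy(), frame or self.frame
        )

    def bounds(self) -> np.ndarray:
        """Axis-aligned bounds, shape (2, 3): [min; max]."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    # -------------------------------------------------------------- integrity
    def signed_volume(self) -> float:
        """Enclosed volume via the divergence theorem (signed tetrahedra).

        Positive for a closed, outward-oriented surface.
        """
        tc = self.triangle_corners()
        return float(np.einsum("ij,ij->i", tc[:, 0], np.cross(tc[:, 1], tc[:, 2])).sum() / 6.0)

    def edge_counts(self):
        """Map undirected-edge use counts; watertight means every count is 2."""
        tri = self.triangles
        edges = np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
        und = np.sort(edges, axis=1)
        uniq, counts = np.unique(und, axis=0, return_counts=True)
        return uniq, counts

    def is_watertight(self) -> bool:
        """True when every undirected edge is used by exactly two triangles,
        once in each direction (consistent winding)."""
        if self.n_triangles == 0:
            return False
        uniq, counts = self.edge_counts()
        if not np.all(counts == 2):
            return False
        # consistent winding: each directed edge appears exactly once
        tri = self.triangles
        directed = np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
        _, dcounts = np.unique(directed, axis=0, return_counts=True)
        return bool(np.all(dcounts == 1))

    def euler_characteristic(self) -> int:
        """V - E + F (2 per sphere-like connected component)."""
        uniq, _ = self.edge_counts()
        used = np.unique(self.triangles)
        return int(len(used) - len(uniq) + self.n_triangles)

    def subdivided(self, max_edge_mm: float) -> "TriMesh":
        """Split triangles until no edge exceeds ``max_edge_mm``.

        Longest-edge midpoint bisection; the surface is geometrically
        identical (useful to tighten per-triangle bounds in proximity
        queries), though shared edges are not kept conforming.
        """
        verts = self.vertices
        tris = self.triangles
        while True:
            tc = verts[tris]
            e = np.stack(
                [
                    np.linalg.norm(tc[:, 1] - tc[:, 0], axis=1),
                    np.linalg.norm(tc[:, 2] - tc[:, 1], axis=1),
                    np.linalg.norm(tc[:, 0] - tc[:, 2], axis=1),
                ],
                axis=1,
            )
            longest = e.argmax(axis=1)
            split = e.max(axis=1) > max_edge_mm
            if not split.any():
                break
            keep = tris[~split]
            st = tris[split]
            le = longest[split]
            i0 = st[np.arange(len(st)), le]
            i1 = st[np.arange(len(st)), (le + 1) % 3]
            i2 = st[np.arange(len(st)), (le + 2) % 3]
            mid = 0.5 * (verts[i0] + verts[i1])
            mi = len(verts) + np.arange(len(st))
            verts = np.vstack([verts, mid])
            new = np.vstack(
                [
                    np.column_stack([i0, mi, i2]),
                    np.column_stack([mi, i1, i2]),
                ]
            )
            tris = np.vstack([keep, new])
        return TriMesh(verts, tris, self.frame)

    # ------------------------------------------------------------------- ops
    @classmethod
    def concatenate(cls, meshes, frame: str | None = None) -> "TriMesh":
        meshes = list(meshes)
        if not meshes:
            raise ValueError("cannot concatenate zero meshes")
        verts, tris, off = [], [], 0
        for m in meshes:
            verts.append(m.vertices)
            tris.append(m.triangles + off)
            off += m.n_vertices
        return cls(np.vstack(verts), np.vstack(tris), frame or meshes[0].frame)

    def to_trimesh(self):
        """Convert to a :class:`trimesh.Trimesh` (no processing/merging)."""
        import trimesh

        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.triangles, process=False
        )

    def export(self, path) -> None:
        """Write the mesh to ``path``; format from the extension (.stl/.obj/.ply)."""
        self.to_trimesh().export(str(path))

    @classmethod
    def load(cls, path, frame: str = "component") -> "TriMesh":
        import trimesh

        tm = trimesh.load_mesh(str(path), process=False)
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), frame)
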
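"""Margin-aware mesh proximity engine and configuration-space sweeps.

A configuration *collides* when the surface clearance of any monitored
component pair is less than or equal to that pair's safety margin (the 3-cm
safety zone by default; the touch guard, being itself a physical buffer, is
checked at margin zero).  The boundary case counts as a collision —
patient-safety conservative.

Distances are exact surface-to-surface minimum distances.  The accelerated
query works best-first: a vertex k-d-tree upper bound, tightened on the
nearest-feature neighborhood, then branch-and-bound over candidate triangle
pairs ordered by axis-aligned-box lower bounds, with the exact triangle-pair
kernel on the survivors.  It therefore matches the exhaustive brute-force
oracle to floating-point accuracy while evaluating only the contact region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ._gjk import gjk_distance
from ._tridist import tri_tri_distance
from .errors import RTClearError
from .kinematics import (
    MachineState,
    RigidTransform,
    couch_transform,
    gantry_transform,
    normalize_angle_deg,
)
from .machine import (
    MachineSpec,
    SceneMesh,
    build_component_meshes,
    build_primitive_mesh,
)
from .mesh import TriMesh

__all__ = [
    "CollisionResult",
    "CollisionMap",
    "CollisionChecker",
    "min_distance",
    "collides",
    "sweep_map",
    "boundary_gantry_angles",
    "trajectory_events",
    "TriggerEvent",
    "paper_grid_couch_angles",
    "paper_grid_gantry_angles",
]

_CHUNK = 1024  # triangle pairs per exact-kernel batch (best-first chunks)
#: proximity structures split triangles to this edge length — the surface is
#: unchanged, but per-triangle bounds (hence pruning) get much tighter
_PROX_MAX_EDGE_MM = 60.0
#: sweep evaluations refine triangle-mesh clearances exactly up to this
#: value; far beyond any safety margin the vertex-sampled upper bound is
#: reported instead (collision flags and near-margin clearances are exact)
CLEARANCE_EXACT_CAP_MM = 150.0


# --------------------------------------------------------------------------
# proximity primitives
# --------------------------------------------------------------------------

class _Prox:
    """Precomputed acceleration structure for one mesh in its local frame."""

    def __init__(self, mesh: TriMesh, max_edge_mm: float = _PROX_MAX_EDGE_MM):
        if mesh.n_triangles == 0:
            raise RTClearError("empty mesh in proximity query")
        self.mesh = mesh  # original, exported for oracle comparisons
        work = mesh.subdivided(max_edge_mm)
        self.verts = work.vertices
        self.tris = work.triangles
        self.corners = work.triangle_corners()  # (M, 3, 3)
        self.centroids = self.corners.mean(axis=1)
        self.radii = np.linalg.norm(
            self.corners - self.centroids[:, None, :], axis=2
        ).max(axis=1)
        self.rmax = float(self.radii.max())
        self.vert_tree = cKDTree(self.verts)
        self.cent_tree = cKDTree(self.centroids)
        self.tri_lo = self.corners.min(axis=1)
        self.tri_hi = self.corners.max(axis=1)
        # vertex -> incident-triangle adjacency (CSR-style)
        flat = self.tris.ravel()
        order = np.argsort(flat, kind="stable")
        self._adj_tris = order // 3
        self._adj_starts = np.searchsorted(
            flat[order], np.arange(len(self.verts) + 1)
        )
        lo, hi = self.verts.min(axis=0), self.verts.max(axis=0)
        self.box_corners = np.array(
            [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])]
        )
        self.lo, self.hi = lo, hi
        self.center = 0.5 * (lo + hi)
        self.bradius = float(np.linalg.norm(self.verts - self.center, axis=1).max())

    def incident_tris(self, vertex_ids: np.ndarray) -> list:
        """Per vertex id, the array of triangle ids touching it."""
        parts = [
            self._adj_tris[self._adj_starts[v] : self._adj_starts[v + 1]]
            for v in np.atleast_1d(vertex_ids)
        ]
        return parts


def _box_gap(lo_a, hi_a, lo_b, hi_b) -> np.ndarray:
    """Distance between axis-aligned boxes, batched over the leading axis."""
    gap = np.maximum(0.0, np.maximum(lo_a - hi_b, lo_b - hi_a))
    return np.linalg.norm(gap, axis=-1)


def _pair_min_distance(
    a: _Prox,
    b: _Prox,
    rel: RigidTransform,
    upper_only_below: float | None = None,
    approx_above: float | None = None,
) -> float:
    """Min distance between A and B placed by ``rel`` in A's frame.

    Exact by default.  If ``upper_only_below`` is set, any proven upper bound
    at or below it is returned immediately (boolean collision tests), and
    refinement stops as soon as no remaining pair could reach it.  If
    ``approx_above`` is set, distances certified to exceed it are returned as
    the (vertex-sampled) upper bound without exhaustive refinement — the
    result is then exact whenever it is at or below ``approx_above``.
    """
    R, t = rel.rotation, rel.translation
    bv = b.verts @ R.T + t
    # query B vertices in ascending order of their distance lower bound to
    # A's bounding box; stop as soon as the bound exceeds the best distance
    boxd = np.linalg.norm(
        np.maximum(0.0, np.maximum(a.lo - bv, bv - a.hi)), axis=1
    )
    vorder = np.argsort(boxd)
    dall = boxd.copy()  # lower bound, replaced by true distance once queried
    queried: list[np.ndarray] = []
    d0 = np.inf
    for s in range(0, len(vorder), 1024):
        idx = vorder[s : s + 1024]
        if boxd[idx[0]] >= d0:
            break
        dq, _ = a.vert_tree.query(bv[idx], k=1)
        dall[idx] = dq
        queried.append(idx)
        d0 = min(d0, float(dq.min()))
        if upper_only_below is not None and d0 <= upper_only_below:
            return d0
    if d0 == 0.0:
        return 0.0
    qidx = np.concatenate(queried)
    dists = dall  # mixed: exact for queried vertices, lower bound otherwise

    # tighten the upper bound around the closest vertices: exact distances
    # between each near B vertex's incident triangles and its nearest A
    # triangles (finds deep interpenetrations immediately via the pierce test)
    m = min(24, len(qidx))
    vs = qidx[np.argpartition(dists[qidx], m - 1)[:m]] if len(qidx) > m else qidx
    k = min(4, len(a.centroids))
    _, atri_near = a.cent_tree.query(bv[vs], k=k)
    atri_near = np.atleast_2d(atri_near)
    seed_a, seed_b = [], []
    for row, bt in enumerate(b.incident_tris(vs)):
        at = atri_near[row]
        seed_a.append(np.repeat(at, len(bt)))
        seed_b.append(np.tile(bt, len(at)))
    ia0 = np.concatenate(seed_a)
    ib0 = np.concatenate(seed_b)
    bc0 = b.corners[ib0] @ R.T + t
    u = min(d0, float(tri_tri_distance(a.corners[ia0], bc0).min()))
    if upper_only_below is not None and u <= upper_only_below:
        return u
    if u == 0.0:
        return 0.0

    # refinement target: pairs are interesting only while they could push
    # the distance below tcap (the current bound, the boolean threshold, or
    # the exactness cap — whichever applies and is smallest)
    tcap = u
    if approx_above is not None:
        tcap = min(tcap, approx_above)
    if upper_only_below is not None:
        tcap = min(tcap, upper_only_below)

    # B triangles that could beat tcap, from per-vertex distances
    tri_vdist = dists[b.tris].min(axis=1)
    keep_j = np.nonzero(tri_vdist - b.radii - a.rmax < tcap)[0]
    if not len(keep_j):
        return u
    bcent = b.centroids[keep_j] @ R.T + t
    btree = cKDTree(bcent)
    cand = a.cent_tree.sparse_distance_matrix(
        btree, tcap + a.rmax + float(b.radii[keep_j].max()), output_type="ndarray"
    )
    if not len(cand):
        return u
    ia = cand["i"]
    ib = keep_j[cand["j"]]
    # cheap sphere filter before touching any corner coordinates
    keep = cand["v"] - a.radii[ia] - b.radii[ib] < tcap
    ia, ib = ia[keep], ib[keep]
    if not len(ia):
        return u

    # tight per-pair lower bounds from axis-aligned boxes in A's frame
    bcorn = b.corners[ib] @ R.T + t
    lb = _box_gap(a.tri_lo[ia], a.tri_hi[ia], bcorn.min(axis=1), bcorn.max(axis=1))
    keep = lb < tcap
    ia, lb, bcorn = ia[keep], lb[keep], bcorn[keep]
    order = np.argsort(lb)
    ia, lb, bcorn = ia[order], lb[order], bcorn[order]

    best = u
    for s in range(0, len(ia), _CHUNK):
        cutoff = min(best, tcap)
        if lb[s] >= cutoff:  # no remaining pair can matter
            break
        sl = slice(s, s + _CHUNK)
        pierce = lb[sl] <= 0.0  # only overlapping boxes can intersect
        d = tri_tri_distance(a.corners[ia[sl]], bcorn[sl], pierce_mask=pierce)
        best = min(best, float(d.min()))
        if best == 0.0 or (
            upper_only_below is not None and best <= upper_only_below
        ):
            return best
    return best


def min_distance(a: TriMesh, b: TriMesh) -> float:
    """Exact Euclidean minimum distance between two mesh surfaces (mm).

    Returns 0 when the surfaces intersect or touch.  Accelerated with
    best-first pruning; agrees with the exhaustive triangle-pair oracle.
    """
    if a.n_triangles == 0 or b.n_triangles == 0:
        raise RTClearError("min_distance requires two non-empty meshes")
    return _pair_min_distance(_Prox(a), _Prox(b), RigidTransform.identity())


# --------------------------------------------------------------------------
# collision results
# --------------------------------------------------------------------------

@dataclass
class PairClearance:
    label_a: str
    label_b: str
    clearance_mm: float
    margin_mm: float

    @property
    def colliding(self) -> bool:
        return self.clearance_mm <= self.margin_mm


@dataclass
class CollisionResult:
    colliding: bool
    per_pair: list[PairClearance]
    min_clearance_mm: float


def _monitored_pairs(scene: list[SceneMesh], spec: MachineSpec):
    pair_set = {frozenset(p) for p in spec.collision_pairs}
    for ga, gb in spec.collision_pairs:
        for g in (ga, gb):
            if g != "patient" and not any(m.group == g for m in scene):
                raise RTClearError(f"collision pair references missing group {g!r}")
    out = []
    for i, ma in enumerate(scene):
        for mb in scene[i + 1 :]:
            if frozenset((ma.group, mb.group)) in pair_set:
                out.append((ma, mb, spec.pair_margin_mm(ma.label, mb.label)))
    return out


def collides(scene: list[SceneMesh], spec: MachineSpec) -> CollisionResult:
    """Evaluate every monitored pair of an assembled scene exactly."""
    monitored = _monitored_pairs(scene, spec)
    if not monitored:
        raise RTClearError("scene has no monitored collision pair")
    out = []
    for ma, mb, margin in monitored:
        d = min_distance(ma.mesh, mb.mesh)
        out.append(PairClearance(ma.label, mb.label, d, margin))
    return CollisionResult(
        colliding=any(p.colliding for p in out),
        per_pair=out,
        min_clearance_mm=min(p.clearance_mm for p in out),
    )


# --------------------------------------------------------------------------
# sweep engine
# --------------------------------------------------------------------------

@dataclass
class _CheckerPair:
    a_label: str
    b_label: str
    a_group: str
    b_group: str
    margin_mm: float
    from_override: bool


class CollisionChecker:
    """Cached scene evaluator for configuration-space sweeps.

    Component meshes are built once (optionally at an overridden tessellation)
    and kept in their local frames; each state evaluation transforms only the
    moving side of each monitored pair into the other's frame, so sweeps
    reuse every acceleration structure.  Pairs whose bounding boxes stay
    farther apart than anything that could matter are skipped outright.

    Machine components are convex primitives, so machine-machine pair
    distances use GJK on the primitive polytopes (exact for disjoint convex
    solids, 0 on contact/overlap); pairs involving the patient mesh — the
    only non-convex collider — use the triangle-mesh engine.
    """

    def __init__(
        self,
        spec: MachineSpec,
        patient=None,
        couch_top_mm: float | None = None,
        machine_segments: int | None = None,
    ):
        self.spec = spec
        meshes = build_component_meshes(spec, machine_segments)
        self._groups = {c.label: c.group for c in spec.components}
        if patient is not None:
            if hasattr(patient, "mesh"):  # PlacedPatient
                if couch_top_mm is None:
                    couch_top_mm = patient.couch_top_mm
                patient = patient.mesh
            meshes["patient"] = patient
            self._groups["patient"] = "patient"
        if couch_top_mm is None:
            couch_top_mm = spec.plate_top_zero_mm
        self.couch_top_mm = float(couch_top_mm)

        pair_set = {frozenset(p) for p in spec.collision_pairs}
        self.pairs: list[_CheckerPair] = []
        labels = list(meshes)
        for i, la in enumerate(labels):
            for lb in labels[i + 1 :]:
                if frozenset((self._groups[la], self._groups[lb])) in pair_set:
                    override = la in spec.margin_overrides or lb in spec.margin_overrides
                    self.pairs.append(
                        _CheckerPair(
                            la,
                            lb,
                            self._groups[la],
                            self._groups[lb],
                            spec.pair_margin_mm(la, lb),
                            override,
                        )
                    )
        if not self.pairs:
            raise RTClearError("no monitored collision pair for this machine")
        monitored_labels = {p.a_label for p in self.pairs} | {
            p.b_label for p in self.pairs
        }
        self._meshes = {l: m for l, m in meshes.items() if l in monitored_labels}
        # convex primitive polytopes for the GJK fast path
        self._polys: dict[str, list[np.ndarray]] = {}
        for comp in spec.components:
            if comp.label in monitored_labels:
                self._polys[comp.label] = [
                    build_primitive_mesh(p, machine_segments).vertices
                    for p in comp.primitives
                ]
        # triangle-engine structures only for labels that meet a non-convex
        # collider; machine components facing the finely faceted patient get
        # finer subdivision, since tight per-triangle bounds matter there
        mesh_path_labels = set()
        for p in self.pairs:
            if p.a_label not in self._polys or p.b_label not in self._polys:
                mesh_path_labels.update((p.a_label, p.b_label))
        self._prox = {
            label: _Prox(
                self._meshes[label], 25.0 if label != "patient" else _PROX_MAX_EDGE_MM
            )
            for label in mesh_path_labels
        }
        # cheap per-label bounding boxes for pair-level gating
        self._boxes = {}
        for label, m in self._meshes.items():
            lo, hi = m.vertices.min(axis=0), m.vertices.max(axis=0)
            corners = np.array(
                [
                    [x, y, z]
                    for x in (lo[0], hi[0])
                    for y in (lo[1], hi[1])
                    for z in (lo[2], hi[2])
                ]
            )
            self._boxes[label] = corners

    # -- transforms ---------------------------------------------------------
    def _group_transform(self, group: str, state: MachineState) -> RigidTransform:
        if group == "gantry_rotating":
            return gantry_transform(state.gantry_angle_deg)
        if group in ("couch_translating", "patient"):
            shift = np.asarray(state.couch_shift_mm) + np.array(
                [0.0, 0.0, self.couch_top_mm]
            )
            return couch_transform(state.couch_angle_deg, shift)
        if group == "couch_rotating":
            return couch_transform(state.couch_angle_deg)
        return RigidTransform.identity()

    def _state_transforms(self, state: MachineState) -> dict:
        groups = {p.a_group for p in self.pairs} | {p.b_group for p in self.pairs}
        return {g: self._group_transform(g, state) for g in groups}

    def _pair_rel(self, pair: _CheckerPair, transforms: dict) -> RigidTransform:
        ta = transforms[pair.a_group]
        tb = transforms[pair.b_group]
        return ta.inverse() @ tb  # B's local frame -> A's local frame

    def _pair_lower(self, pair: _CheckerPair, rel: RigidTransform) -> float:
        """Cheap lower bound: box gap between A's AABB and transformed B's."""
        ca = self._boxes[pair.a_label]
        bc = rel.apply(self._boxes[pair.b_label])
        return float(
            _box_gap(ca.min(axis=0), ca.max(axis=0), bc.min(axis=0), bc.max(axis=0))
        )

    def _exact_pair(
        self,
        pair: _CheckerPair,
        rel: RigidTransform,
        bool_below: float | None = None,
        approx_above: float | None = None,
    ) -> float:
        pa = self._polys.get(pair.a_label)
        pb = self._polys.get(pair.b_label)
        if pa is not None and pb is not None:  # convex-convex fast path
            best = np.inf
            for va in pa:
                for vb in pb:
                    best = min(
                        best, gjk_distance(va, vb, rel.rotation, rel.translation)
                    )
                    if bool_below is not None and best <= bool_below:
                        return best
            return best
        a = self._prox[pair.a_label]
        b = self._prox[pair.b_label]
        if len(b.verts) > len(a.verts):  # query the smaller vertex set
            a, b, rel = b, a, rel.inverse()
        return _pair_min_distance(a, b, rel, bool_below, approx_above)

    def pair_distance(
        self,
        pair: _CheckerPair,
        state: MachineState | None,
        bool_below: float | None = None,
        transforms: dict | None = None,
    ) -> float:
        tf = transforms if transforms is not None else self._state_transforms(state)
        rel = self._pair_rel(pair, tf)
        if bool_below is not None:
            lower = self._pair_lower(pair, rel)
            if lower > bool_below:
                return lower
        return self._exact_pair(pair, rel, bool_below)

    # -- state evaluation ---------------------------------------------------
    def evaluate(self, state: MachineState):
        """Exact per-category minima at one state.

        Returns ``(colliding, min_all, min_default, override_excess)`` where
        ``min_default`` is the minimum clearance over pairs carrying the
        machine default margin and ``override_excess`` the minimum of
        (clearance - margin) over pairs with a component margin override; the
        split lets a map be re-thresholded at any default margin up to
        ``CLEARANCE_EXACT_CAP_MM``.  Pairs that provably cannot affect any of
        the minima or the flag are skipped, and triangle-mesh clearances
        beyond the cap are vertex-sampled upper bounds rather than exact.
        """
        tf = self._state_transforms(state)
        rels = [self._pair_rel(p, tf) for p in self.pairs]
        lowers = [self._pair_lower(p, r) for p, r in zip(self.pairs, rels)]
        order = sorted(range(len(self.pairs)), key=lambda i: lowers[i])
        min_all = np.inf
        min_default = np.inf
        override_excess = np.inf
        colliding = False
        for i in order:
            pair = self.pairs[i]
            lower = lowers[i]
            needed = max(
                min_all,
                min_default if not pair.from_override else -np.inf,
                (override_excess + pair.margin_mm) if pair.from_override else -np.inf,
                pair.margin_mm,
            )
            if lower > needed:
                continue
            d = self._exact_pair(pair, rels[i], approx_above=CLEARANCE_EXACT_CAP_MM)
            min_all = min(min_all, d)
            if pair.from_override:
                override_excess = min(override_excess, d - pair.margin_mm)
            else:
                min_default = min(min_default, d)
            if d <= pair.margin_mm:
                colliding = True
        return colliding, min_all, min_default, override_excess

    def is_colliding(self, state: MachineState) -> bool:
        """Boolean collision test with early exit (used by boundary sweeps)."""
        tf = self._state_transforms(state)
        items = []
        for p in self.pairs:
            rel = self._pair_rel(p, tf)
            items.append((self._pair_lower(p, rel), p, rel))
        items.sort(key=lambda it: it[0] - it[1].margin_mm)
        for lower, pair, rel in items:
            if lower > pair.margin_mm:
                continue
            if self._exact_pair(pair, rel, pair.margin_mm) <= pair.margin_mm:
                return True
        return False

    def result(self, state: MachineState) -> CollisionResult:
        """Full per-pair report at one state (all pairs exact)."""
        tf = self._state_transforms(state)
        out = [
            PairClearance(
                p.a_label,
                p.b_label,
                self.pair_distance(p, state, transforms=tf),
                p.margin_mm,
            )
            for p in self.pairs
        ]
        return CollisionResult(
            any(p.colliding for p in out), out, min(p.clearance_mm for p in out)
        )


# --------------------------------------------------------------------------
# collision maps
# --------------------------------------------------------------------------

@dataclass
class CollisionMap:
    """Collision predictions over couch angle x gantry angle x couch position."""

    machine: str
    couch_angles_deg: np.ndarray
    gantry_angles_deg: np.ndarray
    positions_mm: np.ndarray  # (P, 3) couch shift triples
    colliding: np.ndarray  # (C, G, P) bool
    min_clearance_mm: np.ndarray  # (C, G, P)
    default_min_mm: np.ndarray  # clearance min over default-margin pairs
    override_excess_mm: np.ndarray  # min (clearance - margin) over override pairs
    default_margin_mm: float

    @property
    def n_cells(self) -> int:
        return int(self.colliding.size)

    def colliding_at_margin(self, margin_mm: float) -> np.ndarray:
        """Re-threshold the map at a different default safety margin.

        Component-override margins (the touch guard's zero) stay fixed.
        """
        return (self.override_excess_mm <= 0.0) | (self.default_min_mm <= margin_mm)

    def to_heatmap(self, path, position_index: int = 0) -> None:
        """Render one couch position as a couch-angle x gantry-angle heatmap.

        Colliding cells are drawn dark on a clearance colormap; requires
        matplotlib.
        """
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        clear = np.clip(self.min_clearance_mm[:, :, position_index], 0.0, 300.0)
        col = self.colliding[:, :, position_index]
        fig, ax = plt.subplots(figsize=(9, 5))
        shown = np.where(col, np.nan, clear)
        im = ax.imshow(shown, aspect="auto", cmap="viridis", origin="lower")
        ax.imshow(
            np.where(col, 1.0, np.nan),
            aspect="auto",
            cmap="Reds_r",
            vmin=0,
            vmax=1,
            origin="lower",
        )
        ax.set_xticks(range(0, len(self.gantry_angles_deg), 3))
        ax.set_xticklabels(
            [f"{a:g}" for a in self.gantry_angles_deg[::3]], rotation=90
        )
        ax.set_yticks(range(len(self.couch_angles_deg)))
        ax.set_yticklabels([f"{a:g}" for a in self.couch_angles_deg])
        ax.set_xlabel("gantry angle (deg)")
        ax.set_ylabel("couch angle (deg)")
        pos = self.positions_mm[position_index]
        ax.set_title(
            f"{self.machine}: red = collision (margin {self.default_margin_mm:g} mm), "
            f"shift ({pos[0]:g}, {pos[1]:g}, {pos[2]:g}) mm"
        )
        fig.colorbar(im, ax=ax, label="min clearance (mm)")
        fig.tight_layout()
        fig.savefig(path, dpi=110)
        plt.close(fig)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "machine,couch_deg,gantry_deg,shift_x_mm,shift_y_mm,shift_z_mm,"
                "colliding,min_clearance_mm\n"
            )
            for i, ca in enumerate(self.couch_angles_deg):
                for j, ga in enumerate(self.gantry_angles_deg):
                    for k, pos in enumerate(self.positions_mm):
                        fh.write(
                            f"{self.machine},{ca:g},{ga:g},"
                            f"{pos[0]:g},{pos[1]:g},{pos[2]:g},"
                            f"{int(self.colliding[i, j, k])},"
                            f"{self.min_clearance_mm[i, j, k]:.6f}\n"
                        )


def paper_grid_couch_angles() -> np.ndarray:
    """Couch angles 0-90 and 270-350 in 10-degree steps (19 values)."""
    return np.concatenate([np.arange(0, 91, 10), np.arange(270, 351, 10)]).astype(float)


def paper_grid_gantry_angles() -> np.ndarray:
    """Gantry angles 0-350 in 10-degree steps (36 values)."""
    return np.arange(0, 351, 10).astype(float)


def sweep_map(
    spec: MachineSpec,
    patient=None,
    couch_angles_deg=None,
    gantry_angles_deg=None,
    positions_mm=None,
    couch_top_mm: float | None = None,
    machine_segments: int | None = None,
    checker: CollisionChecker | None = None,
) -> CollisionMap:
    """Evaluate the collision map over a configuration grid.

    Cells are mutually independent, deterministic ``collides`` evaluations;
    the result does not depend on evaluation order.
    """
    couch_angles = np.asarray(
        paper_grid_couch_angles() if couch_angles_deg is None else couch_angles_deg,
        dtype=float,
    )
    gantry_angles = np.asarray(
        paper_grid_gantry_angles() if gantry_angles_deg is None else gantry_angles_deg,
        dtype=float,
    )
    if positions_mm is None:
        positions_mm = [(0.0, 0.0, 0.0)]
    positions = np.asarray(positions_mm, dtype=float).reshape(-1, 3)
    if couch_angles.size == 0 or gantry_angles.size == 0 or positions.size == 0:
        raise RTClearError("sweep grids must be nonempty")

    if checker is None:
        checker = CollisionChecker(
            spec, patient, couch_top_mm, machine_segments=machine_segments
        )
    shape = (len(couch_angles), len(gantry_angles), len(positions))
    colliding = np.zeros(shape, dtype=bool)
    min_clear = np.full(shape, np.inf)
    dmin = np.full(shape, np.inf)
    oexc = np.full(shape, np.inf)
    for i, ca in enumerate(couch_angles):
        for k, pos in enumerate(positions):
            for j, ga in enumerate(gantry_angles):
                state = MachineState(ga, ca, tuple(pos))
                c, mall, mdef, mexc = checker.evaluate(state)
                colliding[i, j, k] = c
                min_clear[i, j, k] = mall
                dmin[i, j, k] = mdef
                oexc[i, j, k] = mexc
    return CollisionMap(
        machine=spec.name,
        couch_angles_deg=couch_angles,
        gantry_angles_deg=gantry_angles,
        positions_mm=positions,
        colliding=colliding,
        min_clearance_mm=min_clear,
        default_min_mm=dmin,
        override_excess_mm=oexc,
        default_margin_mm=spec.default_margin_mm,
    )


# --------------------------------------------------------------------------
# boundary angles and trigger events
# --------------------------------------------------------------------------

def boundary_gantry_angles(
    checker: CollisionChecker,
    couch_angle_deg: float,
    position_mm=(0.0, 0.0, 0.0),
    direction: str = "ccw",
    step_deg: float = 10.0,
) -> float | None:
    """First colliding gantry rotation from 0 deg in the given direction.

    Returns the rotation magnitude (deg, quantized to ``step_deg``) of the
    first colliding sample, or None when the full rotation is clear.  ``ccw``
    steps through increasing gantry angles, ``cw`` through decreasing.
    """
    if step_deg <= 0:
        raise RTClearError("step_deg must be > 0")
    if direction not in ("cw", "ccw"):
        raise RTClearError("direction must be 'cw' or 'ccw'")
    sign = 1.0 if direction == "ccw" else -1.0
    n = int(np.floor(360.0 / step_deg))
    for k in range(n + 1):
        rot = k * step_deg
        if rot >= 360.0:
            break
        state = MachineState(
            normalize_angle_deg(sign * rot), couch_angle_deg, tuple(position_mm)
        )
        if checker.is_colliding(state):
            return rot
    return None


@dataclass(frozen=True)
class TriggerEvent:
    kind: str  # enter | stay | exit
    index: int  # sample index along the path
    pair: tuple[str, str]


def trajectory_events(
    checker: CollisionChecker,
    couch_angle_deg: float,
    position_mm,
    gantry_path_deg,
) -> list[TriggerEvent]:
    """Trigger-style event stream along an ordered gantry path.

    For each monitored pair: ``enter`` on a clear->colliding transition (or a
    colliding first sample), ``stay`` while colliding persists, ``exit`` on
    colliding->clear.  Events are ordered by path index.
    """
    path = list(gantry_path_deg)
    if len(path) < 2:
        raise RTClearError("gantry path needs >= 2 samples")
    prev = {(p.a_label, p.b_label): False for p in checker.pairs}
    events: list[TriggerEvent] = []
    for idx, ga in enumerate(path):
        state = MachineState(ga, couch_angle_deg, tuple(position_mm))
        tf = checker._state_transforms(state)
        for p in checker.pairs:
            key = (p.a_label, p.b_label)
            d = checker.pair_distance(p, state, bool_below=p.margin_mm, transforms=tf)
            hit = d <= p.margin_mm
            if hit and not prev[key]:
                events.append(TriggerEvent("enter", idx, key))
            elif hit and prev[key]:
                events.append(TriggerEvent("stay", idx, key))
            elif not hit and prev[key]:
                events.append(TriggerEvent("exit", idx, key))
            prev[key] = hit
    return events
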
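"""Triangulated-surface primitives for cortical and scalp geometry.

All coordinates live in a common head frame and are expressed in
millimetres.  A :class:`TriangleMesh` is a closed, consistently outward
oriented 2-manifold; a :class:`VertexPatch` is an edge-connected set of
mesh vertices (here: a candidate lesion) with derived centre-of-mass and
boundary information.

The mesh machinery intentionally stays light: construction and normals
are delegated to :mod:`trimesh`, graph geodesics to
:mod:`scipy.sparse.csgraph`.  Decimation is a heap-based quadric
edge-collapse with manifold (link-condition) and normal-flip guards.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import ConvexHull, cKDTree

__all__ = [
    "TriangleMesh",
    "VertexPatch",
    "make_icosphere",
    "merge_meshes",
    "decimate",
    "geodesic_disk",
    "patch_summary",
    "k_nearest_vertices",
]


@dataclass(frozen=True)
class TriangleMesh:
    """Closed triangulated surface in head coordinates (mm)."""

    vertices: np.ndarray  # (n, 3) float64, mm
    faces: np.ndarray  # (m, 3) int

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        object.__setattr__(self, "_cache", {})

    # -- cached derived quantities -------------------------------------
    def _get(self, key, fn):
        cache = self.__dict__["_cache"]
        if key not in cache:
            cache[key] = fn()
        return cache[key]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def as_trimesh(self) -> trimesh.Trimesh:
        return self._get(
            "tm", lambda: trimesh.Trimesh(self.vertices, self.faces, process=False)
        )

    @property
    def vertex_normals(self) -> np.ndarray:
        """Per-vertex outward unit normals (area-weighted face average)."""

        def _compute():
            n = np.array(self.as_trimesh().vertex_normals, dtype=np.float64)
            return n / np.linalg.norm(n, axis=1, keepdims=True)

        return self._get("vnorm", _compute)

    @property
    def face_areas(self) -> np.ndarray:
        return self._get(
            "farea", lambda: np.array(self.as_trimesh().area_faces, dtype=np.float64)
        )

    @property
    def vertex_areas(self) -> np.ndarray:
        """Per-vertex area share: one third of incident face areas (mm^2)."""

        def _compute():
            out = np.zeros(self.n_vertices)
            np.add.at(out, self.faces.ravel(), np.repeat(self.face_areas / 3.0, 3))
            return out

        return self._get("varea", _compute)

    @property
    def total_area(self) -> float:
        return float(self.face_areas.sum())

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges, sorted pairs (e, 2)."""

        def _compute():
            e = np.vstack(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
            )
            e = np.sort(e, axis=1)
            return np.unique(e, axis=0)

        return self._get("edges", _compute)

    def adjacency(self, weighted: bool = True):
        """Sparse vertex adjacency; weights are Euclidean edge lengths (mm)."""

        def _compute():
            e = self.edges
            w = (
                np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
                if weighted
                else np.ones(len(e))
            )
            n = self.n_vertices
            a = coo_matrix(
                (np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
                shape=(n, n),
            )
            return a.tocsr()

        return self._get(("adj", weighted), _compute)

    def kdtree(self) -> cKDTree:
        return self._get("kdtree", lambda: cKDTree(self.vertices))

    # -- invariants ----------------------------------------------------
    def is_closed(self) -> bool:
        """Every undirected edge is shared by exactly two faces."""
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def is_oriented(self) -> bool:
        """Each directed edge appears exactly once (consistent winding)."""
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 1))

    def euler_characteristics(self) -> list:
        """Euler characteristic of each connected component (2 for spheres)."""
        ncomp, labels = connected_components(self.adjacency(False), directed=False)
        chis = []
        for c in range(ncomp):
            vmask = labels == c
            nv = int(vmask.sum())
            fmask = vmask[self.faces[:, 0]]
            nf = int(fmask.sum())
            fe = self.faces[fmask]
            e = np.sort(
                np.vstack([fe[:, [0, 1]], fe[:, [1, 2]], fe[:, [2, 0]]]), axis=1
            )
            ne = len(np.unique(e, axis=0))
            chis.append(nv - ne + nf)
        return chis


@dataclass(frozen=True)
class VertexPatch:
    """Edge-connected vertex set on a mesh (a candidate lesion)."""

    mesh: TriangleMesh
    indices: np.ndarray  # sorted unique vertex indices
    label: str = ""

    def __post_init__(self):
        idx = np.unique(np.asarray(self.indices, dtype=np.int64))
        if idx.size == 0:
            raise ValueError("patch must be non-empty")
        if idx.min() < 0 or idx.max() >= self.mesh.n_vertices:
            raise IndexError("patch indices out of range")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def mean_position(self) -> np.ndarray:
        """Arithmetic mean of member vertex coordinates (mm)."""
        return self.mesh.vertices[self.indices].mean(axis=0)

    @property
    def com_vertex(self) -> int:
        """Member vertex nearest the mean position (the lesion 'COM vertex').

        Restricted to patch members so that a dipole placed there always
        lies on the source space.
        """
        pos = self.mesh.vertices[self.indices]
        d = np.linalg.norm(pos - self.mean_position, axis=1)
        return int(self.indices[np.argmin(d)])

    @property
    def boundary_vertices(self) -> np.ndarray:
        """Members with at least one mesh neighbour outside the patch."""
        member = np.zeros(self.mesh.n_vertices, dtype=bool)
        member[self.indices] = True
        e = self.mesh.edges
        out = np.zeros(self.mesh.n_vertices, dtype=bool)
        a, b = e[:, 0], e[:, 1]
        out[a[member[a] & ~member[b]]] = True
        out[b[member[b] & ~member[a]]] = True
        return np.flatnonzero(out)

    @property
    def area(self) -> float:
        """Sum of member vertex area shares (mm^2)."""
        return float(self.mesh.vertex_areas[self.indices].sum())

    def hull_volume_cm3(self) -> float:
        """Convex-hull volume of the member coordinates, in cm^3."""
        pts = self.mesh.vertices[self.indices]
        if len(pts) < 4 or np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 3:
            return 0.0
        return float(ConvexHull(pts).volume) / 1000.0

    def is_connected(self) -> bool:
        sub = self.mesh.adjacency(False)[np.ix_(self.indices, self.indices)]
        ncomp, _ = connected_components(sub, directed=False)
        return ncomp == 1


# ---------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------


def make_icosphere(order: int, radius: float = 1.0) -> TriangleMesh:
    """Recursively subdivided icosahedron projected onto a sphere.

    Vertex count is exactly ``10 * 4**order + 2``.
    """
    if order < 0 or order > 8:
        raise ValueError("order must be in [0, 8]")
    if radius <= 0:
        raise ValueError("radius must be positive")
    tm = trimesh.creation.icosphere(subdivisions=order, radius=1.0)
    v = np.asarray(tm.vertices, dtype=np.float64)
    v = radius * v / np.linalg.norm(v, axis=1, keepdims=True)
    return TriangleMesh(v, np.asarray(tm.faces))


def merge_meshes(a: TriangleMesh, b: TriangleMesh) -> TriangleMesh:
    """Concatenate two meshes into one multi-component container."""
    return TriangleMesh(
        np.vstack([a.vertices, b.vertices]),
        np.vstack([a.faces, b.faces + a.n_vertices]),
    )


# ---------------------------------------------------------------------
# quadric edge-collapse decimation
# ---------------------------------------------------------------------


def _face_quadric(p0, p1, p2):
    n = np.cross(p1 - p0, p2 - p0)
    norm = np.linalg.norm(n)
    if norm < 1e-300:
        return np.zeros((4, 4))
    n = n / norm
    d = -np.dot(n, p0)
    plane = np.array([n[0], n[1], n[2], d])
    return np.outer(plane, plane) * norm  # area-weighted


def decimate(mesh: TriangleMesh, factor: float) -> TriangleMesh:
    """Reduce vertex count by ``factor`` with quadric edge collapse.

    The result stays a closed, consistently oriented 2-manifold; the
    vertex count lands within a few percent of ``n / factor`` (exact
    when no collapse is blocked by the manifold guards).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    n = mesh.n_vertices
    target = int(round(n / factor))
    if target < 4:
        raise ValueError("decimation target below 4 vertices")
    if factor == 1 or target >= n:
        return TriangleMesh(mesh.vertices.copy(), mesh.faces.copy())

    verts = [v.copy() for v in mesh.vertices]
    alive = np.ones(n, dtype=bool)
    # face store: list of tuples; face_alive flags; vertex->face ids
    faces = [tuple(f) for f in mesh.faces]
    f_alive = [True] * len(faces)
    vfaces = [set() for _ in range(n)]
    for fi, f in enumerate(faces):
        for vi in f:
            vfaces[vi].add(fi)
    neigh = [set() for _ in range(n)]
    for a, b in mesh.edges:
        neigh[a].add(int(b))
        neigh[b].add(int(a))

    quad = np.zeros((n, 4, 4))
    for f in faces:
        K = _face_quadric(verts[f[0]], verts[f[1]], verts[f[2]])
        for vi in f:
            quad[vi] += K

    stamp = np.zeros(n, dtype=np.int64)

    def edge_entry(a, b):
        Q = quad[a] + quad[b]
        A = Q[:3, :3]
        rhs = -Q[:3, 3]
        try:
            x = np.linalg.solve(A + 1e-9 * np.trace(A) / 3.0 * np.eye(3), rhs)
        except np.linalg.LinAlgError:
            x = 0.5 * (verts[a] + verts[b])
        # guard against wild optimal points
        mid = 0.5 * (verts[a] + verts[b])
        if np.linalg.norm(x - mid) > 2.0 * np.linalg.norm(verts[a] - verts[b]) + 1e-12:
            x = mid
        h = np.array([x[0], x[1], x[2], 1.0])
        cost = float(h @ Q @ h)
        return cost, x

    heap = []
    for a, b in mesh.edges:
        a, b = int(a), int(b)
        cost, x = edge_entry(a, b)
        heapq.heappush(heap, (cost, a, b, stamp[a] + stamp[b], x))

    nv = n

    def faces_of(v):
        return [fi for fi in vfaces[v] if f_alive[fi]]

    while nv > target and heap:
        cost, a, b, st, x = heapq.heappop(heap)
        if not (alive[a] and alive[b]) or b not in neigh[a]:
            continue
        if st != stamp[a] + stamp[b]:
            continue
        # link condition: shared neighbours must be exactly the two
        # opposite vertices of the two faces sharing edge (a, b)
        shared_faces = [fi for fi in vfaces[a] & vfaces[b] if f_alive[fi]]
        if len(shared_faces) != 2:
            continue
        opposite = set()
        for fi in shared_faces:
            for vi in faces[fi]:
                if vi != a and vi != b:
                    opposite.add(vi)
        if neigh[a] & neigh[b] != opposite or len(opposite) != 2:
            continue
        # normal-flip guard on surviving faces around a and b
        flip = False
        for v0 in (a, b):
            for fi in faces_of(v0):
                if fi in shared_faces:
                    continue
                f = faces[fi]
                p = [verts[vi] for vi in f]
                nold = np.cross(p[1] - p[0], p[2] - p[0])
                pnew = [x if vi in (a, b) else verts[vi] for vi in f]
                nnew = np.cross(pnew[1] - pnew[0], pnew[2] - pnew[0])
                if np.dot(nold, nnew) <= 0:
                    flip = True
                    break
            if flip:
                break
        if flip:
            continue

        # perform collapse b -> a, a moves to x
        verts[a] = x
        quad[a] = quad[a] + quad[b]
        for fi in shared_faces:
            f_alive[fi] = False
            for vi in faces[fi]:
                vfaces[vi].discard(fi)
        for fi in list(vfaces[b]):
            if not f_alive[fi]:
                vfaces[b].discard(fi)
                continue
            f = faces[fi]
            faces[fi] = tuple(a if vi == b else vi for vi in f)
            vfaces[a].add(fi)
            vfaces[b].discard(fi)
        for vn in list(neigh[b]):
            neigh[vn].discard(b)
            if vn != a:
                neigh[vn].add(a)
                neigh[a].add(vn)
        neigh[a].discard(b)
        neigh[a].discard(a)
        neigh[b] = set()
        alive[b] = False
        nv -= 1
        stamp[a] += 1
        for vn in neigh[a]:
            c2, x2 = edge_entry(*sorted((a, vn)))
            lo, hi = sorted((a, vn))
            heapq.heappush(heap, (c2, lo, hi, stamp[lo] + stamp[hi], x2))

    remap = -np.ones(n, dtype=np.int64)
    keep = np.flatnonzero(alive)
    remap[keep] = np.arange(len(keep))
    new_v = np.array([verts[i] for i in keep])
    new_f = np.array(
        [[remap[vi] for vi in faces[fi]] for fi in range(len(faces)) if f_alive[fi]],
        dtype=np.int64,
    )
    return TriangleMesh(new_v, new_f)


# ---------------------------------------------------------------------
# patches and queries
# ---------------------------------------------------------------------


def geodesic_disk(
    mesh: TriangleMesh, seed_vertex: int, target_area: float, label: str = ""
) -> VertexPatch:
    """Grow an edge-connected patch from ``seed_vertex`` by graph-geodesic
    distance until the cumulative vertex-area share reaches ``target_area``
    (mm^2)."""
    if seed_vertex < 0 or seed_vertex >= mesh.n_vertices:
        raise IndexError("seed vertex out of range")
    if target_area > mesh.total_area + 1e-9:
        raise ValueError("target_area exceeds total mesh area")
    dist = dijkstra(mesh.adjacency(True), directed=False, indices=seed_vertex)
    order = np.argsort(dist, kind="stable")
    cum = np.cumsum(mesh.vertex_areas[order])
    k = int(np.searchsorted(cum, target_area) + 1)
    k = min(k, mesh.n_vertices)
    chosen = order[:k]
    chosen = chosen[np.isfinite(dist[chosen])]  # stay on the seed's component
    return VertexPatch(mesh, chosen, label=label)


def patch_summary(patch: VertexPatch) -> dict:
    """Mean position, COM vertex, boundary set and hull volume of a patch."""
    return {
        "mean_position": patch.mean_position,
        "com_vertex": patch.com_vertex,
        "boundary_vertices": patch.boundary_vertices,
        "hull_volume_cm3": patch.hull_volume_cm3(),
    }


def k_nearest_vertices(mesh: TriangleMesh, point, k: int) -> VertexPatch:
    """The k mesh vertices nearest ``point`` (Euclidean, lowest-index ties)."""
    if k < 1 or k > mesh.n_vertices:
        raise ValueError("k must be in [1, n_vertices]")
    point = np.asarray(point, dtype=np.float64)
    d = np.linalg.norm(mesh.vertices - point, axis=1)
    idx = np.lexsort((np.arange(mesh.n_vertices), d))[:k]
    return VertexPatch(mesh, idx)
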
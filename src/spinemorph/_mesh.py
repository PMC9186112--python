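"""Lightweight triangle-mesh container and geometry kernels.

All heavier mesh machinery in this package (connected components, signed
volume, hole capping, ray casting) is built on numpy/scipy so the package
has no compiled-mesh-library dependency.  Coordinates are micrometers
everywhere downstream of loading.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc


class MeshError(ValueError):
    """Raised for structurally invalid meshes or mesh operations."""


@dataclass
class TriangleMesh:
    """Triangle surface mesh.

    vertices : (V, 3) float array, micrometers.
    faces    : (F, 3) int array of vertex indices.

    Possibly multiple connected components; components are defined over
    faces that share an edge.
    """

    vertices: np.ndarray
    faces: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.shape[0] == 0:
            raise MeshError("empty mesh: no faces")
        if not np.isfinite(self.vertices).all():
            raise MeshError("mesh has non-finite vertex coordinates")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise MeshError("face indices out of range")

    # ------------------------------------------------------------------ basic
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())

    def triangles(self) -> np.ndarray:
        """(F, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    def face_centroids(self) -> np.ndarray:
        return self.triangles().mean(axis=1)

    def face_normals(self, normalized: bool = True) -> np.ndarray:
        t = self.triangles()
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        if normalized:
            norm = np.linalg.norm(n, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            n = n / norm
        return n

    def face_areas(self) -> np.ndarray:
        t = self.triangles()
        return 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1
        )

    def area(self) -> float:
        return float(self.face_areas().sum())

    def signed_volume(self) -> float:
        """Divergence-theorem volume; positive for outward-oriented closed meshes."""
        t = self.triangles()
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def volume(self) -> float:
        return abs(self.signed_volume())

    # ------------------------------------------------------------ connectivity
    def _edge_tables(self):
        """Sorted (edge -> faces) incidence, cached."""
        if "edges" not in self._cache:
            f = self.faces
            e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
            e = np.sort(e, axis=1)
            face_of = np.tile(np.arange(self.n_faces), 3)
            keys = e[:, 0] * (self.n_vertices + 1) + e[:, 1]
            order = np.argsort(keys, kind="stable")
            self._cache["edges"] = (e[order], face_of[order], keys[order])
        return self._cache["edges"]

    def face_adjacency(self) -> np.ndarray:
        """(M, 2) pairs of faces sharing an edge (one row per shared edge pair)."""
        if "face_adjacency" not in self._cache:
            e, face_of, keys = self._edge_tables()
            pairs = []
            i = 0
            n = len(keys)
            while i < n:
                j = i + 1
                while j < n and keys[j] == keys[i]:
                    j += 1
                if j - i >= 2:
                    fs = face_of[i:j]
                    for a in range(len(fs)):
                        for b in range(a + 1, len(fs)):
                            pairs.append((fs[a], fs[b]))
                i = j
            adj = np.array(pairs, dtype=np.int64).reshape(-1, 2)
            self._cache["face_adjacency"] = adj
        return self._cache["face_adjacency"]

    def face_adjacency_edges(self) -> np.ndarray:
        """(M, 2) shared vertex-index edge for each face_adjacency row."""
        self.face_adjacency()
        if "face_adjacency_edges" not in self._cache:
            e, face_of, keys = self._edge_tables()
            out = []
            i = 0
            n = len(keys)
            while i < n:
                j = i + 1
                while j < n and keys[j] == keys[i]:
                    j += 1
                if j - i >= 2:
                    fs = face_of[i:j]
                    for a in range(len(fs)):
                        for b in range(a + 1, len(fs)):
                            out.append(e[i])
                i = j
            self._cache["face_adjacency_edges"] = np.array(out, dtype=np.int64).reshape(-1, 2)
        return self._cache["face_adjacency_edges"]

    def face_components(self) -> np.ndarray:
        """Per-face component label (faces connected via shared edges)."""
        if "face_components" not in self._cache:
            adj = self.face_adjacency()
            if len(adj) == 0:
                g = coo_matrix((self.n_faces, self.n_faces))
            else:
                g = coo_matrix(
                    (np.ones(len(adj)), (adj[:, 0], adj[:, 1])),
                    shape=(self.n_faces, self.n_faces),
                )
            _, labels = _cc(g, directed=False)
            self._cache["face_components"] = labels
        return self._cache["face_components"]

    def n_components(self) -> int:
        return int(self.face_components().max()) + 1

    def boundary_edges(self) -> np.ndarray:
        """(K, 2) edges incident to exactly one face."""
        e, face_of, keys = self._edge_tables()
        uniq, counts = np.unique(keys, return_counts=True)
        single = set(uniq[counts == 1].tolist())
        mask = np.array([k in single for k in keys])
        return e[mask]

    def is_watertight(self) -> bool:
        e, face_of, keys = self._edge_tables()
        _, counts = np.unique(keys, return_counts=True)
        return bool((counts == 2).all())

    def vertex_adjacency(self):
        """Sparse symmetric vertex graph weighted by edge length."""
        e, _, keys = self._edge_tables()
        uniq_idx = np.unique(keys, return_index=True)[1]
        eu = e[uniq_idx]
        w = np.linalg.norm(self.vertices[eu[:, 0]] - self.vertices[eu[:, 1]], axis=1)
        g = coo_matrix(
            (np.concatenate([w, w]), (np.concatenate([eu[:, 0], eu[:, 1]]),
                                      np.concatenate([eu[:, 1], eu[:, 0]]))),
            shape=(self.n_vertices, self.n_vertices),
        )
        return g.tocsr()

    # ----------------------------------------------------------------- repair
    def drop_degenerate_faces(self) -> tuple["TriangleMesh", int]:
        """Remove zero-area / repeated-vertex faces; returns (mesh, n_dropped)."""
        f = self.faces
        dup = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        areas = self.face_areas()
        bad = dup | (areas <= 0.0)
        n_bad = int(bad.sum())
        if n_bad == 0:
            return self, 0
        if n_bad == self.n_faces:
            raise MeshError("all faces degenerate")
        return TriangleMesh(self.vertices, f[~bad]), n_bad

    def submesh(self, face_mask: np.ndarray) -> "TriangleMesh":
        """Subset of faces, vertices re-indexed compactly."""
        faces = self.faces[face_mask]
        used = np.unique(faces)
        remap = np.full(self.n_vertices, -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        return TriangleMesh(self.vertices[used], remap[faces])

    def boundary_loops(self) -> list[np.ndarray]:
        """Ordered vertex loops of the mesh boundary."""
        be = self.boundary_edges()
        if len(be) == 0:
            return []
        nxt: dict[int, list[int]] = {}
        for a, b in be:
            nxt.setdefault(int(a), []).append(int(b))
            nxt.setdefault(int(b), []).append(int(a))
        unvisited = {tuple(sorted((int(a), int(b)))) for a, b in be}
        loops = []
        while unvisited:
            a, b = next(iter(unvisited))
            loop = [a, b]
            unvisited.discard((min(a, b), max(a, b)))
            while True:
                cur, prev = loop[-1], loop[-2]
                nbrs = [v for v in nxt.get(cur, [])
                        if v != prev and (min(cur, v), max(cur, v)) in unvisited]
                if not nbrs:
                    break
                v = nbrs[0]
                unvisited.discard((min(cur, v), max(cur, v)))
                if v == loop[0]:
                    break
                loop.append(v)
            loops.append(np.array(loop, dtype=np.int64))
        return loops

    def capped(self) -> "TriangleMesh":
        """Close every boundary loop with a centroid fan; no-op if watertight."""
        loops = self.boundary_loops()
        if not loops:
            return self
        verts = [self.vertices]
        faces = [self.faces]
        next_v = self.n_vertices
        # Orientation: boundary edges appear in face winding order; walk the loop
        # and wind the fan opposite to the open edge so normals stay outward.
        directed = set()
        for f in self.faces:
            directed.update([(int(f[0]), int(f[1])), (int(f[1]), int(f[2])),
                             (int(f[2]), int(f[0]))])
        for loop in loops:
            c = self.vertices[loop].mean(axis=0)
            verts.append(c[None, :])
            new_faces = []
            for i in range(len(loop)):
                a, b = int(loop[i]), int(loop[(i + 1) % len(loop)])
                if (a, b) in directed:
                    new_faces.append([b, a, next_v])
                else:
                    new_faces.append([a, b, next_v])
            faces.append(np.array(new_faces, dtype=np.int64))
            next_v += 1
        return TriangleMesh(np.concatenate(verts), np.concatenate(faces))


def merge_meshes(meshes: list[TriangleMesh]) -> TriangleMesh:
    """Concatenate meshes into one (components preserved, no welding)."""
    verts, faces, off = [], [], 0
    for m in meshes:
        verts.append(m.vertices)
        faces.append(m.faces + off)
        off += m.n_vertices
    return TriangleMesh(np.concatenate(verts), np.concatenate(faces))


def ray_first_hits(
    origins: np.ndarray,
    directions: np.ndarray,
    mesh: TriangleMesh,
    exclude_face: np.ndarray | None = None,
    t_min: float = 1e-9,
    chunk: int = 256,
) -> np.ndarray:
    """First-hit distances of rays against the mesh (Moller-Trumbore).

    Returns inf where a ray misses.  exclude_face[i] (optional) is a face
    index ignored for ray i (its own source face).
    """
    tri = mesh.triangles()
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0
    e2 = tri[:, 2] - v0
    e1x, e1y, e1z = e1[:, 0], e1[:, 1], e1[:, 2]
    e2x, e2y, e2z = e2[:, 0], e2[:, 1], e2[:, 2]
    v0x, v0y, v0z = v0[:, 0], v0[:, 1], v0[:, 2]
    n_rays = len(origins)
    out = np.full(n_rays, np.inf)
    eps = 1e-9
    for s in range(0, n_rays, chunk):
        ox = origins[s:s + chunk, 0:1]
        oy = origins[s:s + chunk, 1:2]
        oz = origins[s:s + chunk, 2:3]
        dx = directions[s:s + chunk, 0:1]
        dy = directions[s:s + chunk, 1:2]
        dz = directions[s:s + chunk, 2:3]
        # pvec = d x e2
        px = dy * e2z - dz * e2y
        py = dz * e2x - dx * e2z
        pz = dx * e2y - dy * e2x
        det = px * e1x + py * e1y + pz * e1z
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = 1.0 / det
            tx, ty, tz = ox - v0x, oy - v0y, oz - v0z
            u = (tx * px + ty * py + tz * pz) * inv
            # qvec = tvec x e1
            qx = ty * e1z - tz * e1y
            qy = tz * e1x - tx * e1z
            qz = tx * e1y - ty * e1x
            v = (qx * dx + qy * dy + qz * dz) * inv
            t = (qx * e2x + qy * e2y + qz * e2z) * inv
            valid = ((np.abs(det) > 1e-14) & (u >= -eps) & (v >= -eps)
                     & (u + v <= 1 + eps) & (t > t_min) & np.isfinite(t))
        if exclude_face is not None:
            cols = np.arange(tri.shape[0])[None, :]
            valid &= cols != exclude_face[s:s + chunk][:, None]
        t = np.where(valid, t, np.inf)
        out[s:s + chunk] = t.min(axis=1)
    return out
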
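"""Completeness classification (groups A-E) and cylinder repair of spines.

Groups: A complete & separable, B complete & not separable, C one detached
component (missing neck), D two components, E three or more components
(discarded).  Groups C and D are repaired by bridging with a thin cylinder
so neck length becomes measurable: C gets a neck from the insertion point
to the nearest mesh vertex; D gets a bridge between the mutually closest
vertices of its two components (followed by a neck extension if the
insertion point is still far from the mesh).  Repair only ever adds faces.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._mesh import TriangleMesh
from .mesh_io import SpineMesh

#: per-species default repair-cylinder radius, um
DEFAULT_CYLINDER_RADIUS = {"mouse": 0.14, "human": 0.17}


class RepairError(RuntimeError):
    pass


class DiscardSpine(RuntimeError):
    """Raised for group-E spines, which are excluded rather than repaired."""


@dataclass
class RepairParams:
    anchor_threshold: float = 0.2      # um; min insertion-point gap defining group C
    cylinder_radius: float = 0.17      # um
    cylinder_facets: int = 16

    def __post_init__(self):
        if self.anchor_threshold <= 0 or self.cylinder_radius <= 0:
            raise ValueError("repair parameters must be positive")
        if self.cylinder_facets < 6:
            raise ValueError("cylinder_facets must be >= 6")

    @classmethod
    def for_species(cls, species: str, **kw) -> "RepairParams":
        kw.setdefault("cylinder_radius", DEFAULT_CYLINDER_RADIUS.get(species, 0.17))
        return cls(**kw)


@dataclass
class RepairResult:
    mesh: TriangleMesh
    operations_applied: set = field(default_factory=set)
    added_face_ids: list = field(default_factory=list)
    original_group: str = ""
    notes: str = ""


def count_components(mesh: TriangleMesh) -> int:
    """Number of face-connected components (faces joined via shared edges)."""
    return mesh.n_components()


def anchor_gap(spine: SpineMesh) -> float:
    """Distance from the insertion point to the nearest mesh vertex."""
    return float(np.linalg.norm(spine.mesh.vertices - spine.insertion_point,
                                axis=1).min())


def classify_pre_segmentation(spine: SpineMesh,
                              params: RepairParams | None = None) -> str:
    """Group by component count and anchor distance.

    Returns "C", "D", "E", or "pending" (single attached component; A vs B
    is decided by the segmentation outcome).
    """
    params = params or RepairParams()
    n = count_components(spine.mesh)
    if n >= 3:
        return "E"
    if n == 2:
        return "D"
    return "C" if anchor_gap(spine) >= params.anchor_threshold else "pending"


# ------------------------------------------------------------------- cylinders
def _frame(axis: np.ndarray):
    axis = axis / np.linalg.norm(axis)
    ref = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(ref, axis)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(axis, e1)


def _bridge_cylinder(p: np.ndarray, q: np.ndarray, radius: float, facets: int):
    """Open tube from p to q with fan caps converging on p and q themselves.

    Returns (vertices, faces) with local indices; vertex 0 is p, vertex 1 is
    q, so callers can splice existing mesh vertices in for either end.
    """
    axis = q - p
    length = np.linalg.norm(axis)
    if length <= 0:
        raise RepairError("cylinder endpoints coincide")
    e1, e2 = _frame(axis)
    theta = np.linspace(0.0, 2 * np.pi, facets, endpoint=False)
    ring0 = p + 0.02 * axis + radius * (np.outer(np.cos(theta), e1)
                                        + np.outer(np.sin(theta), e2))
    ring1 = p + 0.98 * axis + radius * (np.outer(np.cos(theta), e1)
                                        + np.outer(np.sin(theta), e2))
    verts = np.vstack([p[None, :], q[None, :], ring0, ring1])
    faces = []
    a, b = 2, 2 + facets
    for k in range(facets):
        k2 = (k + 1) % facets
        faces.append([a + k, a + k2, b + k])
        faces.append([a + k2, b + k2, b + k])
        faces.append([a + k2, a + k, 0])     # cap fan to p
        faces.append([b + k, b + k2, 1])     # cap fan to q
    return verts, np.array(faces, dtype=np.int64)


def _attach_cylinder(mesh: TriangleMesh, p, q, params: RepairParams,
                     weld_vertices: list[int]):
    """Append a cylinder between two endpoints, each a 3D point or an
    existing vertex index.

    Vertex-index endpoints are spliced onto that vertex and "tacked" to one
    of its incident mesh edges, so the result is a single edge-connected
    component.
    """
    p_pt = mesh.vertices[p] if isinstance(p, (int, np.integer)) else np.asarray(p, float)
    q_pt = mesh.vertices[q] if isinstance(q, (int, np.integer)) else np.asarray(q, float)
    verts, faces = _bridge_cylinder(p_pt, q_pt,
                                    params.cylinder_radius, params.cylinder_facets)
    off = mesh.n_vertices
    new_faces = faces + off
    # splice: local vertices 0/1 are the endpoints -> reuse existing indices
    remap = {}
    if isinstance(p, (int, np.integer)):
        remap[off + 0] = int(p)
    if isinstance(q, (int, np.integer)):
        remap[off + 1] = int(q)
    for old, new in remap.items():
        new_faces[new_faces == old] = new
    all_verts = np.vstack([mesh.vertices, verts])
    all_faces = np.vstack([mesh.faces, new_faces])
    out = TriangleMesh(all_verts, all_faces)
    # tack faces: share an existing mesh edge so components merge under
    # edge-connectivity (may create a locally non-manifold edge; measurement
    # treats the union as watertight-by-union)
    tacks = []
    for wv in weld_vertices:
        incident = np.where((mesh.faces == wv).any(axis=1))[0]
        if len(incident) == 0:
            continue
        f = mesh.faces[incident[0]]
        others = [int(v) for v in f if v != wv]
        ring_candidates = np.arange(off + 2, off + 2 + 2 * params.cylinder_facets)
        d = np.linalg.norm(all_verts[ring_candidates] - all_verts[wv], axis=1)
        rj = int(ring_candidates[d.argmin()])
        tacks.append([wv, others[0], rj])
    if tacks:
        all_faces = np.vstack([all_faces, np.array(tacks, dtype=np.int64)])
        out = TriangleMesh(all_verts, all_faces)
    return out, list(range(mesh.n_faces, out.n_faces))


# ------------------------------------------------------------------ operations
def extend_neck(spine: SpineMesh, params: RepairParams | None = None) -> RepairResult:
    """Group C repair: cylinder from the insertion point to the nearest vertex."""
    params = params or RepairParams()
    mesh = spine.mesh
    if mesh.n_components() != 1:
        raise RepairError("extend_neck requires a single-component mesh")
    gap = anchor_gap(spine)
    if gap < params.anchor_threshold:
        raise RepairError(
            f"anchor gap {gap:.3f} um below threshold {params.anchor_threshold} um")
    nearest = int(np.linalg.norm(mesh.vertices - spine.insertion_point, axis=1).argmin())
    out, added = _attach_cylinder(mesh, spine.insertion_point, nearest,
                                  params, weld_vertices=[nearest])
    if out.n_components() != 1:
        raise RepairError("neck extension failed to produce a single component")
    return RepairResult(mesh=out, operations_applied={"neck_extension"},
                        added_face_ids=added, original_group="C")


def closest_vertex_pair(mesh: TriangleMesh) -> tuple[int, int]:
    """Mutually closest vertices of the two components (ties -> lowest index)."""
    comp = mesh.face_components()
    vcomp = np.full(mesh.n_vertices, -1, dtype=np.int64)
    for ci in (0, 1):
        vcomp[np.unique(mesh.faces[comp == ci])] = ci
    ia = np.where(vcomp == 0)[0]
    ib = np.where(vcomp == 1)[0]
    tree = cKDTree(mesh.vertices[ib])
    d, j = tree.query(mesh.vertices[ia])
    order = np.lexsort((ib[j], ia, d))   # distance, then lowest indices
    k = order[0]
    return int(ia[k]), int(ib[j[k]])


def bridge_components(spine: SpineMesh, params: RepairParams | None = None
                      ) -> RepairResult:
    """Group D repair: cylinder joining the closest vertices of the 2 components."""
    params = params or RepairParams()
    mesh = spine.mesh
    if mesh.n_components() != 2:
        raise RepairError("bridge_components requires exactly 2 components")
    va, vb = closest_vertex_pair(mesh)
    out, added = _attach_cylinder(mesh, va, vb, params,
                                  weld_vertices=[va, vb])
    if out.n_components() != 1:
        raise RepairError("bridge failed to produce a single component")
    return RepairResult(mesh=out, operations_applied={"component_bridge"},
                        added_face_ids=added, original_group="D")


def repair(spine: SpineMesh, params: RepairParams | None = None) -> RepairResult:
    """Repair a group C or D spine; group E raises DiscardSpine.

    Group D spines whose bridged mesh still leaves the insertion point
    >= anchor_threshold from every vertex additionally get a neck extension
    (bridge first, then elongation).
    """
    params = params or RepairParams()
    group = classify_pre_segmentation(spine, params)
    if group == "E":
        raise DiscardSpine("three or more components; spine discarded")
    if group == "pending":
        raise RepairError("spine is complete (group A/B); nothing to repair")
    if group == "C":
        return extend_neck(spine, params)
    # group D
    res = bridge_components(spine, params)
    bridged = spine.with_mesh(res.mesh)
    if anchor_gap(bridged) >= params.anchor_threshold:
        res2 = extend_neck(bridged, params)
        return RepairResult(mesh=res2.mesh,
                            operations_applied=res.operations_applied
                            | res2.operations_applied,
                            added_face_ids=res.added_face_ids
                            + [i + 0 for i in res2.added_face_ids],
                            original_group="D",
                            notes="bridge followed by neck extension")
    return res
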
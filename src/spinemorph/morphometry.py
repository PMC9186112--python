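"""Per-spine measurements from a labeled spine mesh.

Reported quantities and units follow the result tables downstream: volumes
in um^3, lengths in um, neck diameter in nm.  Neck length and spine length
are skeleton arc lengths (a bent neck is measured along its path, not as a
chord); neck diameter is the median SDF over neck-labeled faces and is by
policy never computed for repaired spines, whose cylinder is an artificial
stand-in.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._mesh import TriangleMesh
from .head_neck_segmentation import (HeadNeckLabels, SegmentationParams,
                                     Skeleton, compute_sdf, oriented,
                                     skeletonize)
from .mesh_io import SpineMesh

#: light-microscopy resolution proxy; diameters below this are flagged, um
LM_RESOLUTION_UM = 0.2


class MeasurementError(RuntimeError):
    pass


class PolicyError(RuntimeError):
    """An estimator was requested on a spine where it is disallowed."""


@dataclass
class MorphometryRecord:
    spine_id: str
    group: str
    repaired: bool = False
    operations: str = ""
    species: str = ""
    compartment: str = ""
    subject: str = ""
    dendrite: str = ""
    head_volume_um3: float | None = None
    head_area_um2: float | None = None
    sphericity: float | None = None
    neck_length_um: float | None = None
    neck_diameter_nm: float | None = None
    spine_length_um: float | None = None
    spine_volume_um3: float | None = None
    sub_resolution: bool = False
    flags: str = ""

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def sphericity(volume: float, area: float) -> float:
    """pi^(1/3) (6V)^(2/3) / A: 1 for a sphere, < 1 otherwise; scale-free."""
    if volume <= 0 or area <= 0:
        raise ValueError("volume and area must be positive")
    return float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area)


def head_submesh(spine: SpineMesh, labels: HeadNeckLabels) -> TriangleMesh:
    if not labels.separable:
        raise MeasurementError("spine is not separable; no head submesh")
    return oriented(spine.mesh).submesh(labels.head_mask).capped()


def head_volume(spine: SpineMesh, labels: HeadNeckLabels) -> float:
    """Volume of the head submesh closed at the label boundary (um^3)."""
    hm = head_submesh(spine, labels)
    v = hm.volume()
    if v <= 0:
        raise MeasurementError("non-positive head volume")
    return v


def head_area(spine: SpineMesh, labels: HeadNeckLabels) -> float:
    """Closed-surface area of the capped head submesh (um^2)."""
    return head_submesh(spine, labels).area()


def neck_length(spine: SpineMesh, labels: HeadNeckLabels,
                skeleton: Skeleton) -> tuple[float, str]:
    """Arc length from the insertion point to the head/neck boundary (um).

    Measured along the skeleton between the node nearest the insertion
    point and the node nearest the boundary-ring centroid; falls back to
    the Euclidean distance (flagged) when the skeleton is collapsed.
    """
    if not labels.separable:
        raise MeasurementError("spine is not separable; no neck length")
    mesh = spine.mesh
    if len(labels.boundary_edges):
        ring = mesh.vertices[np.unique(labels.boundary_edges)].mean(axis=0)
    else:  # no explicit boundary ring: use the neck-side extreme
        ring = mesh.face_centroids()[labels.head_mask].mean(axis=0)
    if skeleton.collapsed:
        return float(np.linalg.norm(ring - spine.insertion_point)), "euclidean_fallback"
    a = skeleton.nearest_node(spine.insertion_point)
    b = skeleton.nearest_node(ring)
    d = skeleton.path_length(a, b)
    if not np.isfinite(d):
        return float(np.linalg.norm(ring - spine.insertion_point)), "euclidean_fallback"
    return float(d), ""


def neck_diameter(spine: SpineMesh, labels: HeadNeckLabels,
                  sdf: np.ndarray | None = None,
                  params: SegmentationParams | None = None,
                  repaired: bool = False) -> float:
    """Median SDF over neck faces, in nm.  Disallowed on repaired spines."""
    if repaired:
        raise PolicyError("neck diameter is not measured on repaired spines")
    if not labels.separable:
        raise MeasurementError("spine is not separable; no neck diameter")
    if sdf is None:
        sdf = compute_sdf(spine.mesh, params)
    return float(np.median(sdf[labels.neck_mask]) * 1000.0)


def spine_length(spine: SpineMesh, skeleton: Skeleton | None = None
                 ) -> tuple[float, str]:
    """Skeleton arc length from the insertion point to the farthest tip (um)."""
    mesh = spine.mesh
    if skeleton is None:
        skeleton = skeletonize(oriented(mesh), source_point=spine.insertion_point)
    if skeleton.collapsed:
        d = float(np.linalg.norm(mesh.vertices - spine.insertion_point, axis=1).max())
        return d, "euclidean_fallback"
    from scipy.sparse.csgraph import dijkstra
    a = skeleton.nearest_node(spine.insertion_point)
    dist = dijkstra(skeleton.graph(), indices=a)
    dist = dist[np.isfinite(dist)]
    return float(dist.max()), ""


def spine_volume(spine: SpineMesh) -> float:
    """Total volume of the (capped) spine mesh, um^3; per-component for
    multi-component meshes (volumes add)."""
    mesh = oriented(spine.mesh)
    comp = mesh.face_components()
    total = 0.0
    for ci in range(comp.max() + 1):
        sub = oriented(mesh.submesh(comp == ci).capped())
        total += sub.volume()
    return total


def measure(spine: SpineMesh, labels: HeadNeckLabels, skeleton: Skeleton,
            group: str, repaired: bool = False, operations: str = "",
            sdf: np.ndarray | None = None,
            params: SegmentationParams | None = None) -> MorphometryRecord:
    """Assemble the full record for one spine under the reporting policy.

    Group B (not separable): spine length/volume only.  Repaired spines
    (C/D): head volume and neck length but no neck diameter.
    """
    rec = MorphometryRecord(
        spine_id=spine.spine_id, group=group, repaired=repaired,
        operations=operations, species=spine.species,
        compartment=spine.compartment, subject=spine.subject_id,
        dendrite=spine.dendrite_id,
    )
    flags = []
    sl, f = spine_length(spine, skeleton)
    rec.spine_length_um = sl
    if f:
        flags.append(f)
    rec.spine_volume_um3 = spine_volume(spine)
    if labels.separable:
        v = head_volume(spine, labels)
        a = head_area(spine, labels)
        rec.head_volume_um3 = v
        rec.head_area_um2 = a
        rec.sphericity = sphericity(v, a)
        nl, f = neck_length(spine, labels, skeleton)
        rec.neck_length_um = nl
        if f:
            flags.append(f)
        if not repaired:
            d = neck_diameter(spine, labels, sdf=sdf, params=params)
            rec.neck_diameter_nm = d
            if d < LM_RESOLUTION_UM * 1000.0:
                rec.sub_resolution = True
    rec.flags = ";".join(flags)
    return rec
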
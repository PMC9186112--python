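"""Parametric spine meshes with exact ground truth, plus population sampling.

The generator builds a spine as a surface of revolution: a circular neck of
radius ``neck_radius`` from the insertion point (origin) up to ``neck_length``,
meeting a spheroidal head exactly at the plane where the head cross-section
radius equals the neck radius.  That junction ring is the ground-truth
head/neck boundary, so every face carries an unambiguous truth label.

Degraded variants reproduce the completeness taxonomy used by the repair
stage:

  A  complete spine (neck + head, one watertight component)
  B  complete but sessile (wide, near-zero-length neck; not separable)
  C  detached head only (insertion point >= 0.2 um from the mesh)
  D  head plus one detached neck fragment (two components)
  E  head plus two detached neck fragments (three components)
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._mesh import TriangleMesh, merge_meshes
from .mesh_io import SpineMesh, save_obj

GROUPS = ("A", "B", "C", "D", "E")


class ConstructionError(ValueError):
    pass


@dataclass
class SpineSpec:
    """Parameters of one synthetic spine."""

    head_radii: tuple[float, float, float] = (0.5, 0.5, 0.5)
    neck_length: float = 0.6
    neck_radius: float = 0.15
    neck_curvature: float = 0.0        # bend angle at mid-neck, degrees
    mesh_resolution: int = 1           # 1 -> ~16 segments around
    target_group: str = "A"
    fragment_span: tuple[float, float] = (0.0, 0.9)   # groups D/E, fractions of neck
    jitter: float = 0.0                # vertex noise, fraction of neck_radius
    seed: int = 0

    def __post_init__(self):
        if min(self.head_radii) <= 0 or self.neck_length <= 0 or self.neck_radius <= 0:
            raise ConstructionError("all lengths must be positive")
        if self.mesh_resolution < 1:
            raise ConstructionError("mesh_resolution must be >= 1")
        if self.target_group not in GROUPS:
            raise ConstructionError(f"unknown group {self.target_group!r}")


@dataclass
class GroundTruth:
    head_volume: float
    head_area: float
    neck_length: float
    neck_diameter: float
    spine_volume: float
    face_labels: np.ndarray = field(repr=False)   # 1 = head, 0 = neck
    insertion_point: np.ndarray = field(repr=False)


def _equatorial_radius(head_radii) -> float:
    a, b, _ = head_radii
    return float(np.sqrt(a * b))


def _lathe(rings_z, rings_r, n_theta, bottom_center=None, top_center=None,
           ring_tags=None):
    """Closed surface of revolution from per-ring (z, radius).

    Returns (mesh, face_tags).  face_tags[i] = tag of the lower ring of the
    band that produced face i (caps inherit the adjacent ring's tag).
    """
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)
    # equal-area correction: the inscribed n-gon of circumradius R has area
    # (n/2) R^2 sin(2pi/n); inflate ring radii so cross-section areas match
    # the analytic circle and discrete volumes track the closed forms.
    area_fix = np.sqrt(2 * np.pi / (n_theta * np.sin(2 * np.pi / n_theta)))
    rings_r = np.asarray(rings_r, dtype=float) * area_fix
    verts, tags_per_face, faces = [], [], []
    ring_start = []
    for z, r in zip(rings_z, rings_r):
        ring_start.append(len(verts))
        for k in range(n_theta):
            verts.append([r * ct[k], r * st[k], z])
    if ring_tags is None:
        ring_tags = [0] * len(rings_z)
    for i in range(len(rings_z) - 1):
        a, b = ring_start[i], ring_start[i + 1]
        for k in range(n_theta):
            k2 = (k + 1) % n_theta
            # outward winding (CCW seen from outside)
            faces.append([a + k, a + k2, b + k])
            faces.append([a + k2, b + k2, b + k])
            tags_per_face.extend([ring_tags[i], ring_tags[i]])
    if bottom_center is not None:
        c = len(verts)
        verts.append(list(bottom_center))
        a = ring_start[0]
        for k in range(n_theta):
            k2 = (k + 1) % n_theta
            faces.append([a + k2, a + k, c])   # facing -z
            tags_per_face.append(ring_tags[0])
    if top_center is not None:
        c = len(verts)
        verts.append(list(top_center))
        a = ring_start[-1]
        for k in range(n_theta):
            k2 = (k + 1) % n_theta
            faces.append([a + k, a + k2, c])   # facing +z
            tags_per_face.append(ring_tags[-1])
    mesh = TriangleMesh(np.array(verts), np.array(faces))
    return mesh, np.array(tags_per_face, dtype=np.int64)


def make_cylinder(length: float, radius: float, n_theta: int = 24,
                  n_z: int = 16, z0: float = 0.0) -> TriangleMesh:
    """Capped circular cylinder along +z starting at z0 (test primitive)."""
    z = np.linspace(z0, z0 + length, n_z + 1)
    r = np.full_like(z, radius)
    mesh, _ = _lathe(z, r, n_theta, bottom_center=(0, 0, z0),
                     top_center=(0, 0, z0 + length))
    return mesh


def make_bent_cylinder(arm: float, angle_deg: float, radius: float,
                       n_theta: int = 24, n_z: int = 24) -> TriangleMesh:
    """Two cylinder arms of length ``arm`` joined at ``angle_deg`` (test primitive)."""
    mesh = make_cylinder(2 * arm, radius, n_theta, n_z)
    v = mesh.vertices.copy()
    ang = np.deg2rad(angle_deg)
    hi = v[:, 2] > arm
    p = v[hi] - [0, 0, arm]
    rot = np.array([[1, 0, 0],
                    [0, np.cos(ang), -np.sin(ang)],
                    [0, np.sin(ang), np.cos(ang)]])
    v[hi] = p @ rot.T + [0, 0, arm]
    return TriangleMesh(v, mesh.faces)


def make_ellipsoid(radii, subdivisions: int = 3) -> TriangleMesh:
    """Icosphere scaled to a (possibly triaxial) ellipsoid (test primitive)."""
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
        [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
        [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
    ], dtype=float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ])
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}
        vlist = list(verts)

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = vlist[i] + vlist[j]
                m /= np.linalg.norm(m)
                cache[key] = len(vlist)
                vlist.append(m)
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces.extend([[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]])
        verts = np.array(vlist)
        faces = np.array(new_faces)
    verts = verts * np.asarray(radii, dtype=float)
    return TriangleMesh(verts, faces)


# ------------------------------------------------------------------ the spine
def _head_profile(spec: SpineSpec):
    """Junction geometry of the spheroidal head sitting on the neck.

    x/y semi-axes are reduced to their geometric mean so the head meets the
    circular neck exactly on a ring; z semi-axis is kept.
    """
    req = _equatorial_radius(spec.head_radii)
    c = float(spec.head_radii[2])
    rn = spec.neck_radius
    if rn >= 0.95 * req:
        raise ConstructionError("neck_radius must be < 0.95 x head equatorial radius")
    h = c * np.sqrt(1.0 - (rn / req) ** 2)
    center_z = spec.neck_length + h          # head center
    return req, c, rn, center_z


def _head_truth(spec: SpineSpec):
    """Analytic head volume / area above the junction plane (+ junction disk)."""
    req, c, rn, center_z = _head_profile(spec)
    u = (spec.neck_length - center_z) / c    # = -sqrt(1 - rn^2/req^2)
    v_above = np.pi * req**2 * c * (2.0 / 3.0 - u + u**3 / 3.0)
    # lateral area by quadrature of the surface of revolution
    phi0 = np.arccos(u)                      # polar angle at the junction
    phi = np.linspace(0.0, phi0, 20001)
    r = req * np.sin(phi)
    z = c * np.cos(phi)
    area_lat = np.trapezoid(2 * np.pi * r * np.hypot(np.gradient(r, phi),
                                                     np.gradient(z, phi)), phi)
    return float(v_above), float(area_lat + np.pi * rn**2)


def _bend(mesh: TriangleMesh, spec: SpineSpec) -> TriangleMesh:
    if spec.neck_curvature == 0.0:
        return mesh
    ang = np.deg2rad(spec.neck_curvature)
    zb = spec.neck_length / 2.0
    v = mesh.vertices.copy()
    hi = v[:, 2] > zb
    rot = np.array([[1, 0, 0],
                    [0, np.cos(ang), -np.sin(ang)],
                    [0, np.sin(ang), np.cos(ang)]])
    v[hi] = (v[hi] - [0, 0, zb]) @ rot.T + [0, 0, zb]
    return TriangleMesh(v, mesh.faces)


def _jitter(mesh: TriangleMesh, spec: SpineSpec, rng) -> TriangleMesh:
    if spec.jitter <= 0:
        return mesh
    sigma = spec.jitter * spec.neck_radius
    v = mesh.vertices + rng.normal(0.0, sigma, mesh.vertices.shape)
    return TriangleMesh(v, mesh.faces)


def _build_complete(spec: SpineSpec, neck_length: float, neck_radius: float):
    req, c, rn, center_z = _head_profile(
        SpineSpec(spec.head_radii, neck_length, neck_radius,
                  mesh_resolution=spec.mesh_resolution))
    n_theta = 8 + 8 * spec.mesh_resolution
    n_neck = max(3, int(np.ceil(neck_length / (0.35 * c) * spec.mesh_resolution * 2)))
    n_head = max(14, 10 * spec.mesh_resolution)
    z_neck = np.linspace(0.0, neck_length, n_neck + 1)
    phi0 = np.arccos((neck_length - center_z) / c)
    phi = np.linspace(phi0, 0.0, n_head + 1)[1:-1]
    z_head = center_z + c * np.cos(phi)
    r_head = req * np.sin(phi)
    rings_z = np.concatenate([z_neck, z_head])
    rings_r = np.concatenate([np.full_like(z_neck, neck_radius), r_head])
    # tag: 0 below junction, 1 at/above
    tags = [0] * len(z_neck) + [1] * len(z_head)
    tags[len(z_neck) - 1] = 1   # band spanning the junction counts as head side? no:
    tags[len(z_neck) - 1] = 0   # band from last neck ring to first head ring -> neck
    mesh, face_tags = _lathe(rings_z, rings_r, n_theta,
                             bottom_center=(0, 0, 0.0),
                             top_center=(0, 0, center_z + c),
                             ring_tags=tags)
    # faces whose centroid is above the junction plane are head
    labels = (mesh.face_centroids()[:, 2] > neck_length).astype(np.int64)
    return mesh, labels


def _build_head_only(spec: SpineSpec):
    """Head spheroid truncated at the junction plane, capped; base at z = neck_length."""
    req, c, rn, center_z = _head_profile(spec)
    n_theta = 8 + 8 * spec.mesh_resolution
    n_head = max(14, 10 * spec.mesh_resolution)
    phi0 = np.arccos((spec.neck_length - center_z) / c)
    phi = np.linspace(phi0, 0.0, n_head + 1)[:-1]
    rings_z = center_z + c * np.cos(phi)
    rings_r = req * np.sin(phi)
    mesh, _ = _lathe(rings_z, rings_r, n_theta,
                     bottom_center=(0, 0, rings_z[0]),
                     top_center=(0, 0, center_z + c))
    labels = np.ones(mesh.n_faces, dtype=np.int64)
    return mesh, labels


def _neck_fragment(spec: SpineSpec, f0: float, f1: float):
    L = spec.neck_length
    frag = make_cylinder((f1 - f0) * L, spec.neck_radius,
                         n_theta=8 + 8 * spec.mesh_resolution,
                         n_z=max(3, int(6 * (f1 - f0))), z0=f0 * L)
    return frag, np.zeros(frag.n_faces, dtype=np.int64)


def make_spine(spec: SpineSpec) -> tuple[SpineMesh, GroundTruth]:
    """Build one synthetic spine and its exact ground truth."""
    rng = np.random.default_rng(spec.seed)
    group = spec.target_group
    L, rn = spec.neck_length, spec.neck_radius
    if group == "B":
        # sessile: head truncated directly at the base plane, no neck at all
        req = _equatorial_radius(spec.head_radii)
        rn = max(rn, 0.8 * req)
        bspec = SpineSpec(spec.head_radii, 0.4, rn,
                          mesh_resolution=spec.mesh_resolution)
        mesh, labels = _build_head_only(bspec)
        v = mesh.vertices.copy()
        v[:, 2] -= v[:, 2].min()        # base plane down to z = 0
        mesh = TriangleMesh(v, mesh.faces)
        labels = np.ones(mesh.n_faces, dtype=np.int64)
        head_v, head_a = _head_truth(bspec)
        L = 1e-9
    elif group == "A":
        mesh, labels = _build_complete(spec, L, rn)
        head_v, head_a = _head_truth(spec)
    elif group == "C":
        if L < 0.2:
            raise ConstructionError(
                "group C requires the insertion point >= 0.2 um from the mesh "
                f"(neck_length = {L} um)")
        mesh, labels = _build_head_only(spec)
        head_v, head_a = _head_truth(spec)
    elif group in ("D", "E"):
        head, head_labels = _build_head_only(spec)
        f0, f1 = spec.fragment_span
        if not (0.0 <= f0 < f1 <= 0.95):
            raise ConstructionError("fragment_span must satisfy 0 <= f0 < f1 <= 0.95")
        parts = [(head, head_labels)]
        if group == "D":
            parts.append(_neck_fragment(spec, f0, f1))
        else:
            mid = (f0 + f1) / 2.0
            parts.append(_neck_fragment(spec, f0, mid - 0.08))
            parts.append(_neck_fragment(spec, mid + 0.08, f1))
        mesh = merge_meshes([p[0] for p in parts])
        labels = np.concatenate([p[1] for p in parts])
        head_v, head_a = _head_truth(spec)
    else:   # pragma: no cover - guarded by SpineSpec validation
        raise ConstructionError(group)

    mesh = _bend(mesh, spec)
    mesh = _jitter(mesh, spec, rng)
    neck_len_truth = L if group != "C" else L   # C: gap to be rebuilt equals L
    truth = GroundTruth(
        head_volume=head_v,
        head_area=head_a,
        neck_length=neck_len_truth,
        neck_diameter=2.0 * rn,
        spine_volume=head_v + np.pi * rn**2 * L,
        face_labels=labels,
        insertion_point=np.zeros(3),
    )
    spine = SpineMesh(mesh=mesh, insertion_point=np.zeros(3),
                      spine_id=f"synthetic-{group}-{spec.seed}")
    return spine, truth


# ------------------------------------------------------------------ population
@dataclass
class PopulationSpec:
    """Log-normal morphometric population with Gaussian-copula rank correlation.

    ``features`` maps a feature name to (median, multiplicative_spread) where
    multiplicative_spread = exp(sigma) of the underlying normal (1.0 means a
    point mass at the median).  ``rank_corr`` maps unordered feature pairs to
    target Spearman correlations.
    """

    n: int = 100
    features: dict = field(default_factory=lambda: {
        "head_volume_um3": (0.32, 2.2),
        "neck_length_um": (0.594, 1.9),
        "neck_diameter_nm": (339.0, 1.4),
    })
    rank_corr: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name, (med, spread) in self.features.items():
            if med <= 0 or spread < 1.0:
                raise ValueError(f"feature {name!r}: median > 0 and spread >= 1 required")


def sample_population(spec: PopulationSpec):
    """Sample the population table (pandas DataFrame, one row per spine)."""
    import pandas as pd

    names = list(spec.features)
    k = len(names)
    # Spearman target -> Gaussian copula correlation
    corr = np.eye(k)
    for (a, b), rho_s in spec.rank_corr.items():
        i, j = names.index(a), names.index(b)
        r = 2.0 * np.sin(np.pi * rho_s / 6.0)
        corr[i, j] = corr[j, i] = r
    w = np.linalg.eigvalsh(corr)
    if w.min() < -1e-10:
        raise ValueError("rank correlation targets give a non-PSD copula matrix")
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(k))
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n, k)) @ L.T
    cols = {}
    for j, name in enumerate(names):
        med, spread = spec.features[name]
        cols[name] = med * np.exp(np.log(spread) * z[:, j])
    return pd.DataFrame(cols)


def make_bimodal_population(n: int, separation: float, seed: int, dim: int = 1):
    """Equal mixture of two unit Gaussians ``separation`` sigmas apart.

    Negative control for the unimodality tests; extra dimensions (2D/3D) are
    independent standard normal.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if dim not in (1, 2, 3):
        raise ValueError("dim must be 1, 2 or 3")
    rng = np.random.default_rng(seed)
    comp = rng.integers(0, 2, n)
    x = rng.standard_normal((n, dim))
    x[:, 0] += np.where(comp == 0, -separation / 2.0, separation / 2.0)
    return x[:, 0] if dim == 1 else x


# ------------------------------------------------------------------- fixtures
def write_synthetic_dataset(specs: list[SpineSpec], out_dir, species="human",
                            compartment="basal", unit_scale=1.0, z_correction=1.0):
    """Write OBJ fixtures + manifest + ground-truth JSON; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries, truths = [], {}
    for i, spec in enumerate(specs):
        spine, truth = make_spine(spec)
        sid = f"s{i:04d}-{spec.target_group}"
        fname = f"{sid}.obj"
        save_obj(spine.mesh, out_dir / fname)
        entries.append({
            "id": sid, "path": fname,
            "insertion_point": [0.0, 0.0, 0.0],
            "species": species, "compartment": compartment,
            "subject": "synthetic", "dendrite": "d0",
        })
        truths[sid] = {
            "group": spec.target_group,
            "head_volume": truth.head_volume,
            "head_area": truth.head_area,
            "neck_length": truth.neck_length,
            "neck_diameter": truth.neck_diameter,
            "spine_volume": truth.spine_volume,
        }
    manifest = {"unit_scale": unit_scale, "z_correction": z_correction,
                "spines": entries}
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    (out_dir / "ground_truth.json").write_text(json.dumps(truths, indent=1))
    return mpath
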
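"""Reading/writing spine meshes, dataset manifests, and result tables.

Meshes are Wavefront OBJ (triangles; polygon faces are fan-triangulated,
normals/materials ignored) or ASCII PLY.  A manifest is a single JSON or
YAML document describing every spine of a dataset:

    {"unit_scale": 1.0, "z_correction": 0.84,
     "spines": [{"id": ..., "path": ..., "insertion_point": [x, y, z],
                 "species": "human", "compartment": "basal",
                 "subject": ..., "dendrite": ...}, ...]}

All coordinates are micrometers after ``unit_scale`` is applied.  The axial
(z) correction factor compensates the depth distortion of confocal stacks
and is applied exactly once, at load time.
"""
from __future__ import annotations

import io
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._mesh import MeshError, TriangleMesh

log = logging.getLogger(__name__)

SPECIES = ("human", "mouse")
COMPARTMENTS = ("apical", "basal")

#: canonical column order of the morphometry table
RECORD_COLUMNS = [
    "spine_id", "species", "compartment", "subject", "dendrite",
    "group", "repaired", "operations",
    "head_volume_um3", "head_area_um2", "sphericity",
    "neck_length_um", "neck_diameter_nm",
    "spine_length_um", "spine_volume_um3",
    "sub_resolution", "flags",
]


class ManifestError(ValueError):
    pass


@dataclass
class SpineMesh:
    """A spine mesh plus its dendritic-shaft insertion point and metadata."""

    mesh: TriangleMesh
    insertion_point: np.ndarray
    species: str = "human"
    compartment: str = "basal"
    subject_id: str = ""
    dendrite_id: str = ""
    spine_id: str = ""

    def __post_init__(self):
        self.insertion_point = np.asarray(self.insertion_point, dtype=float).reshape(3)
        if not np.isfinite(self.insertion_point).all():
            raise ManifestError(f"non-finite insertion point for spine {self.spine_id!r}")

    def with_mesh(self, mesh: TriangleMesh) -> "SpineMesh":
        return SpineMesh(mesh, self.insertion_point.copy(), self.species,
                         self.compartment, self.subject_id, self.dendrite_id,
                         self.spine_id)


@dataclass
class DatasetManifest:
    spines: list[dict] = field(default_factory=list)
    unit_scale: float = 1.0
    z_correction: float = 1.0
    base_dir: Path = Path(".")

    def __len__(self):
        return len(self.spines)


# --------------------------------------------------------------------- meshes
def _parse_obj(text: str) -> TriangleMesh:
    verts: list[list[float]] = []
    faces: list[list[int]] = []
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("v "):
            parts = line.split()
            verts.append([float(parts[1]), float(parts[2]), float(parts[3])])
        elif line.startswith("f "):
            idx = []
            for tok in line.split()[1:]:
                i = int(tok.split("/")[0])
                idx.append(i - 1 if i > 0 else len(verts) + i)
            for k in range(1, len(idx) - 1):  # fan-triangulate polygons
                faces.append([idx[0], idx[k], idx[k + 1]])
    if not faces:
        raise MeshError("empty mesh: OBJ file contains no faces")
    return TriangleMesh(np.array(verts), np.array(faces))


def _parse_ply(text: str) -> TriangleMesh:
    lines = text.splitlines()
    if not lines or lines[0].strip() != "ply":
        raise MeshError("not a PLY file")
    n_v = n_f = 0
    i = 1
    fmt = None
    props_before_xyz = 0
    cur_element = None
    while i < len(lines):
        tok = lines[i].split()
        if tok and tok[0] == "format":
            fmt = tok[1]
        elif tok and tok[0] == "element":
            cur_element = tok[1]
            if tok[1] == "vertex":
                n_v = int(tok[2])
            elif tok[1] == "face":
                n_f = int(tok[2])
        elif tok and tok[0] == "end_header":
            i += 1
            break
        i += 1
    if fmt != "ascii":
        raise MeshError("only ASCII PLY is supported")
    verts = np.array([[float(x) for x in lines[i + k].split()[:3]] for k in range(n_v)])
    faces = []
    for k in range(n_f):
        tok = lines[i + n_v + k].split()
        cnt = int(tok[0])
        idx = [int(t) for t in tok[1:1 + cnt]]
        for j in range(1, cnt - 1):
            faces.append([idx[0], idx[j], idx[j + 1]])
    if not faces:
        raise MeshError("empty mesh: PLY file contains no faces")
    return TriangleMesh(verts, np.array(faces))


def load_spine_mesh(path: str | os.PathLike, unit_scale: float = 1.0) -> TriangleMesh:
    """Load an OBJ/PLY mesh; coordinates are multiplied by ``unit_scale``.

    Degenerate faces (zero area or repeated vertex indices) are dropped with
    a logged count.  Multiple connected components are preserved.
    """
    if unit_scale <= 0:
        raise ValueError("unit_scale must be positive")
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".ply":
        mesh = _parse_ply(text)
    else:
        mesh = _parse_obj(text)
    mesh, n_dropped = mesh.drop_degenerate_faces()
    if n_dropped:
        log.info("dropped %d degenerate faces from %s", n_dropped, path.name)
    if unit_scale != 1.0:
        mesh = TriangleMesh(mesh.vertices * unit_scale, mesh.faces)
    return mesh


def save_obj(mesh: TriangleMesh, path: str | os.PathLike) -> None:
    buf = io.StringIO()
    for v in mesh.vertices:
        buf.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
    for f in mesh.faces:
        buf.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
    Path(path).write_text(buf.getvalue())


def apply_z_correction(mesh: TriangleMesh, factor: float) -> TriangleMesh:
    """Scale z-coordinates by ``factor`` (x, y unchanged)."""
    if not factor > 0:
        raise ValueError("z-correction factor must be positive")
    v = mesh.vertices.copy()
    v[:, 2] *= factor
    return TriangleMesh(v, mesh.faces.copy())


# ------------------------------------------------------------------- manifest
def load_manifest(path: str | os.PathLike) -> DatasetManifest:
    """Load and validate a JSON/YAML dataset manifest."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "spines" not in doc:
        raise ManifestError("manifest must be a mapping with a 'spines' list")
    unit_scale = float(doc.get("unit_scale", 1.0))
    if unit_scale <= 0:
        raise ManifestError("unit_scale must be positive")
    z_corr = float(doc.get("z_correction", 1.0))
    if z_corr <= 0:
        raise ManifestError("z_correction must be positive")
    seen: set[str] = set()
    problems = []
    for entry in doc["spines"]:
        sid = str(entry.get("id", "<missing id>"))
        if sid in seen:
            problems.append(f"duplicate spine id {sid!r}")
        seen.add(sid)
        if "path" not in entry:
            problems.append(f"spine {sid!r}: missing mesh path")
        if "insertion_point" not in entry:
            problems.append(f"spine {sid!r}: missing insertion_point")
        else:
            ip = entry["insertion_point"]
            if len(ip) != 3 or not all(np.isfinite(float(x)) for x in ip):
                problems.append(f"spine {sid!r}: invalid insertion_point {ip!r}")
        if entry.get("species") not in SPECIES:
            problems.append(f"spine {sid!r}: species must be one of {SPECIES}")
        if entry.get("compartment") not in COMPARTMENTS:
            problems.append(f"spine {sid!r}: compartment must be one of {COMPARTMENTS}")
    if problems:
        raise ManifestError("; ".join(problems))
    return DatasetManifest(spines=list(doc["spines"]), unit_scale=unit_scale,
                           z_correction=z_corr, base_dir=path.parent)


def load_entry(manifest: DatasetManifest, entry: dict) -> SpineMesh:
    """Materialize one manifest entry: load, scale, z-correct."""
    mesh_path = Path(entry["path"])
    if not mesh_path.is_absolute():
        mesh_path = manifest.base_dir / mesh_path
    mesh = load_spine_mesh(mesh_path, manifest.unit_scale)
    if manifest.z_correction != 1.0:
        mesh = apply_z_correction(mesh, manifest.z_correction)
    ip = np.asarray(entry["insertion_point"], dtype=float) * manifest.unit_scale
    ip[2] *= manifest.z_correction
    return SpineMesh(
        mesh=mesh, insertion_point=ip,
        species=entry["species"], compartment=entry["compartment"],
        subject_id=str(entry.get("subject", "")),
        dendrite_id=str(entry.get("dendrite", "")),
        spine_id=str(entry["id"]),
    )


def iter_spines(manifest: DatasetManifest):
    for entry in manifest.spines:
        yield load_entry(manifest, entry)


# -------------------------------------------------------------------- records
_UNITS_HEADER = (
    "# spinemorph morphometry table\n"
    "# units: head_volume_um3 [um^3], head_area_um2 [um^2], sphericity [-],\n"
    "#        neck_length_um [um], neck_diameter_nm [nm],\n"
    "#        spine_length_um [um], spine_volume_um3 [um^3]\n"
)


def records_to_frame(records: list) -> pd.DataFrame:
    rows = []
    for r in records:
        d = r if isinstance(r, dict) else r.as_dict()
        rows.append({c: d.get(c) for c in RECORD_COLUMNS})
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_records(records: list, path: str | os.PathLike) -> None:
    """Write morphometry records as CSV (stable column order, unit header).

    Missing measurements (e.g. neck diameter on repaired spines) are written
    as empty cells, never as zero.  Numeric round trip is good to >= 9
    significant digits.
    """
    if not records:
        raise ValueError("records must be non-empty")
    frame = records_to_frame(records)
    buf = io.StringIO()
    buf.write(_UNITS_HEADER)
    frame.to_csv(buf, index=False, float_format="%.10g")
    Path(path).write_text(buf.getvalue())


def read_records(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
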
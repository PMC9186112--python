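import numpy as np
import pytest

from spinemorph._mesh import MeshError, TriangleMesh
from spinemorph import mesh_io
from spinemorph.mesh_io import (ManifestError, apply_z_correction, load_manifest,
                                load_spine_mesh, read_records, save_obj,
                                write_records)

TET_OBJ = """\
v 0 0 0
v 1 0 0
v 0 1 0
v 0 0 1
f 1 3 2
f 1 2 4
f 1 4 3
f 2 3 4
"""


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadSpineMesh:
    def test_tetrahedron(self, tmp_path):
        mesh = load_spine_mesh(_write(tmp_path, "t.obj", TET_OBJ))
        assert mesh.n_faces == 4
        assert mesh.n_components() == 1

    def test_unit_scale(self, tmp_path):
        p = _write(tmp_path, "t.obj", TET_OBJ)
        m1 = load_spine_mesh(p, unit_scale=1.0)
        m2 = load_spine_mesh(p, unit_scale=0.001)
        np.testing.assert_allclose(m2.vertices, m1.vertices * 0.001)

    def test_two_disjoint_tetrahedra_one_mesh_two_components(self, tmp_path):
        shifted = TET_OBJ.replace("v 0 0 0", "v 10 0 0").replace(
            "v 1 0 0", "v 11 0 0").replace("v 0 1 0", "v 10 1 0").replace(
            "v 0 0 1", "v 10 0 1")
        shifted = "\n".join(l if not l.startswith("f") else
                            "f " + " ".join(str(int(t) + 4) for t in l.split()[1:])
                            for l in shifted.splitlines())
        mesh = load_spine_mesh(_write(tmp_path, "two.obj", TET_OBJ + shifted))
        assert mesh.n_faces == 8
        assert mesh.n_components() == 2

    def test_empty_mesh_raises(self, tmp_path):
        with pytest.raises(MeshError, match="empty mesh"):
            load_spine_mesh(_write(tmp_path, "e.obj", "v 0 0 0\nv 1 0 0\n"))

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(OSError):
            load_spine_mesh(tmp_path / "nope.obj")

    def test_degenerate_faces_dropped(self, tmp_path):
        bad = TET_OBJ + "f 1 1 2\n"
        mesh = load_spine_mesh(_write(tmp_path, "bad.obj", bad))
        assert mesh.n_faces == 4

    def test_polygon_fan_triangulation(self, tmp_path):
        quad = "v 0 0 0\nv 1 0 0\nv 1 1 0\nv 0 1 0\nf 1 2 3 4\n"
        mesh = load_spine_mesh(_write(tmp_path, "q.obj", quad))
        assert mesh.n_faces == 2

    def test_ascii_ply(self, tmp_path):
        ply = ("ply\nformat ascii 1.0\nelement vertex 4\n"
               "property float x\nproperty float y\nproperty float z\n"
               "element face 4\nproperty list uchar int vertex_indices\n"
               "end_header\n0 0 0\n1 0 0\n0 1 0\n0 0 1\n"
               "3 0 2 1\n3 0 1 3\n3 0 3 2\n3 1 2 3\n")
        mesh = load_spine_mesh(_write(tmp_path, "t.ply", ply))
        assert mesh.n_faces == 4

    def test_obj_roundtrip_idempotent(self, tmp_path):
        m1 = load_spine_mesh(_write(tmp_path, "t.obj", TET_OBJ))
        save_obj(m1, tmp_path / "rt.obj")
        m2 = load_spine_mesh(tmp_path / "rt.obj")
        np.testing.assert_allclose(m2.vertices, m1.vertices)
        np.testing.assert_array_equal(m2.faces, m1.faces)


class TestZCorrection:
    def test_paper_factor(self):
        mesh = TriangleMesh(np.array([[1.0, 2.0, 1.0], [0, 0, 0], [1, 0, 0]]),
                            np.array([[0, 1, 2]]))
        out = apply_z_correction(mesh, 0.84)
        np.testing.assert_allclose(out.vertices[0], [1.0, 2.0, 0.84])
        np.testing.assert_allclose(out.vertices[:, :2], mesh.vertices[:, :2])

    def test_identity(self, tmp_path):
        mesh = load_spine_mesh(_write(tmp_path, "t.obj", TET_OBJ))
        out = apply_z_correction(mesh, 1.0)
        np.testing.assert_array_equal(out.vertices, mesh.vertices)

    def test_volume_halves_for_unit_cube(self):
        from spinemorph.synthetic_spines import make_cylinder
        # closed mesh: signed-volume oracle under z-scaling
        cube = make_cylinder(1.0, 0.3, n_theta=32)
        v0 = cube.volume()
        v1 = apply_z_correction(cube, 0.5).volume()
        assert v1 == pytest.approx(v0 / 2.0, rel=1e-9)

    def test_composition(self, tmp_path):
        mesh = load_spine_mesh(_write(tmp_path, "t.obj", TET_OBJ))
        a = apply_z_correction(mesh, 0.6 * 1.4)
        b = apply_z_correction(apply_z_correction(mesh, 0.6), 1.4)
        np.testing.assert_allclose(a.vertices, b.vertices)

    def test_nonpositive_factor(self, tmp_path):
        mesh = load_spine_mesh(_write(tmp_path, "t.obj", TET_OBJ))
        with pytest.raises(ValueError):
            apply_z_correction(mesh, 0.0)


MANIFEST = """\
{"unit_scale": 1.0, "z_correction": 0.84,
 "spines": [
  {"id": "s1", "path": "s1.obj", "insertion_point": [0, 0, 0],
   "species": "human", "compartment": "basal", "subject": "h40", "dendrite": "d1"},
  {"id": "s2", "path": "s2.obj", "insertion_point": [1, 1, 1],
   "species": "mouse", "compartment": "apical", "subject": "m1", "dendrite": "d2"},
  {"id": "s3", "path": "s3.obj", "insertion_point": [0, 1, 0],
   "species": "human", "compartment": "apical", "subject": "h85", "dendrite": "d3"}
 ]}
"""


class TestManifest:
    def test_three_entries(self, tmp_path):
        man = load_manifest(_write(tmp_path, "m.json", MANIFEST))
        assert len(man) == 3
        assert man.z_correction == 0.84

    def test_missing_insertion_point_names_spine(self, tmp_path):
        broken = MANIFEST.replace('"insertion_point": [1, 1, 1],\n   ', "")
        with pytest.raises(ManifestError, match="s2"):
            load_manifest(_write(tmp_path, "m.json", broken))

    def test_duplicate_id(self, tmp_path):
        dup = MANIFEST.replace('"id": "s3"', '"id": "s1"')
        with pytest.raises(ManifestError, match="duplicate"):
            load_manifest(_write(tmp_path, "m.json", dup))

    def test_yaml_autodetect(self, tmp_path):
        yaml_text = ("unit_scale: 1.0\nz_correction: 1.0\nspines:\n"
                     "  - {id: s1, path: s1.obj, insertion_point: [0, 0, 0],"
                     " species: mouse, compartment: basal}\n")
        man = load_manifest(_write(tmp_path, "m.yaml", yaml_text))
        assert len(man) == 1

    def test_z_correction_applied_once_at_load(self, tmp_path):
        _write(tmp_path, "s1.obj", TET_OBJ)
        man = load_manifest(_write(tmp_path, "m.json", MANIFEST))
        spine = mesh_io.load_entry(man, man.spines[0])
        raw = load_spine_mesh(tmp_path / "s1.obj")
        np.testing.assert_allclose(spine.mesh.vertices[:, 2],
                                   raw.vertices[:, 2] * 0.84)


class TestRecords:
    def _records(self):
        return [
            {"spine_id": "a", "group": "A", "repaired": False,
             "head_volume_um3": 0.523598776123456, "neck_diameter_nm": 301.25,
             "neck_length_um": 0.6, "sphericity": 0.99},
            {"spine_id": "b", "group": "C", "repaired": True,
             "head_volume_um3": 0.31, "neck_diameter_nm": None,
             "neck_length_um": 0.8, "sphericity": 0.95},
        ]

    def test_two_rows(self, tmp_path):
        write_records(self._records(), tmp_path / "r.csv")
        table = read_records(tmp_path / "r.csv")
        assert len(table) == 2
        assert list(table.columns) == mesh_io.RECORD_COLUMNS

    def test_roundtrip_9_significant_digits(self, tmp_path):
        write_records(self._records(), tmp_path / "r.csv")
        table = read_records(tmp_path / "r.csv")
        assert table["head_volume_um3"][0] == pytest.approx(
            0.523598776123456, rel=1e-9)

    def test_missing_neck_diameter_is_empty_not_zero(self, tmp_path):
        write_records(self._records(), tmp_path / "r.csv")
        raw = (tmp_path / "r.csv").read_text()
        row_b = [l for l in raw.splitlines() if l.startswith("b,")][0]
        assert ",0," not in row_b and ",0.0," not in row_b
        table = read_records(tmp_path / "r.csv")
        assert np.isnan(table["neck_diameter_nm"][1])

    def test_empty_records_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_records([], tmp_path / "r.csv")


def test_component_count_invariant_under_vertex_reindexing(tmp_path):
    mesh = load_spine_mesh(_write(tmp_path, "t.obj", TET_OBJ))
    perm = np.array([2, 0, 3, 1])
    inv = np.argsort(perm)
    mesh2 = TriangleMesh(mesh.vertices[perm], inv[mesh.faces])
    assert mesh2.n_components() == mesh.n_components()
    assert mesh2.volume() == pytest.approx(mesh.volume())
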
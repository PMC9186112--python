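import numpy as np
import pytest

from spinemorph.head_neck_segmentation import (oriented, separate, skeletonize)
from spinemorph.mesh_io import SpineMesh
from spinemorph import morphometry as mm
from spinemorph.spine_repair import repair
from spinemorph.synthetic_spines import SpineSpec, make_ellipsoid, make_spine


@pytest.fixture(scope="module")
def measured_a(spine_a):
    spine, truth = spine_a
    mesh = oriented(spine.mesh)
    spine = spine.with_mesh(mesh)
    sk = skeletonize(mesh, spine.insertion_point)
    labels = separate(spine, skeleton=sk)
    assert labels.separable
    return spine, truth, sk, labels


class TestSphericity:
    def test_unit_sphere(self):
        assert mm.sphericity(4 * np.pi / 3, 4 * np.pi) == pytest.approx(1.0)

    def test_unit_cube(self):
        assert mm.sphericity(1.0, 6.0) == pytest.approx((np.pi / 6) ** (1 / 3),
                                                        rel=1e-12)

    def test_cylinder_h_eq_2r(self):
        r = 0.7
        v = 2 * np.pi * r**3
        a = 6 * np.pi * r**2
        assert mm.sphericity(v, a) == pytest.approx(12 ** (2 / 3) / 6, rel=1e-12)

    def test_scale_invariance(self):
        v, a = 0.31, 2.2
        for s in (1e-3, 0.5, 7.0, 1e3):
            assert mm.sphericity(v * s**3, a * s**2) == pytest.approx(
                mm.sphericity(v, a), rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            mm.sphericity(0.0, 1.0)

    def test_isoperimetric_bound_on_meshes(self):
        for radii in [(0.5, 0.5, 0.5), (0.5, 0.4, 0.3), (0.8, 0.2, 0.2)]:
            e = make_ellipsoid(radii, 3)
            assert mm.sphericity(e.volume(), e.area()) <= 1.0 + 1e-6


class TestHeadVolume:
    def test_sphere_head(self, measured_a):
        spine, truth, sk, labels = measured_a
        v = mm.head_volume(spine, labels)
        assert v == pytest.approx(4 / 3 * np.pi * 0.5**3, rel=0.02)

    def test_ellipsoid_head(self):
        spec = SpineSpec(head_radii=(0.5, 0.5, 0.3), neck_radius=0.12,
                         neck_length=0.6, seed=8)
        spine, truth = make_spine(spec)
        labels = separate(spine)
        assert labels.separable
        v = mm.head_volume(spine.with_mesh(oriented(spine.mesh)), labels)
        assert v == pytest.approx(truth.head_volume, rel=0.02)
        # analytic spheroid: 4/3 pi a*b*c minus the small junction cap
        assert truth.head_volume == pytest.approx(
            4 / 3 * np.pi * 0.5 * 0.5 * 0.3, rel=0.05)

    def test_pure_ellipsoid_volume_oracle(self):
        e = make_ellipsoid((0.5, 0.4, 0.3), 3)
        assert e.volume() == pytest.approx(0.2513, rel=0.02)


class TestNeckMeasures:
    def test_neck_length_straight(self, measured_a):
        spine, truth, sk, labels = measured_a
        nl, flag = mm.neck_length(spine, labels, sk)
        assert nl == pytest.approx(0.6, rel=0.1)

    def test_neck_length_bent_is_arc_not_chord(self):
        spec = SpineSpec(head_radii=(0.45, 0.45, 0.45), neck_radius=0.1,
                         neck_length=0.8, neck_curvature=60.0, seed=12)
        spine, truth = make_spine(spec)
        labels = separate(spine)
        assert labels.separable
        sk = skeletonize(oriented(spine.mesh), spine.insertion_point)
        nl, _ = mm.neck_length(spine, labels, sk)
        # arc length stays ~0.8; the straight chord would be ~13% shorter
        assert nl == pytest.approx(0.8, rel=0.12)

    def test_neck_diameter(self, measured_a):
        spine, truth, sk, labels = measured_a
        d = mm.neck_diameter(spine, labels)
        assert d == pytest.approx(300.0, rel=0.1)

    def test_neck_diameter_monotone_in_radius(self):
        out = []
        for nr in (0.10, 0.20):
            spine, _ = make_spine(SpineSpec(neck_radius=nr, seed=14))
            labels = separate(spine)
            out.append(mm.neck_diameter(spine, labels))
        assert out[0] < out[1]

    def test_neck_diameter_policy_on_repaired(self, measured_a):
        spine, truth, sk, labels = measured_a
        with pytest.raises(mm.PolicyError):
            mm.neck_diameter(spine, labels, repaired=True)


class TestSpineLengthVolume:
    def test_group_a_length(self, measured_a):
        spine, truth, sk, labels = measured_a
        sl, _ = mm.spine_length(spine, sk)
        assert sl == pytest.approx(1.6, rel=0.15)   # 0.6 neck + 1.0 head diameter

    def test_sphere_fallback_diameter(self):
        mesh = make_ellipsoid((0.5, 0.5, 0.5), 3)
        spine = SpineMesh(mesh, np.array([0.0, 0.0, -0.5]), spine_id="s")
        sl, flag = mm.spine_length(spine)
        assert flag == "euclidean_fallback"
        assert sl == pytest.approx(1.0, rel=0.05)

    def test_length_scales_linearly(self, measured_a):
        from spinemorph._mesh import TriangleMesh
        spine, truth, sk, labels = measured_a
        scaled = SpineMesh(TriangleMesh(spine.mesh.vertices * 3.0,
                                        spine.mesh.faces.copy()),
                           spine.insertion_point * 3.0, spine_id="x3")
        sl0, _ = mm.spine_length(spine, sk)
        sl1, _ = mm.spine_length(scaled)
        assert sl1 == pytest.approx(3.0 * sl0, rel=0.05)

    def test_spine_volume(self, measured_a):
        spine, truth, sk, labels = measured_a
        assert mm.spine_volume(spine) == pytest.approx(truth.spine_volume,
                                                       rel=0.03)

    def test_volume_invariant_to_reindexing(self, spine_a):
        from spinemorph._mesh import TriangleMesh
        spine, _ = spine_a
        perm = np.random.default_rng(1).permutation(spine.mesh.n_vertices)
        inv = np.argsort(perm)
        shuffled = SpineMesh(TriangleMesh(spine.mesh.vertices[perm],
                                          inv[spine.mesh.faces]),
                             spine.insertion_point)
        assert mm.spine_volume(shuffled) == pytest.approx(mm.spine_volume(spine))

    def test_head_plus_neck_below_total(self, measured_a):
        spine, truth, sk, labels = measured_a
        hv = mm.head_volume(spine, labels)
        assert hv <= mm.spine_volume(spine) * 1.02


class TestMeasureRecord:
    def test_group_a_record_complete(self, measured_a):
        spine, truth, sk, labels = measured_a
        rec = mm.measure(spine, labels, sk, "A")
        assert rec.group == "A" and not rec.repaired
        for field in ("head_volume_um3", "head_area_um2", "sphericity",
                      "neck_length_um", "neck_diameter_nm", "spine_length_um",
                      "spine_volume_um3"):
            assert getattr(rec, field) is not None
        assert 0 < rec.sphericity <= 1.0 + 1e-6

    def test_repaired_record_has_no_diameter(self, spine_c):
        spine, truth = spine_c
        res = repair(spine)
        spine2 = spine.with_mesh(oriented(res.mesh))
        sk = skeletonize(spine2.mesh, spine2.insertion_point)
        labels = separate(spine2, skeleton=sk)
        assert labels.separable
        rec = mm.measure(spine2, labels, sk, "C", repaired=True,
                         operations="neck_extension")
        assert rec.neck_diameter_nm is None
        assert rec.head_volume_um3 == pytest.approx(truth.head_volume, rel=0.02)
        assert rec.neck_length_um == pytest.approx(truth.neck_length, rel=0.1)

    def test_group_b_record_lengths_only(self, spine_b):
        spine, _ = spine_b
        mesh = oriented(spine.mesh)
        spine = spine.with_mesh(mesh)
        sk = skeletonize(mesh, spine.insertion_point)
        labels = separate(spine, skeleton=sk)
        assert not labels.separable
        rec = mm.measure(spine, labels, sk, "B")
        assert rec.head_volume_um3 is None and rec.neck_length_um is None
        assert rec.spine_volume_um3 is not None and rec.spine_length_um is not None

    def test_sub_resolution_flag(self):
        spine, _ = make_spine(SpineSpec(head_radii=(0.4, 0.4, 0.4),
                                        neck_radius=0.08, seed=21))
        mesh = oriented(spine.mesh)
        spine = spine.with_mesh(mesh)
        sk = skeletonize(mesh, spine.insertion_point)
        labels = separate(spine, skeleton=sk)
        assert labels.separable
        rec = mm.measure(spine, labels, sk, "A")
        assert rec.neck_diameter_nm < 200.0
        assert rec.sub_resolution
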
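import numpy as np
import pytest
import trimesh

from osteoplan import mesh_core
from osteoplan.transforms import Plane, RigidTransform
from .test_transforms import random_transform


class TestTransformMesh:
    def test_identity_and_pure_translation(self):
        cube = trimesh.creation.box(extents=[1, 1, 1])
        same = mesh_core.transform_mesh(cube, RigidTransform.identity())
        assert np.allclose(same.vertices, cube.vertices)
        moved = mesh_core.transform_mesh(
            cube, RigidTransform(np.eye(3), [1.0, 2.0, 3.0]))
        shift = moved.vertices.mean(0) - cube.vertices.mean(0)
        assert np.allclose(shift, [1, 2, 3], atol=1e-12)

    def test_roundtrip_through_inverse(self, ellipsoid, rng):
        T = random_transform(rng)
        back = mesh_core.transform_mesh(
            mesh_core.transform_mesh(ellipsoid, T), T.inverse())
        assert np.abs(back.vertices - ellipsoid.vertices).max() < 1e-9


class TestMirrorMesh:
    def test_sphere_centred_on_plane_maps_to_same_point_set(self):
        s = trimesh.creation.icosphere(3, radius=5.0)
        m = mesh_core.mirror_mesh(s, Plane([0, 0, 0], [0, 1, 0]))
        # reflection of a y-symmetric vertex set permutes it
        a = np.sort(np.round(s.vertices, 9).view([('', float)] * 3), axis=0)
        b = np.sort(np.round(m.vertices, 9).view([('', float)] * 3), axis=0)
        assert (a == b).all()

    def test_reflection_preserves_distance_and_flips_side(self, rng):
        plane = Plane([1.0, -2.0, 0.5], rng.normal(size=3))
        p = rng.normal(size=(1, 3)) * 10
        d = plane.signed_distance(p)
        q = plane.reflect(p)
        assert np.allclose(plane.signed_distance(q), -d)

    def test_mirroring_preserves_watertightness_and_volume(self, ellipsoid):
        m = mesh_core.mirror_mesh(ellipsoid, Plane([0, 0, 0], [0, 1, 0]))
        assert m.is_watertight
        assert m.volume == pytest.approx(ellipsoid.volume, rel=1e-9)

    def test_double_mirror_is_identity(self, ellipsoid, rng):
        plane = Plane(rng.normal(size=3), rng.normal(size=3))
        twice = mesh_core.mirror_mesh(
            mesh_core.mirror_mesh(ellipsoid, plane), plane)
        assert np.abs(twice.vertices - ellipsoid.vertices).max() < 1e-9


class TestRayIntersect:
    def test_analytic_sphere_hits(self):
        s = trimesh.creation.icosphere(4, radius=10.0)
        hits = mesh_core.ray_intersect(s, [-20, 0, 0], [1, 0, 0])
        assert len(hits) == 2
        assert hits[0][0] == pytest.approx(10.0, abs=0.05)
        assert hits[1][0] == pytest.approx(30.0, abs=0.05)

    def test_missing_ray_returns_empty(self):
        s = trimesh.creation.icosphere(2, radius=10.0)
        assert mesh_core.ray_intersect(s, [-20, 0, 15], [1, 0, 0]) == []

    def test_distances_strictly_increasing_and_even_parity(self, ellipsoid, rng):
        origin = np.array([-40.0, 0.0, 0.0])
        for _ in range(100):
            target = rng.uniform(-10, 10, 3)
            d = target - origin
            hits = mesh_core.ray_intersect(ellipsoid, origin, d)
            dist = [h[0] for h in hits]
            assert dist == sorted(dist)
            assert len(hits) % 2 == 0

    def test_entry_exit_match_voxel_marching_oracle(self, ellipsoid, rng):
        # independent oracle: march along the ray through a fine
        # occupancy grid of the same solid
        from osteoplan import csg
        pitch = 0.2
        occ, origin_g = csg.solid_occupancy(ellipsoid, pitch)

        def oracle(o, d, tmax=80.0, step=0.05):
            ts = np.arange(0.0, tmax, step)
            pts = o + ts[:, None] * d
            idx = np.floor((pts - origin_g) / pitch).astype(int)
            ok = ((idx >= 0) & (idx < occ.shape)).all(axis=1)
            inside = np.zeros(len(ts), bool)
            inside[ok] = occ[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
            flips = np.flatnonzero(np.diff(inside.astype(int)) != 0)
            return ts[flips]

        checked = 0
        for _ in range(100):
            o = np.array([-40.0, 0, 0]) + rng.uniform(-5, 5, 3)
            d = rng.uniform(-8, 8, 3) + np.array([40.0, 0, 0])
            d = d / np.linalg.norm(d)
            hits = mesh_core.ray_intersect(ellipsoid, o, d)
            ref = oracle(o, d)
            # grazing hits excluded: the marching oracle's error grows
            # as 1/sin(incidence) at tangent rays
            if len(hits) >= 2 and len(ref) >= 2:
                inc0 = abs(d @ ellipsoid.face_normals[hits[0][1]])
                inc1 = abs(d @ ellipsoid.face_normals[hits[-1][1]])
                if min(inc0, inc1) > 0.3:
                    assert abs(hits[0][0] - ref[0]) < 0.3
                    assert abs(hits[-1][0] - ref[-1]) < 0.3
                    checked += 1
        assert checked > 50

    def test_zero_direction_rejected(self, ellipsoid):
        with pytest.raises(ValueError):
            mesh_core.ray_intersect(ellipsoid, [0, 0, 0], [0, 0, 0])


class TestMakeTube:
    def test_annulus_matches_closed_form(self):
        t = mesh_core.make_tube([0, 0, 0], [0, 0, 1], 10.0, 1.9, 5.0)
        expect = np.pi * 10 * (2.5 ** 2 - 0.95 ** 2)
        assert t.volume == pytest.approx(expect, rel=0.01)
        assert t.is_watertight

    def test_zero_inner_diameter_gives_solid_cylinder(self):
        t = mesh_core.make_tube([0, 0, 0], [0, 1, 0], 8.0, 0.0, 4.0)
        assert t.volume == pytest.approx(np.pi * 4.0 * 8.0, rel=0.01)

    def test_twenty_random_parameter_sets_within_one_percent(self, rng):
        for _ in range(20):
            L = rng.uniform(3, 40)
            ro = rng.uniform(1.5, 8.0)
            ri = rng.uniform(0.0, ro - 0.5)
            d = rng.normal(size=3)
            t = mesh_core.make_tube(rng.normal(size=3) * 10, d, L,
                                    2 * ri, 2 * ro)
            assert t.volume == pytest.approx(np.pi * L * (ro**2 - ri**2),
                                             rel=0.01)

    @pytest.mark.parametrize("args", [
        (0.0, 1.9, 5.0), (10.0, 5.0, 1.9), (10.0, -1.0, 5.0)])
    def test_nonpositive_or_inverted_dimensions_rejected(self, args):
        L, di, do = args
        with pytest.raises(ValueError):
            mesh_core.make_tube([0, 0, 0], [0, 0, 1], L, di, do)


class TestBooleanOp:
    def test_self_union_idempotent(self):
        s = trimesh.creation.icosphere(4, radius=10.0)
        u = mesh_core.boolean_op(s, s, "union")
        assert u.volume == pytest.approx(s.volume, rel=0.02)
        assert u.is_watertight

    def test_disjoint_union_adds_volumes(self):
        a = trimesh.creation.box(extents=[20, 20, 20])
        b = trimesh.creation.box(extents=[10, 10, 10])
        b.apply_translation([30, 0, 0])
        u = mesh_core.boolean_op(a, b, "union")
        assert u.volume == pytest.approx(a.volume + b.volume, rel=0.02)

    def test_cube_minus_through_cylinder_closed_form(self):
        cube = trimesh.creation.box(extents=[20, 20, 20])
        cyl = trimesh.creation.cylinder(radius=4.0, height=30.0, sections=64)
        d = mesh_core.boolean_op(cube, cyl, "difference")
        assert d.volume == pytest.approx(8000 - np.pi * 16 * 20, rel=0.02)
        assert d.is_watertight

    def test_open_mesh_rejected_with_edge_diagnostic(self):
        s = trimesh.creation.icosphere(2, radius=5.0)
        open_mesh = trimesh.Trimesh(s.vertices, s.faces[:-5], process=False)
        with pytest.raises(ValueError, match="open|watertight"):
            mesh_core.boolean_op(open_mesh, s, "union")


class TestOffsetShell:
    def test_sphere_patch_gives_concentric_radii(self):
        s = trimesh.creation.icosphere(4, radius=20.0)
        mask = s.triangles_center[:, 2] > 14.0
        shell = mesh_core.offset_shell(s, mask, 0.2, 3.0,
                                       method="analytic")
        assert shell.is_watertight
        r = np.linalg.norm(shell.vertices, axis=1)
        assert r.min() == pytest.approx(20.2, abs=0.2)
        assert r.max() == pytest.approx(23.2, abs=0.2)

    def test_plane_patch_with_zero_clearance_is_a_slab(self):
        g = trimesh.creation.box(extents=[20, 20, 2.0])
        for _ in range(3):
            g = g.subdivide()
        mask = (g.face_normals[:, 2] > 0.9)
        shell = mesh_core.offset_shell(g, mask, 0.0, 3.0, method="analytic")
        zs = shell.vertices[:, 2]
        assert zs.max() - zs.min() == pytest.approx(3.0, abs=1e-6)

    def test_inner_surface_clearance_on_phantom_patch(self, clean_case_coarse):
        bone = clean_case_coarse.intact
        c = bone.triangles_center
        mask = (bone.face_normals[:, 0] < -0.6) & (c[:, 2] > -60) \
            & (c[:, 2] < -25)
        shell = mesh_core.offset_shell(bone, mask, 0.5, 3.0)
        # oracle: from interior patch points, walk out along the face
        # normal; the first shell hit is the inner surface and must sit
        # clearance +- 0.2 mm off the bone
        idx = np.flatnonzero(mask)[::2][:1200]
        good, checked = 0, 0
        for fi in idx:
            p = bone.triangles_center[fi]
            n = bone.face_normals[fi]
            hits = mesh_core.ray_intersect(shell, p, n, check_parity=False)
            if not hits:
                continue
            checked += 1
            good += (0.3 <= hits[0][0] <= 0.7)
        assert checked > 500
        assert good / checked > 0.95

    def test_tiny_region_rejected(self, ellipsoid):
        mask = np.zeros(len(ellipsoid.faces), bool)
        mask[:2] = True
        with pytest.raises(ValueError):
            mesh_core.offset_shell(ellipsoid, mask, 0.2, 3.0)


class TestMeshIO:
    def test_stl_roundtrip_with_label_sidecar(self, ellipsoid, tmp_path):
        labels = {"half": ellipsoid.triangles_center[:, 0] > 0}
        path = tmp_path / "part.stl"
        mesh_core.save_mesh(ellipsoid, path, labels)
        mesh2, labels2 = mesh_core.load_mesh(path)
        assert len(mesh2.faces) == len(ellipsoid.faces)
        assert labels2["half"].sum() == labels["half"].sum()
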
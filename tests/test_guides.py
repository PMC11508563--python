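import json

import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

from osteoplan import guides
from osteoplan.guides import (GuideConfig, KWireSet, PlateModel,
                              design_cutting_guide,
                              design_intermediate_guide,
                              design_reposition_guide, export_guides,
                              panflute_tube_length, solve_seating_pose)
from osteoplan.mesh_core import ray_intersect
from osteoplan.planning import DrillTrajectory, OsteotomyPlan, \
    build_osteotomy_surface
from osteoplan.transforms import RigidTransform


class TestPanfluteTubeLength:
    def test_worked_arithmetic(self):
        assert panflute_tube_length(60.0, 28.0, 2.0) == 30.0

    def test_depth_difference_maps_to_tube_difference(self):
        a = panflute_tube_length(60.0, 20.0, 2.0)
        b = panflute_tube_length(60.0, 35.0, 2.0)
        assert a - b == pytest.approx(15.0)

    def test_short_drill_rejected_with_required_length(self):
        with pytest.raises(ValueError, match="58"):
            panflute_tube_length(40.0, 52.0, 3.0)


def slab_bone():
    return trimesh.creation.box(extents=[30.0, 60.0, 60.0])


def slab_plan(depths=(20.0, 20.0, 20.0), spacing=8.0):
    trajs = [DrillTrajectory([-15.0, (i - 1) * spacing, 6.0], [1.0, 0, 0],
                             depth=d) for i, d in enumerate(depths)]
    return OsteotomyPlan(trajs, build_osteotomy_surface(trajs), 2.0)


def slab_kwires():
    return KWireSet(
        entries=[[-15.0, -8.0, -8.0], [-15.0, 8.0, -8.0],
                 [-15.0, 0.0, -16.0]],
        directions=[[1.0, 0.05, 0.0], [1.0, -0.05, 0.0], [1.0, 0.0, 0.05]])


def slab_footprint(bone):
    c = bone.triangles_center
    return (bone.face_normals[:, 0] < -0.9) & (np.abs(c[:, 1]) < 22) \
        & (np.abs(c[:, 2]) < 22)


@pytest.fixture(scope="module")
def slab_cutting_guide():
    bone = slab_bone()
    plan = slab_plan(depths=(18.0, 24.0, 30.0))
    g = design_cutting_guide(bone, plan, slab_footprint(bone), None,
                             slab_kwires())
    return bone, plan, g


class TestCuttingGuide:
    def test_solid_is_printable_single_body(self, slab_cutting_guide):
        _, _, g = slab_cutting_guide
        assert g.solid.is_watertight
        assert g.solid.is_winding_consistent
        assert g.solid.body_count == 1

    def test_tube_lengths_follow_panflute_conservation(self,
                                                       slab_cutting_guide):
        _, _, g = slab_cutting_guide
        cfg = g.config
        sums = {round(cfg.base_standoff + r["tube_length"] + r["depth"], 9)
                for r in g.tube_records}
        assert sums == {cfg.drill_working_length}

    def test_staircase_depths_reproduce_height_differences(
            self, slab_cutting_guide):
        _, plan, g = slab_cutting_guide
        # tube tops along -x: reach = standoff + L; deeper hole ->
        # shorter tube, exactly linearly
        reach = [r["outer_reach"] for r in g.tube_records]
        depths = [t.depth for t in plan.trajectories]
        for i in range(1, 3):
            assert reach[0] - reach[i] == pytest.approx(
                depths[i] - depths[0])

    def test_equal_depths_make_tube_tops_coplanar(self):
        bone = slab_bone()
        plan = slab_plan(depths=(20.0, 20.0, 20.0))
        g = design_cutting_guide(bone, plan, slab_footprint(bone), None,
                                 slab_kwires())
        tops = [np.asarray(r["entry"])[0] - r["outer_reach"]
                for r in g.tube_records]
        assert np.ptp(tops) < 1e-9

    def test_every_channel_is_unobstructed(self, slab_cutting_guide):
        bone, _, g = slab_cutting_guide
        for rec in g.channels():
            assert g.channel_is_through(rec)

    def test_material_exists_around_each_bore(self, slab_cutting_guide):
        _, _, g = slab_cutting_guide
        for rec in g.tube_records:
            e = np.asarray(rec["entry"])
            d = np.asarray(rec["direction"])
            mid = e - 0.5 * rec["outer_reach"] * d
            side = np.array([0.0, 0.0, 1.0])
            hits = ray_intersect(g.solid, mid, side, check_parity=False)
            assert hits, "tube wall missing"
            r_in = hits[0][0]
            assert abs(r_in - rec["inner_diameter"] / 2) < 0.2

    def test_guide_never_penetrates_bone(self, slab_cutting_guide):
        bone, _, g = slab_cutting_guide
        g.validate(bone)

    def test_channel_axes_survive_export_reimport(self, slab_cutting_guide,
                                                  tmp_path):
        bone, _, g = slab_cutting_guide
        export_guides([g], tmp_path)
        re = trimesh.load(tmp_path / "guide_cutting.stl", force="mesh")
        for rec in g.tube_records:
            e = np.asarray(rec["entry"])
            d = np.asarray(rec["direction"])
            mid = e - 0.5 * rec["outer_reach"] * d
            for side in (np.array([0.0, 0, 1.0]), np.array([0.0, 1.0, 0])):
                h1 = ray_intersect(re, mid, side, check_parity=False)
                h2 = ray_intersect(re, mid, -side, check_parity=False)
                assert h1 and h2
                # bore wall equidistant -> axis within 0.2 mm of plan
                assert abs(h1[0][0] - h2[0][0]) / 2 < 0.2

    def test_too_close_bores_rejected_with_pair(self):
        bone = slab_bone()
        plan = slab_plan(spacing=2.0)   # 2.0 mm < bore + wall
        with pytest.raises(ValueError, match=r"\(0, 1\)"):
            design_cutting_guide(bone, plan, slab_footprint(bone), None,
                                 slab_kwires())


@pytest.fixture(scope="module")
def slab_plate_pair():
    bone = slab_bone()
    stations = np.arange(-24.0, 25.0, 8.0)
    old = PlateModel.build_on_bone(bone, stations, aim=[0, 1, 0],
                                   role="in_situ", proximal_count=2)
    new = PlateModel.build_on_bone(bone, stations, aim=[0, 1, 0],
                                   role="new", proximal_count=2)
    return bone, old, new


class TestIntermediateGuide:
    def test_channel_counts_match_plate_and_wires(self, slab_plate_pair):
        bone, _, new = slab_plate_pair
        kw = slab_kwires()
        c = bone.triangles_center
        fp = (bone.face_normals[:, 0] < -0.9) | \
             ((bone.face_normals[:, 1] < -0.9) & (np.abs(c[:, 2]) < 27))
        g = design_intermediate_guide(bone, new, kw, footprint=fp)
        assert len(g.drill_records) == len(new.distal_hole_axes)
        assert len(g.kwire_records) == 3
        assert g.solid.is_watertight

    def test_kwire_axes_identical_across_guides(self, slab_cutting_guide,
                                                slab_plate_pair):
        _, _, g_cut = slab_cutting_guide
        bone, _, new = slab_plate_pair
        kw = slab_kwires()
        g_int = design_intermediate_guide(
            bone, new, kw, footprint=slab_footprint(bone))
        for a, b in zip(g_cut.kwire_records, g_int.kwire_records):
            assert np.allclose(a["entry"], b["entry"], atol=1e-6)
            assert np.allclose(a["direction"], b["direction"], atol=1e-6)

    def test_in_situ_plate_refused(self, slab_plate_pair):
        bone, old, _ = slab_plate_pair
        with pytest.raises(ValueError):
            design_intermediate_guide(bone, old, slab_kwires())


class TestRepositionGuide:
    def test_envelope_clears_plate_and_bone(self, slab_plate_pair):
        bone, _, new = slab_plate_pair
        g = design_reposition_guide(new, bone, slab_kwires())
        assert g.solid.is_watertight
        g.validate(bone)

    def test_new_plate_required(self, slab_plate_pair):
        bone, old, _ = slab_plate_pair
        with pytest.raises(ValueError):
            design_reposition_guide(old, bone, slab_kwires())


class TestSeatingPose:
    def wires(self):
        return [(np.array([0.0, 0, 0]), np.array([1.0, 0.1, 0]) / np.sqrt(1.01)),
                (np.array([0.0, 12, 0]), np.array([1.0, -0.1, 0]) / np.sqrt(1.01)),
                (np.array([0.0, 6, -10]), np.array([1.0, 0, 0.1]) / np.sqrt(1.01))]

    def test_planned_pose_solves_to_identity(self):
        w = self.wires()
        pts = np.array([e + s * d for e, d in w for s in (0.0, 20.0)])
        T = solve_seating_pose(pts, w)
        assert np.abs(T.matrix - np.eye(4)).max() < 1e-6

    def test_three_mm_perturbation_recovered(self):
        w = self.wires()
        pts = np.array([e + s * d for e, d in w for s in (0.0, 20.0)])
        P = RigidTransform.about_point(
            Rotation.from_euler("zxy", [2.0, -1.5, 1.0],
                                degrees=True).as_matrix(),
            pts.mean(axis=0), [3.0, -1.0, 2.0])
        seated = solve_seating_pose(P.apply(pts), w,
                                    body_wire_points=P.apply(pts))
        back = seated @ P
        assert np.abs(back.translation).max() < 0.2
        assert back.rotation_angle_deg() < 0.5

    def test_parallel_wires_leave_translation_free(self):
        d = np.array([1.0, 0, 0])
        w = [(np.array([0.0, 0, 0]), d), (np.array([0.0, 12, 0]), d),
             (np.array([0.0, 6, -10]), d)]
        pts = np.array([e + s * dd for e, dd in w for s in (0.0, 20.0)])
        with pytest.raises(ValueError, match="underdetermined"):
            solve_seating_pose(pts, w)

    def test_single_wire_underdetermined(self):
        w = self.wires()[:1]
        pts = np.array([e + s * d for e, d in w for s in (0.0, 20.0)])
        with pytest.raises(ValueError, match="underdetermined"):
            solve_seating_pose(pts, w)


class TestExportGuides:
    def test_manifest_tables_and_deterministic_checksums(
            self, slab_cutting_guide, tmp_path):
        _, plan, g = slab_cutting_guide
        m1 = export_guides([g], tmp_path / "a")
        m2 = export_guides([g], tmp_path / "b")
        assert m1["guides"][0]["sha256"] == m2["guides"][0]["sha256"]
        assert len(m1["guides"][0]["tubes"]) == len(plan.trajectories)
        written = json.loads((tmp_path / "a" / "manifest.json").read_text())
        assert written["guides"][0]["kind"] == "cutting"

    def test_reimport_reproduces_geometry_bit_identically(
            self, slab_cutting_guide, tmp_path):
        _, _, g = slab_cutting_guide
        export_guides([g], tmp_path)
        re = trimesh.load(tmp_path / "guide_cutting.stl", force="mesh",
                          process=False)
        assert len(re.faces) == len(g.solid.faces)
        assert g.solid.volume == pytest.approx(
            trimesh.Trimesh(re.vertices, re.faces).volume, rel=1e-6)

    def test_invalid_guide_blocks_export(self, tmp_path):
        bad = guides.GuideModel(trimesh.Trimesh(), "cutting")
        with pytest.raises(ValueError):
            export_guides([bad], tmp_path)
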
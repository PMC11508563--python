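import numpy as np
import pytest
import trimesh

from osteoplan import planning
from osteoplan.planning import (DrillTrajectory, FractureTrace, build_plan,
                                build_osteotomy_surface, compute_depth,
                                plan_trajectories, resample_trace)


def slab(thickness=30.0, width=60.0):
    """Flat bone stand-in: a slab whose faces are normal to x."""
    m = trimesh.creation.box(extents=[thickness, width, width])
    return m


def straight_trace(length=25.0, n=11):
    y = np.linspace(-length / 2, length / 2, n)
    pts = np.column_stack([np.full_like(y, -15.0), y, np.zeros_like(y)])
    return FractureTrace(pts)


class TestResampleTrace:
    def test_straight_segment_uniform_points(self):
        tr = FractureTrace([[0, 0, 0], [10, 0, 0]])
        rs = resample_trace(tr, 2.5)
        assert np.allclose(rs.points[:, 0], [0, 2.5, 5, 7.5, 10])

    def test_closed_circle_chords_equal(self):
        a = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        r = 10.0
        tr = FractureTrace(np.column_stack(
            [r * np.cos(a), r * np.sin(a), np.zeros_like(a)]), closed=True)
        rs = resample_trace(tr, 2.0)
        pts = np.vstack([rs.points, rs.points[:1]])
        chords = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        assert chords.std() / chords.mean() < 0.01

    def test_random_polyline_arc_length_preserved(self, rng):
        # smooth random curve: resampling preserves length when spacing
        # resolves the curvature
        t = np.linspace(0, 2 * np.pi, 200)
        a, b, c = rng.uniform(5, 12, 3)
        pts = np.column_stack([a * np.sin(t), b * np.cos(1.3 * t),
                               c * np.sin(0.7 * t + 1)])
        tr = FractureTrace(pts)
        rs = resample_trace(tr, 0.5)
        assert rs.arc_length() == pytest.approx(tr.arc_length(), rel=0.005)

    def test_endpoints_preserved(self, rng):
        pts = np.cumsum(rng.uniform(-1, 1, (10, 3)), axis=0) * 5
        rs = resample_trace(FractureTrace(pts), 2.0)
        assert np.allclose(rs.points[0], pts[0])
        assert np.allclose(rs.points[-1], pts[-1])

    def test_overlong_spacing_returns_endpoints_with_warning(self):
        tr = FractureTrace([[0, 0, 0], [5, 0, 0]])
        with pytest.warns(UserWarning):
            rs = resample_trace(tr, 50.0)
        assert len(rs.points) == 2

    def test_invalid_traces_rejected(self):
        with pytest.raises(ValueError):
            FractureTrace([[0, 0, 0]])
        with pytest.raises(ValueError):
            FractureTrace([[0, 0, 0], [0, 0, 0]])


class TestPlanTrajectories:
    def test_slab_fence_is_parallel_with_collinear_entries(self):
        trajs = plan_trajectories(slab(), straight_trace(), [1, 0, 0])
        dirs = np.array([t.direction for t in trajs])
        assert np.allclose(dirs, [1, 0, 0], atol=1e-9)
        entries = np.array([t.entry for t in trajs])
        assert np.allclose(entries[:, 0], -15.0, atol=1e-6)
        assert np.ptp(entries[:, 2]) < 1e-9

    def test_spacing_arithmetic_on_25mm_trace(self):
        trajs = plan_trajectories(slab(), straight_trace(), [1, 0, 0],
                                  spacing=2.5)
        assert len(trajs) == 11

    def test_miss_and_parallel_points_dropped_with_warning(self):
        pts = np.array([[-15.0, 0, 0], [-15.0, 2.5, 0], [-15.0, 200.0, 0]])
        with pytest.warns(UserWarning):
            trajs = plan_trajectories(slab(), FractureTrace(pts), [1, 0, 0],
                                      spacing=2.5)
        entries = np.array([t.entry for t in trajs])
        assert (np.abs(entries[:, 1]) <= 30.0 + 1e-6).all()

    def test_phantom_entries_on_surface_with_smooth_fan(self,
                                                       clean_case_coarse):
        from scipy.spatial import cKDTree
        case = clean_case_coarse
        trajs = plan_trajectories(case.intact, FractureTrace(case.trace),
                                  [1.0, 0, 0], fan_scale=1.0)
        assert len(trajs) >= 4
        tree = cKDTree(case.intact.vertices)
        d, _ = tree.query([t.entry for t in trajs])
        assert d.max() < 0.5
        dirs = np.array([t.direction for t in trajs])
        dots = np.einsum("ij,ij->i", dirs[:-1], dirs[1:])
        assert np.degrees(np.arccos(np.clip(dots, -1, 1))).max() < 15.0


class TestComputeDepth:
    def test_slab_depth_is_chord_minus_margin(self):
        t = DrillTrajectory([-15.0, 0, 0], [1, 0, 0], depth=1.0)
        assert compute_depth(slab(), t, 2.0) == pytest.approx(28.0, abs=0.05)

    def test_zero_margin_gives_full_chord(self):
        t = DrillTrajectory([-15.0, 5.0, 5.0], [1, 0, 0], depth=1.0)
        assert compute_depth(slab(), t, 0.0) == pytest.approx(30.0, abs=0.05)

    def test_thin_bone_flagged_too_shallow(self):
        thin = trimesh.creation.box(extents=[2.0, 40, 40])
        t = DrillTrajectory([-1.0, 0, 0], [1, 0, 0], depth=1.0)
        d = compute_depth(thin, t, 2.0)
        assert "too_shallow" in t.flags
        assert d <= 2.0

    def test_tip_never_reaches_exit_on_phantom(self, clean_case_coarse):
        from osteoplan.mesh_core import ray_intersect
        case = clean_case_coarse
        plan = build_plan(case.intact, FractureTrace(case.trace), [1.0, 0, 0])
        for t in plan.trajectories:
            hits = ray_intersect(case.intact, t.entry - t.direction,
                                 t.direction)
            exit_d = hits[1][0] - 1.0
            assert exit_d - t.depth >= plan.posterior_margin - 1e-6


class TestOsteotomySurface:
    def test_two_parallel_segments_rule_a_rectangle(self):
        a = DrillTrajectory([0, 0, 0], [1, 0, 0], depth=10.0)
        b = DrillTrajectory([0, 5.0, 0], [1, 0, 0], depth=10.0)
        surf = build_osteotomy_surface([a, b])
        assert surf.area == pytest.approx(50.0, abs=1e-9)

    def test_coplanar_fan_matches_shoelace_area(self):
        # three coplanar segments fanning in the xy-plane
        trajs = [DrillTrajectory([0, y, 0], d / np.linalg.norm(d), depth=10.0)
                 for y, d in [(0.0, np.array([1.0, 0, 0])),
                              (3.0, np.array([1.0, 0.2, 0])),
                              (6.0, np.array([1.0, 0.4, 0]))]]
        surf = build_osteotomy_surface(trajs)
        pts2 = np.vstack([[t.entry for t in trajs][::-1],
                          [t.tip for t in trajs]])[:, :2]
        x, y = pts2[:, 0], pts2[:, 1]
        shoelace = 0.5 * abs(np.dot(x, np.roll(y, -1))
                             - np.dot(y, np.roll(x, -1)))
        assert surf.area == pytest.approx(shoelace, rel=1e-6)

    def test_crossing_segments_rejected(self):
        a = DrillTrajectory([0, 0, 0], np.array([1.0, 0.3, 0]) / np.sqrt(1.09),
                            depth=20.0)
        b = DrillTrajectory([0, 2.0, 0],
                            np.array([1.0, -0.3, 0]) / np.sqrt(1.09),
                            depth=20.0)
        with pytest.raises(ValueError, match="cross"):
            build_osteotomy_surface([a, b])

    def test_phantom_cut_surface_tracks_true_interface(self,
                                                       clean_case_coarse):
        from scipy.spatial import cKDTree
        from osteoplan import phantom
        case = clean_case_coarse
        plan = build_plan(case.intact, FractureTrace(case.trace), [1.0, 0, 0])
        frag, _ = phantom.cut_components(case.spec)
        side = phantom.cut_side(case.spec, frag.triangles_center)
        iface = frag.submesh([np.flatnonzero(np.abs(side) < 0.6)], append=True)
        tree = cKDTree(iface.vertices)
        samp = np.vstack([plan.surface.vertices,
                          plan.surface.triangles_center])
        d, _ = tree.query(samp)
        assert d.max() < 1.5


class TestBuildPlan:
    def test_deterministic_rerun_bit_identical(self, clean_case_coarse):
        case = clean_case_coarse
        p1 = build_plan(case.intact, FractureTrace(case.trace), [1.0, 0, 0])
        p2 = build_plan(case.intact, FractureTrace(case.trace), [1.0, 0, 0])
        assert len(p1) == len(p2)
        for a, b in zip(p1.trajectories, p2.trajectories):
            assert (a.entry == b.entry).all()
            assert (a.direction == b.direction).all()
            assert a.depth == b.depth

    def test_finer_spacing_gives_more_trajectories(self, clean_case_coarse):
        case = clean_case_coarse
        n = [len(build_plan(case.intact, FractureTrace(case.trace),
                            [1.0, 0, 0], spacing=s))
             for s in (4.0, 2.5, 1.5)]
        assert n[0] < n[1] < n[2]

    def test_plan_roundtrips_through_json(self, clean_case_coarse, tmp_path):
        case = clean_case_coarse
        p = build_plan(case.intact, FractureTrace(case.trace), [1.0, 0, 0])
        path = tmp_path / "plan.json"
        planning.save_plan(p, path)
        p2 = planning.load_plan(path)
        assert len(p2) == len(p)
        assert p2.posterior_margin == p.posterior_margin
        for a, b in zip(p.trajectories, p2.trajectories):
            assert np.allclose(a.entry, b.entry)
            assert a.depth == b.depth


class TestPlanReduction:
    def test_already_anatomical_fragment_gives_identity(self,
                                                        clean_case_coarse):
        case = clean_case_coarse
        frag = case.intact.submesh(
            [np.flatnonzero(case.intact_labels["fragment"])], append=True)
        T = planning.plan_reduction(frag, frag)
        assert np.abs(T.matrix - np.eye(4)).max() < 1e-6

    def test_reduction_inverts_implanted_deformity(self, study_case_coarse):
        case = study_case_coarse
        frag_aff = case.affected.submesh(
            [np.flatnonzero(case.affected_labels["fragment"])], append=True)
        frag_tpl = case.intact.submesh(
            [np.flatnonzero(case.intact_labels["fragment"])], append=True)
        T = planning.plan_reduction(frag_aff, frag_tpl)
        # reduction composed with the implanted displacement ~ identity
        comp = T @ case.true_transform
        assert np.abs(comp.translation).max() < 0.2
        assert comp.rotation_angle_deg() < 0.5
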
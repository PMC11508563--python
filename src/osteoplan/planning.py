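"""Curved-osteotomy planning as depth-controlled drill trajectories.

A curved intra-articular cut cannot be made with an oscillating saw; it
can be made as a fence of parallel-ish drill holes along the old
fracture line, finished with an osteotome. Each trajectory carries a
planned in-bone depth so the drill stops short of the far (posterior)
cortex, protecting the neurovascular structures behind it. The ordered
trajectories rule a surface — the planned cut sheet.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation

from . import morphometry
from .mesh_core import ray_intersect
from .transforms import RigidTransform

__all__ = ["FractureTrace", "DrillTrajectory", "OsteotomyPlan",
           "resample_trace", "plan_trajectories", "compute_depth",
           "build_osteotomy_surface", "plan_reduction", "build_plan",
           "save_plan", "load_plan"]

DEFAULT_DRILL_DIAMETER = 1.8   # mm, the drill used through the guide
DEFAULT_SPACING = 2.5          # mm centre-to-centre along the trace
DEFAULT_POSTERIOR_MARGIN = 2.0  # mm of far cortex left undrilled


@dataclass(frozen=True)
class FractureTrace:
    """Ordered polyline on the bone surface marking the old fracture
    line (mm). ``closed`` joins the last point back to the first."""

    points: np.ndarray
    closed: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(pts) < 2:
            raise ValueError("a trace needs at least two points")
        if (np.linalg.norm(np.diff(pts, axis=0), axis=1) < 1e-12).any():
            raise ValueError("consecutive trace points must be distinct")
        object.__setattr__(self, "points", pts)

    @property
    def segments(self) -> np.ndarray:
        pts = self.points
        if self.closed:
            pts = np.vstack([pts, pts[:1]])
        return np.stack([pts[:-1], pts[1:]], axis=1)

    def arc_length(self) -> float:
        seg = self.segments
        return float(np.linalg.norm(seg[:, 1] - seg[:, 0], axis=1).sum())


@dataclass(frozen=True)
class DrillTrajectory:
    """One drill hole: entry on the bone surface, unit direction into
    the bone, planned in-bone depth and drill diameter (mm)."""

    entry: np.ndarray
    direction: np.ndarray
    depth: float
    diameter: float = DEFAULT_DRILL_DIAMETER
    flags: tuple = ()

    def __post_init__(self) -> None:
        e = np.asarray(self.entry, float).reshape(3)
        d = np.asarray(self.direction, float).reshape(3)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("trajectory direction must be nonzero")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        object.__setattr__(self, "entry", e)
        object.__setattr__(self, "direction", d / n)

    @property
    def tip(self) -> np.ndarray:
        return self.entry + self.depth * self.direction


@dataclass
class OsteotomyPlan:
    """Ordered drill fence plus the ruled cut surface it forms."""

    trajectories: list
    surface: trimesh.Trimesh
    posterior_margin: float = DEFAULT_POSTERIOR_MARGIN
    reduction: RigidTransform | None = None

    def __len__(self) -> int:
        return len(self.trajectories)


def resample_trace(trace: FractureTrace, spacing: float) -> FractureTrace:
    """Arc-length-uniform resampling; endpoints are preserved.

    If ``spacing`` exceeds the trace length the endpoints alone are
    returned with a warning.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    pts = trace.points
    if trace.closed:
        pts = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if spacing >= total:
        warnings.warn("spacing exceeds trace length; returning endpoints only",
                      stacklevel=2)
        return FractureTrace(np.vstack([pts[0], pts[-1]]), closed=False)
    n = int(round(total / spacing)) + 1
    si = np.linspace(0.0, total, n)
    out = np.column_stack([np.interp(si, s, pts[:, k]) for k in range(3)])
    if trace.closed:
        out = out[:-1]
    return FractureTrace(out, closed=trace.closed)


def _tangents(pts: np.ndarray, closed: bool) -> np.ndarray:
    ext = np.vstack([pts[-1:], pts, pts[:1]]) if closed else \
        np.vstack([pts[:1] * 2 - pts[1:2], pts, pts[-1:] * 2 - pts[-2:-1]])
    t = ext[2:] - ext[:-2]
    return t / np.linalg.norm(t, axis=1)[:, None]


def plan_trajectories(bone: trimesh.Trimesh, trace: FractureTrace,
                      approach: np.ndarray,
                      spacing: float = DEFAULT_SPACING,
                      diameter: float = DEFAULT_DRILL_DIAMETER,
                      max_tilt_deg: float = 30.0,
                      fan_scale: float = 1.0,
                      ) -> list[DrillTrajectory]:
    """One trajectory per resampled trace point.

    Each direction is the approach vector orthogonalised against the
    local trace tangent (so consecutive drill segments rule a smooth
    surface), then lightly smoothed along the fence; the entry is
    snapped onto the bone surface along the direction. Points are
    dropped with a warning when they are not drillable from the chosen
    approach: the orthogonalised direction tilts more than
    ``max_tilt_deg`` away from the approach (the trace runs parallel to
    it there), or the snap ray misses the bone. Depths are attached
    separately by :func:`compute_depth`.
    """
    approach = np.asarray(approach, float).reshape(3)
    approach = approach / np.linalg.norm(approach)
    # work on a finely resampled trace, then pick holes by arc length
    # PERPENDICULAR to the drill axes — that is the physical
    # centre-to-centre spacing; where the trace runs partly along the
    # approach, plain arc-length spacing would pinch adjacent bores
    fine = resample_trace(trace, min(spacing / 4.0, 1.0))
    tangents = _tangents(fine.points, fine.closed)
    cos_max = np.cos(np.radians(max_tilt_deg))

    dirs, pts = [], []
    dropped = 0
    for p, tg in zip(fine.points, tangents):
        d = approach - (approach @ tg) * tg
        nd = np.linalg.norm(d)
        if nd < 1e-9 or (d / nd) @ approach < cos_max:
            dropped += 1
            continue
        dirs.append(d / nd)
        pts.append(p)
    if dropped:
        warnings.warn(
            f"{dropped} trace points not drillable from this approach "
            f"(direction tilt over {max_tilt_deg:g} degrees); dropped",
            stacklevel=2)
    if not dirs:
        return []
    dirs = np.asarray(dirs)
    pts = np.asarray(pts)
    # 1-2-1 smoothing of the direction fan removes tangent-estimate
    # jitter without flattening the intended curvature
    if len(dirs) > 2:
        for _ in range(3):
            sm = dirs.copy()
            sm[1:-1] = 0.25 * dirs[:-2] + 0.5 * dirs[1:-1] + 0.25 * dirs[2:]
            dirs = sm / np.linalg.norm(sm, axis=1)[:, None]
    mean = dirs.mean(axis=0)
    mean /= np.linalg.norm(mean)
    if fan_scale < 1.0:
        # entries on a convex arc give a converging fan whose focus can
        # sit shallower than the drill depth; pulling the directions
        # toward the fence mean moves the focus out (0 = parallel fence)
        dirs = mean + fan_scale * (dirs - mean)
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]

    # greedy walk enforcing the perpendicular CHORD between holes: on a
    # curved trace the perpendicular arc overestimates the separation
    # of the straight, parallel bores
    picks = [0]
    for i in range(1, len(pts)):
        v = pts[i] - pts[picks[-1]]
        v_perp = v - (v @ mean) * mean
        if np.linalg.norm(v_perp) >= spacing - 1e-9:
            picks.append(i)

    # rate-limit the fan: successive tubes of a physical guide cannot
    # kink sharply, so clamp the per-hole direction change to 12 deg
    sel_dirs = [dirs[picks[0]]]
    max_step = np.radians(12.0)
    for i in picks[1:]:
        prev, cur = sel_dirs[-1], dirs[i]
        ang = np.arccos(np.clip(prev @ cur, -1.0, 1.0))
        if ang > max_step:
            axis = np.cross(prev, cur)
            axis /= np.linalg.norm(axis)
            cur = Rotation.from_rotvec(axis * max_step).apply(prev)
        sel_dirs.append(cur)

    out: list[DrillTrajectory] = []
    for i, d in zip(picks, sel_dirs):
        p = pts[i]
        # cast from well outside so the snap also works for points
        # slightly inside or off the surface
        start = p - 30.0 * d
        hits = ray_intersect(bone, start, d)
        if not hits:
            warnings.warn(f"trace point {p.round(2)} misses the bone; dropped",
                          stacklevel=2)
            continue
        entry = start + hits[0][0] * d
        if np.linalg.norm(entry - p) > 25.0:
            warnings.warn(f"trace point {p.round(2)} snapped implausibly far; "
                          "dropped", stacklevel=2)
            continue
        out.append(DrillTrajectory(entry, d, depth=1.0, diameter=diameter))
    return out


def compute_depth(bone: trimesh.Trimesh, traj: DrillTrajectory,
                  posterior_margin: float = DEFAULT_POSTERIOR_MARGIN) -> float:
    """Planned drilling depth: distance from entry to the far-cortex
    exit along the trajectory, minus the posterior safety margin.

    Uses the first in/out crossing pair of the ray from the entry; the
    returned depth never reaches the exit and is clamped to >= 1 mm.
    A trajectory whose in-bone path is shorter than ``margin + 1`` mm
    is flagged ``too_shallow``.
    """
    if posterior_margin < 0:
        raise ValueError("posterior margin cannot be negative")
    start = traj.entry - 1.0 * traj.direction
    hits = ray_intersect(bone, start, traj.direction)
    if len(hits) < 2:
        raise ValueError("trajectory does not enter the bone")
    exit_d = hits[1][0] - 1.0   # distance from entry to far-cortex exit
    depth = exit_d - posterior_margin
    if depth < 1.0:
        object.__setattr__(traj, "flags", traj.flags + ("too_shallow",))
        depth = min(1.0, max(exit_d - 0.1, 0.1))
    return float(depth)


def build_osteotomy_surface(trajs: list[DrillTrajectory]) -> trimesh.Trimesh:
    """Ruled surface through the ordered drill segments (entry -> tip).

    Plans whose consecutive segments cross are rejected: the cut would
    self-intersect.
    """
    if len(trajs) < 2:
        raise ValueError("need at least two trajectories")
    entries = np.array([t.entry for t in trajs])
    tips = np.array([t.tip for t in trajs])
    for i in range(len(trajs) - 1):
        if _segments_cross(entries[i], tips[i], entries[i + 1], tips[i + 1]):
            raise ValueError(f"drill segments {i} and {i + 1} cross; "
                             "cut surface would self-intersect")
    verts = np.vstack([entries, tips])
    n = len(trajs)
    faces = []
    for i in range(n - 1):
        a, b = i, i + 1
        faces.append([a, b, n + a])
        faces.append([b, n + b, n + a])
    return trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)


def _segments_cross(a0, a1, b0, b1, tol: float = 1e-9) -> bool:
    """True if segment a and b intersect at interior points (the shared
    ruled-quad edge case of touching endpoints is fine)."""
    da, db = a1 - a0, b1 - b0
    r = b0 - a0
    n = np.cross(da, db)
    n2 = n @ n
    if n2 < tol:   # parallel segments never cross transversally
        return False
    t = np.cross(r, db) @ n / n2
    u = np.cross(r, da) @ n / n2
    gap = np.linalg.norm((a0 + t * da) - (b0 + u * db))
    return (0.02 < t < 0.98) and (0.02 < u < 0.98) and gap < 0.05


def plan_reduction(fragment: trimesh.Trimesh,
                   template_fragment: trimesh.Trimesh) -> RigidTransform:
    """Planned reduction: the rigid transform bringing the osteotomised
    fragment onto its anatomical (mirrored-template) position."""
    res = morphometry.fit_fragment_transform(fragment, template_fragment)
    return res.transform


def build_plan(bone: trimesh.Trimesh, trace: FractureTrace,
               approach: np.ndarray,
               spacing: float = DEFAULT_SPACING,
               diameter: float = DEFAULT_DRILL_DIAMETER,
               posterior_margin: float = DEFAULT_POSTERIOR_MARGIN,
               fan_scale: float = 0.0,
               ) -> OsteotomyPlan:
    """Full planning pass: trajectories along the trace, per-hole depth
    control, ruled cut surface.

    The default fence is parallel (``fan_scale=0``): all drills share
    the mean orthogonalised direction, which is what keeps the guide
    tubes from converging above the bone — the classic panpipe profile.
    A positive ``fan_scale`` lets the directions follow the local trace
    tangent instead; if the fanned drill segments would then cross at
    full depth, the fan is deterministically narrowed (halved each
    pass, parallel in the limit) until the ruled surface is valid.
    """
    fan = fan_scale
    for _ in range(8):
        trajs = plan_trajectories(bone, trace, approach, spacing, diameter,
                                  fan_scale=fan)
        if len(trajs) < 2:
            raise ValueError("fewer than two usable trajectories")
        trajs = [
            DrillTrajectory(t.entry, t.direction,
                            compute_depth(bone, t, posterior_margin),
                            t.diameter, t.flags)
            for t in trajs]
        entries = [t.entry for t in trajs]
        tips = [t.tip for t in trajs]
        crossing = any(
            _segments_cross(entries[i], tips[i], entries[i + 1], tips[i + 1])
            for i in range(len(trajs) - 1))
        if not crossing:
            break
        fan *= 0.5
    surface = build_osteotomy_surface(trajs)
    return OsteotomyPlan(trajs, surface, posterior_margin)


def save_plan(plan: OsteotomyPlan, path) -> None:
    data = {
        "posterior_margin_mm": plan.posterior_margin,
        "trajectories": [
            {"entry_mm": t.entry.tolist(), "direction": t.direction.tolist(),
             "depth_mm": t.depth, "diameter_mm": t.diameter,
             "flags": list(t.flags)}
            for t in plan.trajectories],
        "reduction": None if plan.reduction is None
        else plan.reduction.matrix.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def load_plan(path) -> OsteotomyPlan:
    with open(path) as fh:
        data = json.load(fh)
    trajs = [DrillTrajectory(np.array(t["entry_mm"]), np.array(t["direction"]),
                             t["depth_mm"], t["diameter_mm"],
                             tuple(t.get("flags", ())))
             for t in data["trajectories"]]
    surface = build_osteotomy_surface(trajs) if len(trajs) >= 2 else None
    plan = OsteotomyPlan(trajs, surface, data["posterior_margin_mm"])
    if data.get("reduction") is not None:
        plan.reduction = RigidTransform.from_matrix(np.array(data["reduction"]))
    return plan
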
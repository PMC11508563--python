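"""Printable surgical-guide solids for the curved-osteotomy workflow.

Three guides share one set of K-wire reference trajectories so each can
be seated in exactly the pose the previous one defined:

* the **cutting guide** — a bone-conforming shell carrying one drill
  tube per planned trajectory. Tube lengths are tailored per hole
  (``working length = standoff + tube + depth``), so a fixed-length
  drill inserted to its stop reaches exactly the planned depth: the
  Panflute profile. Extensions over the anterior shaft and over the
  in-situ plate give it a unique seating;
* the **intermediate guide** — replicates the *new* plate's distal
  screw-hole axes so they can be predrilled while exposure is good;
* the **reposition guide** — a negative imprint of the new plate
  (which is fixed to the osteotomised fragment through the old proximal
  screw holes); seating it on the K-wires steers the fragment to the
  planned pose.

All solids are produced by voxel CSG and are watertight by
construction; every drill/K-wire hole is audited as an unobstructed
through-channel.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation

from . import csg
from .mesh_core import (make_tube, patch_samples, ray_intersect,
                        check_printable)
from .transforms import RigidTransform

__all__ = ["GuideConfig", "KWireSet", "PlateModel", "GuideModel",
           "panflute_tube_length", "design_cutting_guide",
           "design_intermediate_guide", "design_reposition_guide",
           "export_guides", "solve_seating_pose", "default_kwires",
           "intermediate_footprint",
           "cutting_footprint", "shaft_footprint"]


@dataclass(frozen=True)
class GuideConfig:
    """Print/fit tolerances and guide dimensions (mm). Channel bores get
    the drill/wire diameter plus a print clearance; shells float a fit
    clearance off bone and plate, common FDM/SLS practice."""

    fit_clearance: float = 0.2
    channel_clearance: float = 0.1
    shell_thickness: float = 3.0
    tube_outer_d: float = 5.0
    base_standoff: float = 3.2        # bone entry -> tube base, along the axis
    drill_working_length: float = 60.0
    kwire_diameter: float = 2.0
    min_tube_length: float = 3.0
    min_bore_wall: float = 0.5
    csg_pitch: float = 0.3            # signed-field CSG is sub-voxel accurate


@dataclass(frozen=True)
class KWireSet:
    """Shared K-wire reference trajectories (default three wires)."""

    entries: np.ndarray
    directions: np.ndarray
    diameter: float = 2.0

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, float).reshape(-1, 3)
        d = np.asarray(self.directions, float).reshape(-1, 3)
        if len(e) != len(d) or len(e) == 0:
            raise ValueError("need matching nonempty entries/directions")
        d = d / np.linalg.norm(d, axis=1)[:, None]
        for i in range(len(e)):
            for j in range(i + 1, len(e)):
                parallel = abs(d[i] @ d[j]) > 0.999
                if parallel and np.linalg.norm(e[i] - e[j]) < 5.0:
                    raise ValueError(
                        f"wires {i} and {j} are parallel and closer than 5 mm: "
                        "seating would be ambiguous")
        object.__setattr__(self, "entries", e)
        object.__setattr__(self, "directions", d)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class PlateModel:
    """Parametric slab plate swept on the bone surface.

    Stands in for the proprietary anatomical plate: a strip of given
    width/thickness following a surface centerline, with ordered screw
    holes along it. ``role`` distinguishes the in-situ (old) plate from
    the new one; old and new share the proximal hole pattern so the new
    plate can reuse the old proximal screw holes in the fragment.
    """

    centerline: np.ndarray            # (m, 3) points on the bone surface
    normals: np.ndarray               # (m, 3) outward surface normals
    width: float = 14.0
    thickness: float = 4.0
    hole_stations: tuple = ()         # indices into the centerline
    hole_diameter: float = 3.5
    role: str = "in_situ"             # "in_situ" | "new"
    proximal_count: int = 2           # first N stations are proximal holes

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, float).reshape(-1, 3)
        self.normals = np.asarray(self.normals, float).reshape(-1, 3)
        self.normals /= np.linalg.norm(self.normals, axis=1)[:, None]
        if self.role not in ("in_situ", "new"):
            raise ValueError("role must be in_situ or new")

    @property
    def hole_axes(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(surface point, into-bone direction) per screw hole."""
        return [(self.centerline[i].copy(), -self.normals[i].copy())
                for i in self.hole_stations]

    @property
    def distal_hole_axes(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return self.hole_axes[self.proximal_count:]

    @property
    def proximal_hole_axes(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return self.hole_axes[:self.proximal_count]

    def solid(self, pitch: float = 0.3) -> trimesh.Trimesh:
        """Slab solid: oriented boxes swept along the centerline, screw
        holes drilled through."""
        boxes = []
        for a, b, na, nb in zip(self.centerline[:-1], self.centerline[1:],
                                self.normals[:-1], self.normals[1:]):
            mid = 0.5 * (a + b)
            n = 0.5 * (na + nb)
            n /= np.linalg.norm(n)
            axis = b - a
            L = np.linalg.norm(axis)
            axis /= L
            lat = np.cross(n, axis)
            lat /= np.linalg.norm(lat)
            R = np.column_stack([lat, n, axis])
            box = trimesh.creation.box(
                extents=[self.width, self.thickness, L + 2.0])
            m = np.eye(4)
            m[:3, :3] = R
            m[:3, 3] = mid + n * (self.thickness / 2.0)
            box.apply_transform(m)
            boxes.append(box)
        # hole cylinders run outward from inside the bone through the slab
        holes = [make_tube(p + d * 2.0, -d, self.thickness + 6.0, 0.0,
                           self.hole_diameter) for p, d in self.hole_axes]
        return csg.compose(boxes, holes, pitch=pitch)

    @classmethod
    def build_on_bone(cls, bone: trimesh.Trimesh, z_stations: np.ndarray,
                      aim: np.ndarray, hole_every: int = 1, **kw) -> "PlateModel":
        """Sweep a plate over the bone: for each z station cast a ray
        from outside along ``aim`` and take the first surface hit."""
        aim = np.asarray(aim, float)
        aim /= np.linalg.norm(aim)
        center = bone.bounds.mean(axis=0)
        pts, nrms = [], []
        # proximal (cranial) stations first: the "first N are proximal"
        # hole labelling then holds regardless of caller ordering
        z_stations = np.sort(np.asarray(z_stations, float))[::-1]
        for z in z_stations:
            start = np.array([center[0], center[1], z]) - 80.0 * aim
            start[2] = z
            hits = ray_intersect(bone, start, aim)
            if not hits:
                continue
            d, fidx = hits[0]
            pts.append(start + d * aim)
            nrms.append(bone.face_normals[fidx])
        if len(pts) < 2:
            raise ValueError("plate centerline needs at least two stations")
        kw.setdefault("hole_stations", tuple(range(0, len(pts), hole_every)))
        return cls(np.asarray(pts), np.asarray(nrms), **kw)


@dataclass
class GuideModel:
    """A printable guide: solid plus the audit records of its channels."""

    solid: trimesh.Trimesh
    kind: str                                  # cutting|intermediate|reposition
    tube_records: list = dfield(default_factory=list)
    drill_records: list = dfield(default_factory=list)
    kwire_records: list = dfield(default_factory=list)
    config: GuideConfig = dfield(default_factory=GuideConfig)

    def channels(self) -> list[dict]:
        return self.tube_records + self.drill_records + self.kwire_records

    def channel_is_through(self, rec: dict, span_pad: float = 1.0) -> bool:
        """A hole is a through-channel when the axis segment from just
        above the guide to the bone entry meets no guide material."""
        entry = np.asarray(rec["entry"])
        d = np.asarray(rec["direction"])
        top = entry - rec["outer_reach"] * d
        hits = ray_intersect(self.solid, top - span_pad * d, d,
                             check_parity=False)
        span = rec["outer_reach"] + span_pad - 0.05
        return not any(h[0] < span for h in hits)

    def validate(self, bone: trimesh.Trimesh | None = None) -> None:
        check_printable(self.solid)
        bodies = self.solid.body_count
        if bodies != 1:
            raise ValueError(f"guide solid is {bodies} disconnected pieces")
        for rec in self.channels():
            if not self.channel_is_through(rec):
                raise ValueError(f"obstructed channel: {rec}")
        if bone is not None:
            # 0.4 mm is plenty for a 1 mm^3 interpenetration audit
            inter = csg.voxel_boolean(self.solid, bone, "intersection",
                                      pitch=0.4)
            if len(inter.faces) and inter.volume > 1.0:
                raise ValueError(
                    f"guide intersects bone by {inter.volume:.2f} mm^3")


def panflute_tube_length(drill_working_length: float, depth: float,
                         base_standoff: float,
                         min_tube_length: float = 3.0) -> float:
    """Tube length for one hole: ``working length - depth - standoff``.

    A drill of fixed working length inserted until its stop meets the
    tube top then protrudes exactly ``depth`` into the bone. Tubes
    shorter than ``min_tube_length`` are unprintable/unstable, so the
    precondition is enforced with the drill length that would be
    required.
    """
    L = drill_working_length - depth - base_standoff
    if L < min_tube_length:
        need = depth + base_standoff + min_tube_length
        raise ValueError(
            f"drill working length {drill_working_length:g} mm too short for "
            f"depth {depth:g} mm: needs >= {need:g} mm")
    return float(L)


def _merge_bounds(bounds_list):
    return np.array([
        np.min([b[0] for b in bounds_list], axis=0),
        np.max([b[1] for b in bounds_list], axis=0)])


def _shell_field(bone, footprint, clearance, thickness, pitch):
    """Offset-shell contribution for :func:`csg.compose`, plus the
    world bounds it needs the grid to cover."""
    face_idx = np.flatnonzero(np.asarray(footprint, bool)) \
        if np.asarray(footprint).dtype == bool else np.asarray(footprint)
    samples, normals = patch_samples(bone, face_idx, max_edge=0.8 * pitch)
    pad = clearance + thickness + 2 * pitch
    bounds = np.array([samples.min(axis=0) - pad, samples.max(axis=0) + pad])

    def field(origin, shape, p):
        return csg.offset_band_field(samples, normals, origin, shape, p,
                                     clearance, thickness)

    return field, bounds


def _channel(entry, direction, outer_reach, inner_reach, diameter):
    """Cylinder used to drill a channel out of a guide solid: runs from
    ``outer_reach`` above the bone entry down to ``inner_reach`` short
    of/into it."""
    entry = np.asarray(entry, float)
    direction = np.asarray(direction, float)
    start = entry - outer_reach * direction
    return make_tube(start, direction, outer_reach + inner_reach, 0.0, diameter)


def _faces_near_points(mesh: trimesh.Trimesh, points: np.ndarray,
                       radius: float) -> np.ndarray:
    from scipy.spatial import cKDTree
    tree = cKDTree(np.asarray(points, float).reshape(-1, 3))
    d, _ = tree.query(mesh.triangles_center)
    return d <= radius


def cutting_footprint(bone: trimesh.Trimesh, entries: np.ndarray,
                      radius: float = 9.0,
                      shaft_extension_z: float = -55.0,
                      plate: PlateModel | None = None) -> np.ndarray:
    """Default cutting-guide footprint: bone faces around the drill
    entries, a connected strip down the anterior shaft (distal to the
    tuberosity) for unique seating, and — when an in-situ plate is
    referenced — the faces under/around it so the base meets the
    plate-conforming extension."""
    entries = np.asarray(entries, float).reshape(-1, 3)
    near = _faces_near_points(bone, entries, radius)
    c = bone.triangles_center
    n = bone.face_normals
    # run the strip up to the drill field so the footprint is connected
    z_top = entries[:, 2].min() + 4.0
    anterior = (n[:, 0] < -0.55) & (c[:, 2] > shaft_extension_z) \
        & (c[:, 2] < z_top)
    out = near | anterior
    if plate is not None:
        out |= _faces_near_points(bone, plate.centerline,
                                  plate.width / 2.0 + 4.0)
    return out


def shaft_footprint(bone: trimesh.Trimesh,
                    z_range: tuple = (-70.0, -25.0)) -> np.ndarray:
    c = bone.triangles_center
    n = bone.face_normals
    return (n[:, 0] < -0.35) & (c[:, 2] > z_range[0]) & (c[:, 2] < z_range[1])


def intermediate_footprint(bone: trimesh.Trimesh, new_plate: PlateModel,
                           kwires: KWireSet) -> np.ndarray:
    """Footprint for the predrill guide: an anterolateral wrap that
    spans from the K-wire entry field down over the plate's distal
    screw-hole region, so one connected shell carries both channel
    sets."""
    distal_pts = np.array([p for p, _ in new_plate.distal_hole_axes])
    anchor_pts = np.vstack([distal_pts, kwires.entries])
    near = _faces_near_points(bone, anchor_pts, 10.0)
    c = bone.triangles_center
    n = bone.face_normals
    z_lo = distal_pts[:, 2].min() - 8.0
    z_hi = kwires.entries[:, 2].max() + 8.0
    band = (c[:, 2] > z_lo) & (c[:, 2] < z_hi) & (c[:, 1] < 5.0) \
        & ((n[:, 0] < -0.25) | (n[:, 1] < -0.25)) & (n[:, 2] < 0.7)
    return near | band


def default_kwires(bone: trimesh.Trimesh, entries_hint: np.ndarray,
                   diameter: float = 2.0) -> KWireSet:
    """Three reference wires fanned through the anterolateral
    metaphysis, placed relative to the planned drill fence and close to
    the proximal end of the plate so every guide in the sequence can
    reach them."""
    entries_hint = np.asarray(entries_hint, float)
    lo = entries_hint.mean(axis=0)
    # three stations below the drill field, each aimed from an
    # anterolateral stance at the shaft axis: entries land on bone by
    # construction and the approach angles differ (unique seating)
    stations = lo[2] + np.array([-12.0, -19.0, -26.0])
    stance_y = lo[1] - 6.0
    targets_y = np.array([3.0, -3.0, 0.0])
    pts, dd = [], []
    for z, ty in zip(stations, targets_y):
        start = np.array([lo[0] - 25.0, stance_y, z])
        d = np.array([0.0, ty, z]) - start
        d = d / np.linalg.norm(d)
        hits = ray_intersect(bone, start, d)
        if not hits:
            raise ValueError("K-wire ray misses the bone")
        pts.append(start + hits[0][0] * d)
        dd.append(d)
    return KWireSet(np.asarray(pts), np.asarray(dd), diameter)


def _bore_conflicts(axes: list, min_gap: float) -> list[tuple[int, int]]:
    """Pairs of channel axes whose bores come closer than ``min_gap``
    (outer tube walls may merge — that is the panpipe look — but bores
    must keep a wall between them)."""
    bad = []
    for i in range(len(axes)):
        ei, di, Li, ri = axes[i]
        for j in range(i + 1, len(axes)):
            ej, dj, Lj, rj = axes[j]
            d = _segment_distance(ei, ei + Li * di, ej, ej + Lj * dj)
            if d < ri + rj + min_gap:
                bad.append((i, j))
    return bad


def _segment_distance(a0, a1, b0, b1):
    # closest distance between two segments
    da, db = a1 - a0, b1 - b0
    r = a0 - b0
    A, B, C = da @ da, da @ db, db @ db
    D, E = da @ r, db @ r
    den = A * C - B * B
    s = np.clip((B * E - C * D) / den, 0, 1) if den > 1e-12 else 0.0
    t = np.clip((A * E - B * D) / den, 0, 1) if den > 1e-12 else \
        np.clip(E / C, 0, 1)
    # refine once holding the other fixed
    s = np.clip((B * t - D) / A, 0, 1) if A > 1e-12 else s
    t = np.clip((B * s + E) / C, 0, 1) if C > 1e-12 else t
    return float(np.linalg.norm(a0 + s * da - (b0 + t * db)))


def design_cutting_guide(bone: trimesh.Trimesh, plan,
                         footprint: np.ndarray,
                         plate: PlateModel | None,
                         kwires: KWireSet,
                         config: GuideConfig = GuideConfig()) -> GuideModel:
    """Panflute cutting guide.

    Base shell over the footprint (drill field + anterior shaft strip),
    a conforming extension over the in-situ plate, one depth-tailored
    tube per trajectory, and the K-wire reference channels. Bores
    closer than drill diameter + minimum wall are rejected (the outer
    tube walls are allowed — expected — to merge).
    """
    trajs = plan.trajectories
    if plate is not None and plate.role != "in_situ":
        raise ValueError("cutting guide references the in-situ plate")
    entries = np.array([t.entry for t in trajs])
    if not footprint.any():
        raise ValueError("empty footprint")

    # per-hole Panflute tube lengths
    tubes, tube_records, bores = [], [], []
    for i, t in enumerate(trajs):
        L = panflute_tube_length(config.drill_working_length, t.depth,
                                 config.base_standoff, config.min_tube_length)
        outer_reach = config.base_standoff + L
        tubes.append(make_tube(t.entry, -t.direction, outer_reach,
                               0.0, config.tube_outer_d))
        bore_d = t.diameter + config.channel_clearance
        bores.append((t.entry - outer_reach * t.direction, t.direction,
                      outer_reach + 0.5, bore_d / 2.0))
        tube_records.append({
            "index": i, "tube_length": L, "outer_reach": outer_reach,
            "inner_diameter": bore_d, "outer_diameter": config.tube_outer_d,
            "entry": t.entry.tolist(), "direction": t.direction.tolist(),
            "depth": t.depth})
    conflicts = _bore_conflicts(bores, config.min_bore_wall)
    if conflicts:
        raise ValueError(f"drill bores too close (need "
                         f"{config.min_bore_wall} mm wall): pairs {conflicts}")

    # shell sits half a voxel beyond the carved clearance zone so the
    # two surfaces never coincide exactly (knife-edge membranes)
    shell_field, shell_bounds = _shell_field(
        bone, footprint, config.fit_clearance + 0.5 * config.csg_pitch,
        config.shell_thickness, config.csg_pitch)
    add = list(tubes)
    subtract = []
    subtract_dilated = [(bone, config.fit_clearance)]
    if plate is not None:
        plate_solid = plate.solid(pitch=config.csg_pitch)
        cover = csg.inflate(plate_solid,
                            config.fit_clearance + config.shell_thickness,
                            pitch=config.csg_pitch)
        add.append(cover)
        subtract_dilated.append((plate_solid, config.fit_clearance))
    bounds = _merge_bounds([m.bounds for m in add] + [shell_bounds])

    drill_channels = [
        _channel(t.entry, t.direction, rec["outer_reach"] + 1.0, 2.0,
                 rec["inner_diameter"])
        for t, rec in zip(trajs, tube_records)]
    kwire_records = []
    kwire_channels = []
    for k in range(len(kwires)):
        e, d = kwires.entries[k], kwires.directions[k]
        reach = config.base_standoff + config.shell_thickness + 12.0
        kwire_channels.append(_channel(
            e, d, reach, 2.0, kwires.diameter + config.channel_clearance))
        kwire_records.append({
            "index": k, "entry": e.tolist(), "direction": d.tolist(),
            "diameter": kwires.diameter + config.channel_clearance,
            "outer_reach": reach})
    subtract += drill_channels + kwire_channels

    solid = csg.compose(add, subtract, pitch=config.csg_pitch,
                        subtract_dilated=subtract_dilated,
                        add_fields=[shell_field], bounds=bounds)
    return GuideModel(solid, "cutting", tube_records=tube_records,
                      kwire_records=kwire_records, config=config)


def design_intermediate_guide(bone: trimesh.Trimesh, new_plate: PlateModel,
                              kwires: KWireSet,
                              footprint: np.ndarray | None = None,
                              config: GuideConfig = GuideConfig()) -> GuideModel:
    """Predrill guide for the new plate's distal screw holes, seated on
    the shared K-wires."""
    if new_plate.role != "new":
        raise ValueError("intermediate guide predrills the NEW plate holes")
    distal = new_plate.distal_hole_axes
    if not distal:
        raise ValueError("new plate has no distal holes labelled")
    if footprint is None:
        footprint = intermediate_footprint(bone, new_plate, kwires)
    shell_field, shell_bounds = _shell_field(
        bone, footprint, config.fit_clearance + 0.5 * config.csg_pitch,
        config.shell_thickness, config.csg_pitch)
    shell_reach = config.fit_clearance + config.shell_thickness + 1.0

    drill_records, channels = [], []
    for i, (p, d) in enumerate(distal):
        channels.append(_channel(p, d, shell_reach + 1.0, 2.0,
                                 new_plate.hole_diameter
                                 + config.channel_clearance))
        drill_records.append({
            "index": i, "entry": p.tolist(), "direction": d.tolist(),
            "diameter": new_plate.hole_diameter + config.channel_clearance,
            "outer_reach": shell_reach + 1.0})
    kwire_records, kchan = [], []
    for k in range(len(kwires)):
        e, d = kwires.entries[k], kwires.directions[k]
        reach = shell_reach + 12.0
        kchan.append(_channel(e, d, reach, 2.0,
                              kwires.diameter + config.channel_clearance))
        kwire_records.append({
            "index": k, "entry": e.tolist(), "direction": d.tolist(),
            "diameter": kwires.diameter + config.channel_clearance,
            "outer_reach": reach})
    solid = csg.compose([], channels + kchan, pitch=config.csg_pitch,
                        subtract_dilated=[(bone, config.fit_clearance)],
                        add_fields=[shell_field], bounds=shell_bounds)
    return GuideModel(solid, "intermediate", drill_records=drill_records,
                      kwire_records=kwire_records, config=config)


def design_reposition_guide(new_plate: PlateModel,
                            bone_planned: trimesh.Trimesh,
                            kwires: KWireSet,
                            config: GuideConfig = GuideConfig()) -> GuideModel:
    """Reposition guide: a shell enveloping the new plate (negative
    imprint at fit clearance) carrying the K-wire channels.

    With the plate screwed to the fragment, seating this guide on the
    in-situ K-wires forces the fragment into the planned pose; the
    pose-from-constraints solve (:func:`solve_seating_pose`) verifies
    in software that the seating is unique.
    """
    if new_plate.role != "new":
        raise ValueError("reposition guide envelops the NEW plate")
    plate_solid = new_plate.solid(pitch=config.csg_pitch)
    cover = csg.inflate(plate_solid,
                        config.fit_clearance + config.shell_thickness,
                        pitch=config.csg_pitch)
    kwire_records, kchan = [], []
    for k in range(len(kwires)):
        e, d = kwires.entries[k], kwires.directions[k]
        # long enough to pierce the bridge hull wherever it bulges
        reach = 35.0
        kchan.append(_channel(e, d, reach, 2.0,
                              kwires.diameter + config.channel_clearance))
        kwire_records.append({
            "index": k, "entry": e.tolist(), "direction": d.tolist(),
            "diameter": kwires.diameter + config.channel_clearance,
            "outer_reach": reach})
    # bridge body: convex hull spanning the wire collars and the plate's
    # proximal end, so the envelope and the wire seats form one solid.
    # Elbow anchors — straight wire-to-plate segments re-projected a few
    # mm off the bone surface — make the hull wrap convex corners
    # instead of passing through the carved bone zone.
    hull_pts = [kwires.entries, kwires.entries - 16.0 * kwires.directions]
    prox = new_plate.centerline[:3]
    prox_n = new_plate.normals[:3]
    lat = np.cross(prox_n, [0.0, 0.0, 1.0])
    lat /= np.linalg.norm(lat, axis=1)[:, None]
    plate_outer = []
    for s in (-1.0, 1.0):
        pts = prox + prox_n * (new_plate.thickness + 3.0) \
            + s * lat * (new_plate.width / 2.0)
        hull_pts.append(pts)
        plate_outer.append(pts)
    from scipy.spatial import cKDTree
    surf_pts, surf_nrm = patch_samples(
        bone_planned, np.arange(len(bone_planned.faces)), max_edge=3.0)
    surf_tree = cKDTree(surf_pts)
    wire_outer = kwires.entries - 16.0 * kwires.directions
    elbows = []
    for w in wire_outer:
        for p in np.vstack(plate_outer):
            for lam in (0.25, 0.5, 0.75):
                s = (1 - lam) * w + lam * p
                _, si = surf_tree.query(s)
                elbows.append(surf_pts[si] + surf_nrm[si]
                              * (config.fit_clearance
                                 + config.shell_thickness + 4.0))
    hull_pts.append(np.asarray(elbows))
    bridge = trimesh.convex.convex_hull(np.vstack(hull_pts))
    solid = csg.compose(
        [cover, bridge], kchan, pitch=config.csg_pitch,
        subtract_dilated=[(plate_solid, config.fit_clearance),
                          (bone_planned, config.fit_clearance)])
    return GuideModel(solid, "reposition", kwire_records=kwire_records,
                      config=config)


def solve_seating_pose(body_points: np.ndarray,
                       wire_lines: list[tuple[np.ndarray, np.ndarray]],
                       body_wire_points: np.ndarray | None = None,
                       contact_points: np.ndarray | None = None,
                       contact_normals: np.ndarray | None = None,
                       contact_targets: np.ndarray | None = None,
                       max_iter: int = 50) -> RigidTransform:
    """Rigid pose that seats a body on line (K-wire) and surface
    (plate-contact) constraints, by Gauss-Newton least squares.

    ``body_wire_points`` are two points per wire fixed on the body that
    must land on the corresponding world line; contact points must land
    on their target planes. Raises if the constraint system leaves a
    rigid degree of freedom free (underdetermined seating).
    """
    if body_wire_points is None:
        body_wire_points = np.array(
            [e + s * d for (e, d) in wire_lines for s in (0.0, 20.0)])
    T = RigidTransform.identity()
    for _ in range(max_iter):
        J_blocks, r_blocks = [], []
        for w, (e, d) in enumerate(wire_lines):
            P = np.eye(3) - np.outer(d, d)
            for p in body_wire_points[2 * w:2 * w + 2]:
                pc = T.apply(p)
                r = P @ (pc - e)
                Jw = P @ (-_skew(pc))
                J_blocks.append(np.hstack([Jw, P]))
                r_blocks.append(r)
        if contact_points is not None:
            for p, n, q in zip(contact_points, contact_normals,
                               contact_targets):
                pc = T.apply(p)
                r = np.array([n @ (pc - q)])
                Jw = (n @ (-_skew(pc)))[None, :]
                J_blocks.append(np.hstack([Jw, n[None, :]]))
                r_blocks.append(r)
        J = np.vstack(J_blocks)
        r = np.concatenate(r_blocks)
        JTJ = J.T @ J
        sv = np.linalg.svd(JTJ, compute_uv=False)
        if sv[-1] < 1e-6 * max(sv[0], 1.0):
            raise ValueError("seating underdetermined: a rigid degree of "
                             "freedom is unconstrained")
        dx = np.linalg.solve(JTJ, -J.T @ r)
        step = RigidTransform(Rotation.from_rotvec(dx[:3]).as_matrix(), dx[3:])
        T = step @ T
        if np.linalg.norm(dx) < 1e-12:
            break
    return T


def _skew(v):
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])


def export_guides(guides: list[GuideModel], out_dir,
                  bone: trimesh.Trimesh | None = None) -> dict:
    """Validate and write one binary STL per guide plus a JSON manifest
    (tube/K-wire tables, checksums). Export is deterministic; re-import
    reproduces the solids bit-identically."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"guides": []}
    for g in guides:
        g.validate(bone)
        name = f"guide_{g.kind}.stl"
        data = g.solid.export(file_type="stl")
        (out_dir / name).write_bytes(data)
        manifest["guides"].append({
            "kind": g.kind, "file": name,
            "sha256": hashlib.sha256(data).hexdigest(),
            "vertices": len(g.solid.vertices), "faces": len(g.solid.faces),
            "volume_mm3": float(g.solid.volume),
            "tubes": g.tube_records, "drill_channels": g.drill_records,
            "kwires": g.kwire_records,
        })
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
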
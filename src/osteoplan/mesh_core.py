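"""Triangle-mesh substrate: transforms, mirroring, rays, tubes, shells.

Meshes are :class:`trimesh.Trimesh` throughout (vertices in mm). Region
labels — "fragment", "shaft", "articular", guide footprints — travel as
a separate ``dict[str, np.ndarray]`` of per-face boolean masks so that
operations which preserve face order and count (rigid transforms,
mirroring) can carry them through unchanged.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from . import csg
from .transforms import Plane, RigidTransform

__all__ = [
    "transform_mesh", "mirror_mesh", "ray_intersect", "make_tube",
    "boolean_op", "offset_shell", "check_printable", "transfer_labels",
    "save_mesh", "load_mesh",
]

# deterministic direction used to nudge rays off edge/vertex grazings
_TIE_BREAK = np.array([1.0, 1.0 / np.pi, 1.0 / np.e])
_TIE_BREAK /= np.linalg.norm(_TIE_BREAK)


def transform_mesh(mesh: trimesh.Trimesh, T: RigidTransform) -> trimesh.Trimesh:
    """Rigidly move a mesh; topology (and hence any face labels) unchanged."""
    if len(mesh.vertices) == 0:
        raise ValueError("cannot transform an empty mesh")
    return trimesh.Trimesh(vertices=T.apply(mesh.vertices),
                           faces=mesh.faces.copy(), process=False)


def mirror_mesh(mesh: trimesh.Trimesh, plane: Plane) -> trimesh.Trimesh:
    """Reflect across a plane, flipping windings so normals stay outward."""
    verts = plane.reflect(mesh.vertices)
    faces = mesh.faces[:, ::-1]
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def _raw_hits(mesh: trimesh.Trimesh, origin: np.ndarray, direction: np.ndarray):
    # vectorised Moller-Trumbore over every triangle
    tri_v = mesh.triangles
    v0, v1, v2 = tri_v[:, 0], tri_v[:, 1], tri_v[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    h = np.cross(direction, e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > 1e-12
    f = np.zeros_like(a)
    f[ok] = 1.0 / a[ok]
    s = origin - v0
    u = f * np.einsum("ij,ij->i", s, h)
    q = np.cross(s, e1)
    v = f * np.einsum("ij,ij->i", q, np.broadcast_to(direction, s.shape))
    t = f * np.einsum("ij,ij->i", e2, q)
    hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-9)
    if not hit.any():
        return np.empty(0), np.empty(0, int)
    tri = np.flatnonzero(hit)
    dist = t[hit]
    order = np.argsort(dist)
    dist, tri = dist[order], tri[order]
    keep = np.ones(len(dist), dtype=bool)
    keep[1:] = np.diff(dist) > 1e-7  # drop duplicate edge hits
    return dist[keep], tri[keep]


def ray_intersect(mesh: trimesh.Trimesh, origin, direction,
                  check_parity: bool | None = None) -> list[tuple[float, int]]:
    """All ray/surface intersections as ``(distance_mm, face_index)``.

    Distances are strictly increasing. For a watertight solid and an
    exterior origin the hit count must be even; an odd count (edge or
    vertex grazing) triggers a deterministic origin nudge of 1e-6 mm
    along a fixed tie-break direction rather than an error.
    """
    origin = np.asarray(origin, dtype=float).reshape(3)
    direction = np.asarray(direction, dtype=float).reshape(3)
    n = np.linalg.norm(direction)
    if n == 0:
        raise ValueError("ray direction must be nonzero")
    direction = direction / n
    if check_parity is None:
        check_parity = mesh.is_watertight
    dist, tri = _raw_hits(mesh, origin, direction)
    if check_parity and len(dist) % 2 == 1:
        lateral = _TIE_BREAK - (_TIE_BREAK @ direction) * direction
        lateral /= np.linalg.norm(lateral)
        jitter = 1e-6
        for _ in range(4):  # grow the nudge if the grazing persists
            dist, tri = _raw_hits(mesh, origin + jitter * lateral, direction)
            if len(dist) % 2 == 0:
                break
            jitter *= 10.0
    return [(float(d), int(t)) for d, t in zip(dist, tri)]


def make_tube(axis_point, direction, length: float, inner_d: float,
              outer_d: float, sections: int = 64) -> trimesh.Trimesh:
    """Annular (or, for ``inner_d == 0``, solid) cylinder.

    Runs from ``axis_point`` to ``axis_point + length * direction``.
    At the default 64 circumferential segments the mesh volume matches
    pi * L * (ro^2 - ri^2) to well under 1%.
    """
    if length <= 0 or outer_d <= 0 or inner_d < 0 or (inner_d >= outer_d):
        raise ValueError("need outer_d > inner_d >= 0 and length > 0")
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    if inner_d == 0:
        tube = trimesh.creation.cylinder(radius=outer_d / 2.0, height=length,
                                         sections=sections)
    else:
        tube = trimesh.creation.annulus(r_min=inner_d / 2.0, r_max=outer_d / 2.0,
                                        height=length, sections=sections)
    # creation helpers centre the solid on the origin with +z axis
    m = trimesh.geometry.align_vectors([0, 0, 1], direction)
    m[:3, 3] = np.asarray(axis_point, float) + direction * (length / 2.0)
    tube.apply_transform(m)
    return tube


def _open_edges(mesh: trimesh.Trimesh) -> np.ndarray:
    edges = mesh.edges_sorted
    unique, counts = np.unique(edges, axis=0, return_counts=True)
    return unique[counts != 2]


def boolean_op(a: trimesh.Trimesh, b: trimesh.Trimesh, op: str,
               pitch: float = csg.DEFAULT_PITCH) -> trimesh.Trimesh:
    """Watertight union/difference of two watertight solids (voxel CSG)."""
    for name, m in (("a", a), ("b", b)):
        if not m.is_watertight:
            bad = _open_edges(m)
            raise ValueError(
                f"operand {name} is not watertight: {len(bad)} open/non-manifold "
                f"edges, e.g. {bad[:5].tolist()}")
    return csg.voxel_boolean(a, b, op, pitch=pitch)


def offset_shell(mesh: trimesh.Trimesh, face_region: np.ndarray,
                 clearance: float, thickness: float,
                 method: str = "auto") -> trimesh.Trimesh:
    """Bone-conforming shell over a surface patch.

    The inner surface floats ``clearance`` mm above the bone (the print
    fit gap) and the outer surface ``clearance + thickness`` mm; the
    walls close the patch boundary.

    ``method='analytic'`` offsets the patch along per-vertex normals
    and stitches the boundary — exact, but it needs a clean manifold
    patch. ``method='voxel'`` rasterises the offset band instead, which
    tolerates the ragged footprints produced by face-mask selections.
    ``'auto'`` tries analytic first and falls back.
    """
    face_region = np.asarray(face_region)
    if face_region.dtype == bool:
        face_idx = np.flatnonzero(face_region)
    else:
        face_idx = face_region
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    if len(face_idx) < 4:
        raise ValueError("region too small to offset stably")
    if method == "voxel":
        return _voxel_offset_shell(mesh, face_idx, clearance, thickness)
    try:
        return _analytic_offset_shell(mesh, face_idx, clearance, thickness)
    except ValueError:
        if method == "analytic":
            raise
        return _voxel_offset_shell(mesh, face_idx, clearance, thickness)


def _analytic_offset_shell(mesh: trimesh.Trimesh, face_idx: np.ndarray,
                           clearance: float, thickness: float) -> trimesh.Trimesh:
    patch = mesh.submesh([face_idx], append=True)
    # area-weighted vertex normals of the patch alone
    vn = trimesh.geometry.weighted_vertex_normals(
        len(patch.vertices), patch.faces, patch.face_normals,
        patch.area_faces[:, None] * np.ones((1, 3)))
    inner = patch.vertices + vn * clearance
    outer = patch.vertices + vn * (clearance + thickness)
    nv = len(patch.vertices)
    verts = np.vstack([outer, inner])
    faces = [patch.faces, patch.faces[:, ::-1] + nv]
    boundary = _open_edges(patch)
    if len(boundary) == 0:
        raise ValueError("region covers a closed surface; shell needs a boundary")
    # orient each boundary edge as it appears in its (single) patch face
    edge_dir = {}
    for tri in patch.faces:
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            edge_dir[(min(a, b), max(a, b))] = (a, b)
    wall = []
    for e in boundary:
        a, b = edge_dir[(int(e[0]), int(e[1]))]
        wall.append([a, b, b + nv])
        wall.append([a, b + nv, a + nv])
    faces.append(np.array(wall))
    shell = trimesh.Trimesh(vertices=verts, faces=np.vstack(faces), process=True)
    if not shell.is_watertight:
        raise ValueError("region too irregular to offset stably (open shell)")
    if shell.volume < 0:
        shell.invert()
    return shell


def patch_samples(mesh: trimesh.Trimesh, face_idx: np.ndarray,
                  max_edge: float) -> tuple[np.ndarray, np.ndarray]:
    """Dense oriented point sampling of a surface patch (subdivision
    centroids + face normals)."""
    patch = mesh.submesh([np.asarray(face_idx)], append=True)
    v, f = trimesh.remesh.subdivide_to_size(
        patch.vertices, patch.faces, max_edge=max_edge, max_iter=12)
    samples = v[f].mean(axis=1)
    nrm = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    good = np.linalg.norm(nrm, axis=1) > 1e-16
    samples, nrm = samples[good], nrm[good]
    nrm = nrm / np.linalg.norm(nrm, axis=1)[:, None]
    return samples, nrm


def _voxel_offset_shell(mesh: trimesh.Trimesh, face_idx: np.ndarray,
                        clearance: float, thickness: float,
                        pitch: float = 0.3) -> trimesh.Trimesh:
    """Rasterised offset band: voxels whose height above the patch
    (along the local outward normal) lies in [clearance, clearance +
    thickness]."""
    samples, nrm = patch_samples(mesh, face_idx, max_edge=0.8 * pitch)
    pad = clearance + thickness + 3 * pitch
    lo = samples.min(axis=0) - pad
    hi = samples.max(axis=0) + pad
    shape = np.ceil((hi - lo) / pitch).astype(int)
    field = csg.offset_band_field(samples, nrm, lo, shape, pitch,
                                  clearance, thickness)
    if not (field > 0).any():
        raise ValueError("region too small to offset stably")
    return csg.field_to_mesh(field, lo, pitch, min_component=1.0)


def check_printable(mesh: trimesh.Trimesh) -> None:
    """Raise unless the mesh is a printable solid (watertight, consistent
    winding, positive volume)."""
    if not mesh.is_watertight:
        raise ValueError(f"mesh not watertight ({len(_open_edges(mesh))} bad edges)")
    if not mesh.is_winding_consistent:
        raise ValueError("mesh winding inconsistent")
    if mesh.volume <= 0:
        raise ValueError("mesh volume not positive")


def transfer_labels(src: trimesh.Trimesh, src_labels: dict[str, np.ndarray],
                    dst: trimesh.Trimesh, max_dist: float = 2.0) -> dict[str, np.ndarray]:
    """Carry face labels from one meshing of a surface to another.

    Each destination face takes the label of the nearest source face
    centroid; faces farther than ``max_dist`` mm from any labelled
    source face stay unlabelled. Used to move ground-truth or manual
    region picks onto re-segmented surfaces.
    """
    tree = cKDTree(src.triangles_center)
    d, idx = tree.query(dst.triangles_center)
    out = {}
    for name, mask in src_labels.items():
        mask = np.asarray(mask, dtype=bool)
        out[name] = mask[idx] & (d <= max_dist)
    return out


def save_mesh(mesh: trimesh.Trimesh, path, labels: dict[str, np.ndarray] | None = None):
    """Write STL/PLY; labels go to a JSON sidecar (label -> face indices)."""
    path = Path(path)
    mesh.export(path)
    if labels:
        sidecar = {k: np.flatnonzero(np.asarray(v, bool)).tolist()
                   for k, v in labels.items()}
        path.with_suffix(path.suffix + ".labels.json").write_text(
            json.dumps(sidecar))


def load_mesh(path) -> tuple[trimesh.Trimesh, dict[str, np.ndarray]]:
    path = Path(path)
    mesh = trimesh.load(path, force="mesh", process=False)
    labels = {}
    sidecar = path.with_suffix(path.suffix + ".labels.json")
    if sidecar.exists():
        raw = json.loads(sidecar.read_text())
        for k, idx in raw.items():
            mask = np.zeros(len(mesh.faces), dtype=bool)
            mask[np.asarray(idx, int)] = True
            labels[k] = mask
    return mesh, labels
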
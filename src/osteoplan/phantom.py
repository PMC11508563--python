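"""Synthetic proximal-tibia phantoms with exactly known ground truth.

The generator emulates the study situation — an affected proximal tibia
carrying a malunited lateral split(-depression) fragment, plus the
intact contralateral side — as a *stylised* parametric surrogate: a
tapered shaft, a superellipsoid plateau and a tuberosity bump, blended
as implicit solids. It is NOT a statistical tibia; the downstream
contracts are purely geometric, so anatomical realism is unnecessary
and deliberately not attempted.

What makes the phantom useful is exactness: the fragment is separated
by a cubic Bezier cut sheet and displaced by a rigid transform built
with the same anatomical Euler convention the morphometry module
reports, about the same centre (the fragment-surface centroid). Every
downstream estimate therefore has a known true value.

All randomness (contralateral asymmetry noise, CT scatter) derives from
``PhantomSpec.seed``; identical specs produce identical bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .imaging import CTVolume
from .morphometry import DeformityReport, recompose_transform
from .transforms import AnatomicalFrame, RigidTransform

__all__ = ["PhantomSpec", "PhantomCase", "generate_tibia_pair",
           "induce_malunion", "voxelize_ct", "fixture", "cut_components",
           "adjacent_bones_volume"]


# Default cut sheet: y = B(x, z) cubic Bezier control grid. Rows run
# distal -> proximal in z, columns anterior -> posterior in x. Distal
# rows sit far lateral (outside the bone) so the fragment is confined
# to the plateau; proximal rows carve off the lateral part. The columns
# are linear in x, so the sheet is ruled along the drill approach
# (straight drills can reproduce it exactly) while curving through the
# coronal plane — a plausible invented split-fracture geometry (the
# study case's true fracture line is unknown).
_DEFAULT_CUT = np.array([
    [-70.0, -70.0, -70.0, -70.0],
    [-48.0, -48.0, -48.0, -48.0],
    [-16.0, -15.0, -14.0, -13.0],
    [-15.0, -14.0, -13.0, -12.0],
])
_CUT_X = (-35.0, 35.0)   # Bezier u-domain in x
_CUT_Z = (-45.0, 20.0)   # Bezier w-domain in z


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom case. Lengths mm, angles degrees."""

    seed: int = 42
    shaft_radius: float = 11.0
    shaft_length: float = 110.0
    plateau_halfwidth: float = 35.0    # y, medial-lateral
    plateau_halfdepth: float = 24.0    # x, anterior-posterior
    plateau_halfheight: float = 14.0
    plateau_exponent: float = 3.5      # superellipsoid squareness
    tuberosity_offset: float = 16.0    # anterior bump distance from axis
    asymmetry_noise_sigma: float = 0.0
    cut_control: np.ndarray = field(
        default_factory=lambda: _DEFAULT_CUT.copy())
    deformity: tuple = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)  # dx dy dz zeta theta phi
    depression_depth: float = 0.0
    depression_radius: float = 0.0
    with_plate: bool = False
    scatter_amplitude: float = 0.0
    hu_cortical: float = 700.0
    hu_trabecular: float = 300.0
    hu_soft: float = 40.0
    hu_air: float = -1000.0
    hu_metal: float = 8000.0
    cortical_thickness: float = 2.0
    mesh_pitch: float = 0.5            # marching-cubes sampling of the solids


@dataclass
class PhantomCase:
    """One generated case with its ground truth."""

    spec: PhantomSpec
    frame: AnatomicalFrame
    intact: trimesh.Trimesh                  # affected side, before malunion
    intact_labels: dict
    affected: trimesh.Trimesh
    affected_labels: dict
    contralateral: trimesh.Trimesh
    contralateral_labels: dict
    true_transform: RigidTransform           # anatomical -> displaced fragment
    true_report: DeformityReport
    fragment_centroid: np.ndarray
    trace: np.ndarray                        # fracture line polyline (n, 3)


# --------------------------------------------------------------------
# implicit solid model (inside-positive, approximately mm-scaled)

def _smax(a, b, k=4.0):
    """Smooth union of inside-positive fields (blend radius ~k mm)."""
    h = np.maximum(k - np.abs(a - b), 0.0) / k
    return np.maximum(a, b) + 0.25 * k * h * h


def bone_field(spec: PhantomSpec, pts: np.ndarray) -> np.ndarray:
    """Inside-positive implicit function of the intact right tibia."""
    x, y, z = pts[..., 0], pts[..., 1], pts[..., 2]
    # shaft: tapered tube along z, flaring toward the plateau, with the
    # triangular cross-section (anterior crest) of a real tibia — which
    # is also what pins the rotational degree of freedom of shaft-based
    # registration
    flare = 1.0 + 0.5 / (1.0 + np.exp(-(z + 18.0) / 6.0))
    r = np.sqrt(x * x + y * y)
    az = np.arctan2(y, x)
    tri = 1.0 + 0.12 * np.cos(3.0 * (az - np.pi))
    shaft = spec.shaft_radius * flare * tri - r
    shaft = np.minimum(shaft, z + spec.shaft_length)      # distal cap
    shaft = np.minimum(shaft, 2.0 - z)                    # merge into plateau
    # plateau: superellipsoid centred just below the articular surface,
    # with the posterior condylar bulge and the ~7 degree posterior
    # slope of a real plateau (also what gives the fragment surface
    # enough shape character for registration to be well-posed)
    p = spec.plateau_exponent
    depth_eff = spec.plateau_halfdepth * (1.0 + 0.15 * np.tanh(x / 12.0))
    z_tilt = z + 2.0 + 0.12 * x
    rr = (np.abs(x / depth_eff) ** p
          + np.abs(y / spec.plateau_halfwidth) ** p
          + np.abs(z_tilt / spec.plateau_halfheight) ** p) ** (1.0 / p)
    plateau = (1.0 - rr) * spec.plateau_halfheight
    # tibial tuberosity: anterior ellipsoid bump riding on the shaft
    tx = (x + spec.tuberosity_offset) / 8.0
    ty = y / 10.0
    tz = (z + 28.0) / 14.0
    tub = (1.0 - np.sqrt(tx * tx + ty * ty + tz * tz)) * 8.0
    return _smax(_smax(shaft, plateau), tub)


def _bernstein(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    u = 1.0 - t
    return np.stack([u ** 3, 3 * u * u * t, 3 * u * t * t, t ** 3], axis=-1)


def cut_side(spec: PhantomSpec, pts: np.ndarray) -> np.ndarray:
    """Signed side function of the cut sheet: positive on the lateral
    (fragment) side, approximately mm (height above the sheet in y)."""
    x, z = pts[..., 0], pts[..., 2]
    u = (x - _CUT_X[0]) / (_CUT_X[1] - _CUT_X[0])
    w = (z - _CUT_Z[0]) / (_CUT_Z[1] - _CUT_Z[0])
    bu = _bernstein(u)
    bw = _bernstein(w)
    # tensor product: B(u, w) = sum_ij bw_i bu_j C_ij (rows index z)
    sheet_y = np.einsum("...i,ij,...j->...", bw, spec.cut_control, bu)
    return sheet_y - pts[..., 1]


def _field_mesh(fn, bounds: np.ndarray, pitch: float) -> trimesh.Trimesh:
    lo = bounds[0] - 3 * pitch
    shape = np.ceil((bounds[1] - bounds[0] + 6 * pitch) / pitch).astype(int)
    axes = [lo[i] + (np.arange(shape[i]) + 0.5) * pitch for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    vals = fn(grid)
    field = np.pad(vals, 1, constant_values=-1.0)
    verts, faces, _, _ = measure.marching_cubes(field, level=0.0)
    verts = (verts - 1.0) * pitch + lo + 0.5 * pitch
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _intact_bounds(spec: PhantomSpec) -> np.ndarray:
    return np.array([
        [-spec.tuberosity_offset - 12.0, -spec.plateau_halfwidth - 3.0,
         -spec.shaft_length - 3.0],
        [spec.plateau_halfdepth + 3.0, spec.plateau_halfwidth + 3.0,
         spec.plateau_halfheight + 2.0],
    ])


# --------------------------------------------------------------------
# generation

def generate_tibia_pair(spec: PhantomSpec) -> tuple[trimesh.Trimesh, trimesh.Trimesh]:
    """Right (affected-side, still intact) and left (contralateral)
    surface meshes.

    The left bone is the exact mirror of the right across the y=0
    mid-sagittal plane, plus optional Gaussian surface noise of
    ``asymmetry_noise_sigma`` mm along vertex normals emulating natural
    bilateral asymmetry. Deterministic per seed.
    """
    if spec.shaft_radius <= 0 or spec.shaft_length <= 0 \
            or spec.plateau_halfwidth <= 0 or spec.mesh_pitch <= 0:
        raise ValueError("degenerate phantom parameters")
    right = _field_mesh(lambda p: bone_field(spec, p),
                        _intact_bounds(spec), spec.mesh_pitch)
    left_v = right.vertices.copy()
    left_v[:, 1] *= -1.0
    left = trimesh.Trimesh(vertices=left_v, faces=right.faces[:, ::-1],
                           process=False)
    if spec.asymmetry_noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.asymmetry_noise_sigma,
                           size=len(left.vertices))
        left = trimesh.Trimesh(
            vertices=left.vertices + left.vertex_normals * noise[:, None],
            faces=left.faces, process=False)
    return right, left


def _fragment_mask(spec: PhantomSpec, mesh: trimesh.Trimesh,
                   margin: float = 0.5) -> np.ndarray:
    return cut_side(spec, mesh.triangles_center) > margin


def _shaft_mask(mesh: trimesh.Trimesh, fraction: float = 0.40) -> np.ndarray:
    z = mesh.triangles_center[:, 2]
    return z <= z.min() + fraction * (z.max() - z.min())


def _affected_field(spec: PhantomSpec, T: RigidTransform,
                    dep_center: np.ndarray | None):
    """Inside-positive field of the malunited bone: remainder united
    with the rigidly displaced (optionally depressed) fragment."""
    Ti = T.inverse()

    def fn(pts):
        flat = pts.reshape(-1, 3)
        rem = np.minimum(bone_field(spec, flat), -cut_side(spec, flat))
        q = Ti.apply(flat)
        # +0.05 mm overlap so the zero-deformity union has no seam
        frag = np.minimum(bone_field(spec, q), cut_side(spec, q) + 0.05)
        if dep_center is not None:
            dep = np.linalg.norm(q - dep_center, axis=-1) - spec.depression_radius
            frag = np.minimum(frag, dep)
        return np.maximum(rem, frag).reshape(pts.shape[:-1])

    return fn


def _fracture_trace(spec: PhantomSpec, n: int = 40) -> np.ndarray:
    """Ground-truth fracture line: anterior-most crossing of the cut
    sheet with the intact bone surface, sampled along z."""
    pts = []
    for z in np.linspace(-20.0, spec.plateau_halfheight - 3.0, n):
        xs = np.linspace(-spec.plateau_halfdepth - 8.0, 0.0, 200)
        probe = np.stack([xs, np.zeros_like(xs), np.full_like(xs, z)], axis=-1)
        probe[:, 1] = cut_side(spec, probe) + probe[:, 1]  # y on the sheet
        f = bone_field(spec, probe)
        cross = np.flatnonzero((f[:-1] < 0) & (f[1:] >= 0))
        if len(cross) == 0:
            continue
        i = cross[0]
        # linear root on the sampled segment
        t = -f[i] / (f[i + 1] - f[i])
        p = probe[i] * (1 - t) + probe[i + 1] * t
        # keep only anterior-facing cortex (the drillable fence face);
        # outward normal from the implicit-field gradient
        eps = 0.2
        grad = np.array([
            bone_field(spec, p + [eps, 0, 0]) - bone_field(spec, p - [eps, 0, 0]),
            bone_field(spec, p + [0, eps, 0]) - bone_field(spec, p - [0, eps, 0]),
            bone_field(spec, p + [0, 0, eps]) - bone_field(spec, p - [0, 0, eps]),
        ])
        normal = -grad / np.linalg.norm(grad)
        if normal[0] < -0.35:
            pts.append(p)
    out = np.asarray(pts)
    if len(out) < 2:
        raise ValueError("cut sheet does not intersect the bone surface")
    return out


def induce_malunion(spec: PhantomSpec) -> PhantomCase:
    """Cut the bone with the Bezier sheet, displace the lateral fragment
    by the spec deformity, optionally subtract a depression defect.

    The deformity transform is built with the morphometry convention
    (intrinsic z-x-y angles about the fragment-surface centroid), so the
    quantification pipeline's estimate has this exact transform as truth.
    """
    frame = AnatomicalFrame()
    right, left = generate_tibia_pair(spec)

    frag_mask_i = _fragment_mask(spec, right)
    if not frag_mask_i.any():
        raise ValueError("cut sheet does not separate a fragment")
    w = right.area_faces[frag_mask_i]
    centroid = (right.triangles_center[frag_mask_i] * w[:, None]).sum(0) / w.sum()

    dx, dy, dz, zeta, theta, phi = spec.deformity
    true_report = DeformityReport(dx=dx, dy=dy, dz=dz, zeta=zeta, theta=theta,
                                  phi=phi, context="pre")
    T = recompose_transform(true_report, frame, center=centroid)

    dep_center = None
    if spec.depression_radius > 0:
        # sphere sunk into the articular face of the fragment
        top = right.triangles_center[frag_mask_i]
        art = top[top[:, 2] > top[:, 2].max() - 2.0].mean(axis=0)
        dep_center = art + np.array([0.0, 0.0,
                                     spec.depression_radius - spec.depression_depth])

    # reject cuts that fail to split the bone in exactly two
    _check_two_components(spec)

    bounds = _intact_bounds(spec)
    disp = np.abs(np.array([dx, dy, dz])) + 6.0
    bounds = np.array([bounds[0] - disp, bounds[1] + disp])
    affected = _field_mesh(_affected_field(spec, T, dep_center),
                           bounds, spec.mesh_pitch)

    # affected fragment label: faces on the (displaced) original outer
    # surface of the fragment — cut faces and the depression crater,
    # which have no counterpart on the template, are excluded
    q = T.inverse().apply(affected.triangles_center)
    on_surface = np.abs(bone_field(spec, q)) < 0.8
    frag_aff = (cut_side(spec, q) > 0.5) & on_surface
    if dep_center is not None:
        frag_aff &= (np.linalg.norm(q - dep_center, axis=-1)
                     > spec.depression_radius + 0.8)

    case = PhantomCase(
        spec=spec, frame=frame,
        intact=right,
        intact_labels={"fragment": frag_mask_i, "shaft": _shaft_mask(right)},
        affected=affected,
        affected_labels={"fragment": frag_aff, "shaft": _shaft_mask(affected)},
        contralateral=left,
        contralateral_labels={"fragment": frag_mask_i.copy(),
                              "shaft": _shaft_mask(left)},
        true_transform=T,
        true_report=true_report,
        fragment_centroid=centroid,
        trace=_fracture_trace(spec),
    )
    return case


def _check_two_components(spec: PhantomSpec) -> None:
    pitch = max(spec.mesh_pitch, 1.0)
    bounds = _intact_bounds(spec)
    lo = bounds[0]
    shape = np.ceil((bounds[1] - bounds[0]) / pitch).astype(int)
    axes = [lo[i] + (np.arange(shape[i]) + 0.5) * pitch for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    f = bone_field(spec, grid)
    g = cut_side(spec, grid)
    for part in (( f > 0) & (g <= 0), (f > 0) & (g > 0)):
        if not part.any():
            raise ValueError("cut sheet does not produce two components")
        _, n = ndimage.label(part)
        if n != 1:
            raise ValueError(
                f"cut sheet produces {n + 1} components, expected exactly 2")


def cut_components(spec: PhantomSpec) -> tuple[trimesh.Trimesh, trimesh.Trimesh]:
    """Fragment and remainder solids at the anatomical pose (for volume
    bookkeeping and as the ground-truth cutting interface)."""
    bounds = _intact_bounds(spec)

    def frag(p):
        flat = p.reshape(-1, 3)
        return np.minimum(bone_field(spec, flat),
                          cut_side(spec, flat)).reshape(p.shape[:-1])

    def rem(p):
        flat = p.reshape(-1, 3)
        return np.minimum(bone_field(spec, flat),
                          -cut_side(spec, flat)).reshape(p.shape[:-1])

    return (_field_mesh(frag, bounds, spec.mesh_pitch),
            _field_mesh(rem, bounds, spec.mesh_pitch))


# --------------------------------------------------------------------
# CT simulation

def _plate_slab(spec: PhantomSpec) -> trimesh.Trimesh:
    """Simple lateral plate slab hugging the proximal lateral cortex."""
    box = trimesh.creation.box(extents=[16.0, 4.0, 70.0])
    box.apply_translation([-4.0, -spec.shaft_radius * 1.5 - 3.5, -30.0])
    return box


def voxelize_ct(case_mesh: trimesh.Trimesh | None, spacing: float,
                spec: PhantomSpec,
                field_fn=None,
                plate: bool | None = None) -> CTVolume:
    """Simulated CT of one bone: cortical shell (outer 2 mm) at cortical
    HU, interior trabecular, a soft-tissue envelope, air beyond, and an
    optional metal plate with scatter-like streak noise.

    Occupancy comes from the implicit field when available (exact);
    otherwise the supplied mesh is rasterised.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if field_fn is None and case_mesh is None:
        raise ValueError("need a mesh or an implicit field")
    if field_fn is not None:
        bounds = _intact_bounds(spec)
        if case_mesh is not None:
            bounds = np.array([
                np.minimum(bounds[0], case_mesh.bounds[0]),
                np.maximum(bounds[1], case_mesh.bounds[1])])
    else:
        bounds = case_mesh.bounds.copy()
    margin = 12.0
    lo = bounds[0] - margin
    shape = np.ceil((bounds[1] - bounds[0] + 2 * margin) / spacing).astype(int)

    if field_fn is not None:
        axes = [lo[i] + (np.arange(shape[i]) + 0.5) * spacing for i in range(3)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        occ = field_fn(grid) > 0
    else:
        from . import csg
        occ = csg.solid_occupancy(case_mesh, spacing, lo, shape)[0]

    inside_d = ndimage.distance_transform_edt(occ, sampling=spacing)
    outside_d = ndimage.distance_transform_edt(~occ, sampling=spacing)
    hu = np.full(occ.shape, spec.hu_air, dtype=np.float32)
    hu[outside_d <= 10.0] = spec.hu_soft
    hu[occ] = spec.hu_trabecular
    hu[occ & (inside_d <= spec.cortical_thickness)] = spec.hu_cortical
    # scanner point-spread function: fixed physical width (0.4 mm),
    # independent of the reconstruction voxel size
    hu = ndimage.gaussian_filter(hu, sigma=0.4 / spacing)

    use_plate = spec.with_plate if plate is None else plate
    if use_plate:
        from . import csg
        slab = _plate_slab(spec)
        pocc = csg.solid_occupancy(slab, spacing, lo, shape)[0]
        hu[pocc] = spec.hu_metal
        if spec.scatter_amplitude > 0:
            pd = ndimage.distance_transform_edt(~pocc, sampling=spacing)
            near = (pd > 0) & (pd <= 15.0)
            idx = np.argwhere(near)
            centers = lo + (idx + 0.5) * spacing
            c = slab.bounds.mean(axis=0)
            az = np.arctan2(centers[:, 1] - c[1], centers[:, 0] - c[0])
            rng = np.random.default_rng(spec.seed + 1)
            streak = (np.cos(7.0 * az + rng.uniform(0, 2 * np.pi))
                      * np.exp(-pd[near] / 8.0))
            wobble = rng.normal(0.0, 0.4, size=len(idx))
            hu[near[...]] = hu[near] + spec.scatter_amplitude * (streak + wobble)
    return CTVolume(hu, np.full(3, float(spacing)), lo)


def adjacent_bones_volume(spec: PhantomSpec, spacing: float = 1.0) -> CTVolume:
    """CT with the tibia plus simplified fibula and femur solids, the
    fibula touching the tibia through a thin bridge — the seeded-split
    test scenario."""
    def fn(p):
        x, y, z = p[..., 0], p[..., 1], p[..., 2]
        tibia = bone_field(spec, p)
        # fibula: thin cylinder lateral-posterior of the tibia
        fr = 5.0 - np.sqrt((x - 8.0) ** 2 + (y + spec.plateau_halfwidth + 8.5) ** 2)
        fib = np.minimum(np.minimum(fr, z + spec.shaft_length), -2.0 - z)
        # femur: flat ellipsoid floating above the plateau
        fx, fy, fz = x / 28.0, y / 32.0, (z - 30.0) / 12.0
        fem = (1.0 - np.sqrt(fx * fx + fy * fy + fz * fz)) * 12.0
        return np.maximum(np.maximum(tibia, fib), fem)

    return voxelize_ct(None, spacing, spec, field_fn=fn, plate=False)


# --------------------------------------------------------------------
# named fixtures

#: preoperative deformity of the study case (mm / degrees): posterior,
#: lateral (negative y on a right leg), caudal; sagittal/coronal/axial
_PRE_DEFORMITY = (5.4, -2.9, -5.9, 10.2, 23.0, 0.8)
#: achieved-vs-planned residual of the study case
_POSTOP_RESIDUAL = (0.5, -1.0, 0.6, 3.8, 1.3, 0.1)


def fixture(name: str, mesh_pitch: float = 0.5) -> PhantomCase:
    """Deterministic named cases.

    * ``study_case`` — implants the preoperative malunion of the study
      case as exact truth (with a depression defect).
    * ``study_postop`` — implants the achieved-vs-planned residual; the
      intact model doubles as the planned model.
    * ``clean`` — zero deformity, zero noise.
    * ``scatter`` — ``study_case`` plus an in-situ plate with CT
      scatter noise.
    """
    base = PhantomSpec(seed=42, mesh_pitch=mesh_pitch)
    if name == "study_case":
        spec = replace(base, deformity=_PRE_DEFORMITY,
                       depression_depth=4.0, depression_radius=8.0)
    elif name == "study_postop":
        spec = replace(base, deformity=_POSTOP_RESIDUAL)
    elif name == "clean":
        spec = base
    elif name == "scatter":
        spec = replace(base, deformity=_PRE_DEFORMITY,
                       depression_depth=4.0, depression_radius=8.0,
                       with_plate=True, scatter_amplitude=400.0)
    else:
        raise ValueError(f"unknown fixture {name!r}")
    return induce_malunion(spec)
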
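"""CT volumes, bone segmentation and surface extraction.

The segmentation recipe is the standard clinical one for bone: a
Hounsfield threshold (inclusive, default >= 226 HU) selects candidate
bone voxels, region growing keeps the connected bone of interest, a
seeded split separates bones touching through thin bridges, and
marching cubes turns the final binary mask into a surface mesh in mm.

Volumes are plain numpy arrays with spacing/origin metadata; array axes
map one-to-one onto the anatomical frame axes (index ``i`` along x,
``j`` along y, ``k`` along z). Voxel ``(i, j, k)`` is centred at
``origin + (idx + 0.5) * spacing`` and the volume extent is half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import trimesh
from scipy import ndimage
from skimage import measure

__all__ = [
    "CTVolume", "LabelMask", "threshold_bone", "region_grow", "split_mask",
    "extract_surface", "read_volume", "write_volume",
    "METAL_HU", "DEFAULT_BONE_HU",
]

DEFAULT_BONE_HU = 226.0
METAL_HU = 3000.0

# 26-connectivity: the medical-segmentation default, keeps thin cortical
# shells connected
_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class CTVolume:
    """Voxel grid of Hounsfield units plus geometry metadata (mm)."""

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = np.broadcast_to(
            np.asarray(self.spacing, float), (3,)).copy()
        self.origin = np.asarray(self.origin, float).reshape(3)
        if (self.spacing <= 0).any():
            raise ValueError("spacing must be strictly positive")
        if not np.isfinite(self.voxels).all():
            raise ValueError("HU values must be finite")

    def voxel_center(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + (np.asarray(idx, float) + 0.5) * self.spacing


@dataclass
class LabelMask:
    """Integer labels on the same grid as a source volume (0=background)."""

    labels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.spacing = np.broadcast_to(
            np.asarray(self.spacing, float), (3,)).copy()
        self.origin = np.asarray(self.origin, float).reshape(3)

    @classmethod
    def like(cls, vol: CTVolume, labels: np.ndarray) -> "LabelMask":
        if labels.shape != vol.voxels.shape:
            raise ValueError("label grid must match the source volume")
        return cls(labels, vol.spacing, vol.origin)


def threshold_bone(vol: CTVolume, hu_min: float = DEFAULT_BONE_HU,
                   exclude_metal: bool = True) -> LabelMask:
    """Binary bone mask: voxel is bone iff ``HU >= hu_min`` (inclusive).

    Voxels at metal attenuation (>= 3000 HU, e.g. an in-situ plate) are
    excluded by default with a warning — hardware corrupts the bone
    surface and no artifact correction is attempted here.
    """
    mask = vol.voxels >= hu_min
    if exclude_metal:
        metal = vol.voxels >= METAL_HU
        if metal.any():
            warnings.warn(
                f"{int(metal.sum())} metal voxels (HU >= {METAL_HU:g}) excluded "
                "from the bone mask; expect degraded surfaces near hardware",
                stacklevel=2)
            mask &= ~metal
    return LabelMask.like(vol, mask.astype(np.uint8))


def region_grow(mask: LabelMask, seed: tuple[int, int, int]) -> LabelMask:
    """26-connected component of the foreground containing ``seed``."""
    seed = tuple(int(s) for s in seed)
    if not mask.labels[seed]:
        raise ValueError(f"seed {seed} is not foreground")
    comp, _ = ndimage.label(mask.labels > 0, structure=_CONN26)
    out = (comp == comp[seed]).astype(np.uint8)
    return LabelMask(out, mask.spacing, mask.origin)


def split_mask(mask: LabelMask, seeds: list[tuple[tuple[int, int, int], int]],
               erosion_radius: int = 1) -> LabelMask:
    """Assign each foreground voxel the label of its seed's component,
    separating bones that touch through thin bridges.

    Components still holding two seeds after an erosion of
    ``erosion_radius`` voxels are reported with a warning rather than
    split arbitrarily. Eroded bridge voxels are re-assigned to the
    nearest surviving label.
    """
    if not seeds:
        raise ValueError("need at least one seed")
    fg = mask.labels > 0
    for voxel, lab in seeds:
        if not fg[tuple(int(v) for v in voxel)]:
            raise ValueError(f"seed {voxel} (label {lab}) is not foreground")

    comp, _ = ndimage.label(fg, structure=_CONN26)
    out = np.zeros_like(mask.labels, dtype=np.int32)

    by_comp: dict[int, list] = {}
    for voxel, lab in seeds:
        by_comp.setdefault(int(comp[tuple(voxel)]), []).append((voxel, lab))

    for cid, comp_seeds in by_comp.items():
        region = comp == cid
        if len(comp_seeds) == 1:
            out[region] = comp_seeds[0][1]
            continue
        # multiple seeds share a component: erode away thin bridges
        eroded = ndimage.binary_erosion(region, iterations=erosion_radius)
        sub, _ = ndimage.label(eroded, structure=_CONN26)
        seed_sub = {}
        for voxel, lab in comp_seeds:
            sid = int(sub[tuple(voxel)])
            if sid == 0:  # seed sat on a bridge voxel; snap to nearest core
                _, (ii, jj, kk) = ndimage.distance_transform_edt(
                    sub == 0, return_indices=True)
                v = tuple(voxel)
                sid = int(sub[ii[v], jj[v], kk[v]])
            seed_sub.setdefault(sid, []).append(lab)
        if any(len(v) > 1 for v in seed_sub.values()):
            warnings.warn(
                "seeds share an inseparable component at erosion radius "
                f"{erosion_radius}; labels {sorted(l for ls in seed_sub.values() for l in ls)} "
                "not fully separated", stacklevel=2)
        labelled = np.zeros_like(sub)
        for sid, labs in seed_sub.items():
            labelled[sub == sid] = labs[0]
        # grow labels back over eroded voxels, nearest-label within region
        missing = region & (labelled == 0)
        if missing.any():
            _, idx = ndimage.distance_transform_edt(
                labelled == 0, return_indices=True, sampling=mask.spacing)
            grown = labelled[idx[0], idx[1], idx[2]]
            labelled[missing] = grown[missing]
        out[region] = labelled[region]
    return LabelMask(out, mask.spacing, mask.origin)


def extract_surface(mask: LabelMask, label: int = 1,
                    smooth_iterations: int = 0) -> trimesh.Trimesh:
    """Marching-cubes surface of a label at the 0.5 iso-level, in mm.

    Output is watertight (the binary field is zero-padded before
    extraction). Taubin smoothing is available but off by default so
    surfaces stay faithful to the voxel data.
    """
    binary = (mask.labels == label)
    if not binary.any():
        raise ValueError(f"label {label} not present in mask")
    field = np.pad(binary.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(
        field, level=0.5, spacing=tuple(mask.spacing))
    verts = verts - mask.spacing + 0.5 * mask.spacing + mask.origin
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if mesh.volume < 0:
        mesh.invert()
    if smooth_iterations > 0:
        trimesh.smoothing.filter_taubin(mesh, iterations=smooth_iterations)
    return mesh


def write_volume(vol: CTVolume | LabelMask, path) -> None:
    """Write NIfTI / MetaImage (.nii, .nii.gz, .mha, .mhd, .nrrd)."""
    arr = vol.voxels if isinstance(vol, CTVolume) else vol.labels
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.T))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o + 0.5 * s)
                        for o, s in zip(vol.origin, vol.spacing)))
    sitk.WriteImage(img, str(path))


def read_volume(path, as_labels: bool = False) -> CTVolume | LabelMask:
    img = sitk.ReadImage(str(Path(path)))
    arr = sitk.GetArrayFromImage(img).T
    spacing = np.asarray(img.GetSpacing(), float)
    origin = np.asarray(img.GetOrigin(), float) - 0.5 * spacing
    if as_labels:
        return LabelMask(arr.astype(np.int32), spacing, origin)
    return CTVolume(arr.astype(np.float32), spacing, origin)
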
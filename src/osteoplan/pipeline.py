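"""End-to-end convenience pipelines over the module building blocks.

These are the compositions the command-line tool and the reproduction
script run: simulate or load a CT, segment it, quantify the deformity,
plan the osteotomy, and assess an achieved reduction.
"""

from __future__ import annotations

import numpy as np
import trimesh

from . import imaging, morphometry, phantom
from .mesh_core import transfer_labels
from .morphometry import DeformityReport
from .phantom import PhantomCase

__all__ = ["segment_bone_ct", "quantify_case_from_ct", "assess_case"]


def segment_bone_ct(vol: imaging.CTVolume, seed_world: np.ndarray,
                    hu_min: float = imaging.DEFAULT_BONE_HU) -> trimesh.Trimesh:
    """Standard bone segmentation: threshold -> seeded region growing ->
    marching-cubes surface. ``seed_world`` is a point (mm) inside the
    bone of interest."""
    mask = imaging.threshold_bone(vol, hu_min=hu_min)
    seed_idx = tuple(np.clip(
        ((np.asarray(seed_world, float) - vol.origin) / vol.spacing - 0.5)
        .round().astype(int), 0, np.array(vol.voxels.shape) - 1))
    grown = imaging.region_grow(mask, seed_idx)
    return imaging.extract_surface(grown, label=1)


def quantify_case_from_ct(case: PhantomCase, spacing: float = 0.5
                          ) -> tuple[DeformityReport, dict]:
    """Run the whole preoperative quantification on simulated CT.

    Both sides are voxelised at ``spacing`` mm, segmented with the
    standard recipe, the ground-truth region labels are transferred
    onto the segmented surfaces by proximity (standing in for a manual
    region pick), and the malunion is quantified against the mirrored
    contralateral segmentation.
    """
    spec = case.spec
    vol_aff = phantom.voxelize_ct(case.affected, spacing, spec)
    vol_con = phantom.voxelize_ct(case.contralateral, spacing, spec)

    # interior shaft points are safe seeds on both sides
    seed_aff = np.array([0.0, 0.0, -spec.shaft_length * 0.5])
    seed_con = seed_aff * np.array([1.0, -1.0, 1.0])
    mesh_aff = segment_bone_ct(vol_aff, seed_aff)
    mesh_con = segment_bone_ct(vol_con, seed_con)

    lab_aff = transfer_labels(case.affected, case.affected_labels, mesh_aff,
                              max_dist=1.5)
    lab_con = transfer_labels(case.contralateral, case.contralateral_labels,
                              mesh_con, max_dist=1.5)

    report = morphometry.quantify_malunion(
        mesh_aff, mesh_con, case.frame,
        lab_aff["fragment"], lab_con["fragment"])
    artifacts = {"affected_mesh": mesh_aff, "contralateral_mesh": mesh_con,
                 "affected_labels": lab_aff, "contralateral_labels": lab_con}
    return report, artifacts


def assess_case(case: PhantomCase) -> DeformityReport:
    """Planned-versus-postoperative assessment on a fixture whose
    ``affected`` model plays the postoperative bone and whose ``intact``
    model is the plan."""
    return morphometry.assess_postop(
        case.affected, case.intact, case.frame,
        case.affected_labels["fragment"], case.intact_labels["fragment"])
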
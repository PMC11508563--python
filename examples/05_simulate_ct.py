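"""Simulate CT of a phantom bone and run the segmentation recipe.

Shows the HU model (cortical 700 / trabecular 300 / soft 40 / air
-1000) and the effect of in-situ metal scatter on segmentation.
"""
import warnings
from dataclasses import replace

import numpy as np

from osteoplan import imaging, phantom

warnings.simplefilter("ignore")

spec = phantom.PhantomSpec(seed=7)
field = lambda p: phantom.bone_field(spec, p)   # noqa: E731
vol = phantom.voxelize_ct(None, 1.0, spec, field_fn=field)
print("volume", vol.voxels.shape, "at", vol.spacing, "mm;",
      f"HU range [{vol.voxels.min():.0f}, {vol.voxels.max():.0f}]")

mask = imaging.threshold_bone(vol)
seed = tuple(np.round((np.array([0, 0, -55.0]) - vol.origin)
                      / vol.spacing - 0.5).astype(int))
grown = imaging.region_grow(mask, seed)
mesh = imaging.extract_surface(grown)
print(f"segmented bone surface: {len(mesh.faces)} faces, "
      f"volume {mesh.volume / 1000:.1f} cm^3, watertight={mesh.is_watertight}")

print("\nsegmentation Dice vs ground truth under metal scatter:")
for amp in (0.0, 300.0, 700.0):
    s2 = replace(spec, with_plate=True, scatter_amplitude=amp)
    f2 = lambda p: phantom.bone_field(s2, p)    # noqa: E731
    v2 = phantom.voxelize_ct(None, 1.2, s2, field_fn=f2)
    m2 = imaging.threshold_bone(v2).labels > 0
    axes = [v2.origin[i] + (np.arange(v2.voxels.shape[i]) + 0.5) * 1.2
            for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    truth = phantom.bone_field(s2, grid) > 0
    dice = 2 * (m2 & truth).sum() / (m2.sum() + truth.sum())
    print(f"  scatter amplitude {amp:5.0f} HU -> Dice {dice:.4f}")
print("Monotone degradation reproduces why in-situ hardware makes")
print("segmentation (and hence guide design) less reliable.")
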
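"""Contour-based lesion segmentation and volumetry.

Builds a lesion outlined on every second slice (as a reader would), fills
the gaps by shape-based interpolation of signed distance transforms,
rasterizes to a voxel mask and reports the volume.
"""
import numpy as np

import hepquant as hq


def circle(radius_mm: float, center: float = 25.0, n: int = 72) -> np.ndarray:
    th = np.linspace(0.0, 2.0 * np.pi, n + 1)[:-1]
    return np.column_stack([center + radius_mm * np.cos(th), center + radius_mm * np.sin(th)])


# drawn on slices 0, 2, 4 only; slice thickness 3 mm, in-plane 1.3 mm
stack = hq.ContourStack(
    {0: circle(8.0), 2: circle(14.0), 4: circle(9.0)},
    slice_thickness_mm=3.0,
    in_plane_spacing_mm=(1.3, 1.3),
)
full = hq.interpolate_contours(stack)
print(f"drawn slices: {sorted(stack.slices)} -> populated: {sorted(full.slices)}")

mask = hq.rasterize(full, grid_shape=(40, 40, 6))
print(f"mask voxels: {int(mask.voxels.sum())}")
print(f"lesion volume: {hq.mask_volume_cm3(mask):.2f} cm3")

# masked mean T1 on a synthetic map: lesion at 900 ms in 700 ms liver
t1 = np.full((40, 40, 6), 700.0)
t1[mask.voxels] = 900.0
mean = hq.mean_in_mask(hq.T1Map(t1, mask.spacing_mm), mask)
print(f"mean T1 in lesion: {mean.mean:.1f} ms over {mean.n_used} voxels")
# The interpolated slices 1 and 3 take intermediate cross sections, so the
# volume reflects the whole lesion, not just the drawn slices.
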
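"""Fill unannotated slices: contours, cell density and graded lesions.

Histology sections exist every 5 mm while the MRI grid has 2.5 mm
slices, so every second slice carries no data.  Contours are filled
morphologically, density by neighbour averaging (then converted to
volumetric units with a 3/2-power law), and graded lesions with the
probabilistic 0.5-weighting scheme.
"""

import numpy as np

from voxatlas import SparseSliceStack, VoxelGrid
from voxatlas.slicefill import (
    interpolate_contours,
    interpolate_density,
    interpolate_lesions,
    to_volumetric,
)

# --- contours: discs of radius 5 and 9 voxels on the annotated slices ----
vals = np.zeros((31, 31, 3), dtype=np.uint8)
xx, yy = np.meshgrid(np.arange(31) - 15, np.arange(31) - 15, indexing="ij")
vals[:, :, 0] = xx**2 + yy**2 <= 5**2
vals[:, :, 2] = xx**2 + yy**2 <= 9**2
stack = SparseSliceStack(VoxelGrid(vals, (1, 1, 2.5)), [0, 2], "contour")
filled = interpolate_contours(stack)
areas = [int(filled.values[:, :, k].sum()) for k in range(3)]
print(f"contour areas (voxels): lower {areas[0]}, filled {areas[1]}, "
      f"upper {areas[2]}  -> the filled shape is geometrically intermediate")

# --- density: neighbours 100 and 200 cells/mm^2 --------------------------
d = np.zeros((5, 5, 3))
d[:, :, 0], d[:, :, 2] = 100.0, 200.0
dd = interpolate_density(
    SparseSliceStack(VoxelGrid(d, (1, 1, 2.5)), [0, 2], "density"))
print(f"density filled slice: {dd.values[2, 2, 1]:.0f} cells/mm^2 "
      "(arithmetic mean of the neighbours)")
vol = to_volumetric(dd)  # default exponent 3/2
print(f"volumetric conversion: 150^1.5 = {vol.values[2, 2, 1]:.1f} cells/mm^3")

# --- graded lesions: the probabilistic weighting rules -------------------
def lesion(n=9, lower=False, upper=False):
    v = np.zeros((n, n, 3), dtype=np.uint8)
    if lower:
        v[3:6, 3:6, 0] = 1
    if upper:
        v[3:6, 3:6, 2] = 1
    return SparseSliceStack(VoxelGrid(v, (1, 1, 2.5)), [0, 2], "lesion_grade")

both = interpolate_lesions({4: lesion(lower=True, upper=True)})
one = interpolate_lesions({4: lesion(lower=True)})
two = interpolate_lesions({3: lesion(lower=True), 5: lesion(upper=True)})
print(f"same grade on both flanks -> filled weight "
      f"{both[4].values[4, 4, 1]:.1f}")
print(f"lesion on one flank only  -> filled weight "
      f"{one[4].values[4, 4, 1]:.1f}")
print(f"different grades flanking -> {two[3].values[4, 4, 1]:.1f} in each "
      "grade's volume")
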
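"""Inter-slice interpolation of sparse histology-derived data.

Whole-mount histology sections sample the gland at 5 mm intervals while
the co-registered MRI has 2.5 mm slices, so every second axial slice
carries no histology data.  Three interpolation schemes fill the gaps,
one per data type:

* **Contours** (binary anatomy masks): morphological interpolation — the
  filled slice is the zero-superlevel set of the mean of the two
  neighbouring slices' signed distance functions, after centroid
  pre-alignment, giving a geometrically intermediate shape.
* **Cell density**: in-plane-position-wise linear interpolation (the
  arithmetic mean of the two flanking slices), which keeps filled values
  inside the range of the adjacent measured values.  Cross-sectional
  density (cells/mm^2) is subsequently converted to volumetric density
  (cells/mm^3) by a 3/2-power law.
* **Graded tumour lesions**: probabilistic interpolation — each Gleason
  grade gets its own label volume; annotated lesion voxels carry 1, and
  the slices immediately before/after an annotated slice receive a 0.5
  weighting at covered in-plane positions.  Contributions from the two
  flanking slices add and are capped at 1, so a voxel flanked by
  same-grade lesions on both sides carries 1, and a voxel flanked by two
  different grades carries 0.5 in each grade's volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import VoxelGrid

__all__ = [
    "SparseSliceStack",
    "interpolate_contours",
    "interpolate_density",
    "to_volumetric",
    "interpolate_lesions",
    "fill_patient",
]


@dataclass
class SparseSliceStack:
    """A volume whose payload is defined only on ``annotated_slices``.

    Gaps between consecutive annotated slices must be exactly one slice
    (the study's every-second-slice geometry); wider gaps are rejected.
    """

    grid: VoxelGrid
    annotated_slices: list[int]
    payload_kind: str  # {contour | density | lesion_grade}

    def __post_init__(self) -> None:
        sl = np.asarray(self.annotated_slices, dtype=int)
        if sl.size == 0:
            raise ValueError("annotated_slices must be non-empty")
        if sl.size > 1 and not np.all(np.diff(sl) > 0):
            raise ValueError("annotated_slices must be strictly increasing")
        if sl.min() < 0 or sl.max() >= self.grid.shape[2]:
            raise ValueError("annotated_slices out of range for grid")
        gaps = np.diff(sl)
        if sl.size > 1 and not np.all(gaps == 2):
            raise ValueError(
                "gaps between annotated slices must be exactly one slice; "
                f"got slice spacing(s) {sorted(set(int(g) for g in gaps))}"
            )
        if self.payload_kind not in ("contour", "density", "lesion_grade"):
            raise ValueError(f"unknown payload_kind {self.payload_kind!r}")


# ----------------------------------------------------------------------
# morphological contour interpolation
# ----------------------------------------------------------------------
def _signed_distance_2d(region: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance, positive inside, in voxel units."""
    region = region.astype(bool)
    inside = ndimage.distance_transform_edt(region)
    outside = ndimage.distance_transform_edt(~region)
    return inside - outside


def _interp_slice_pair(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Morphological midpoint between two binary 2D regions."""
    a = a.astype(bool)
    b = b.astype(bool)
    if not a.any() and not b.any():
        return np.zeros_like(a)
    if a.any() and b.any():
        ca = np.array(ndimage.center_of_mass(a))
        cb = np.array(ndimage.center_of_mass(b))
        mid = (ca + cb) / 2.0
        sa = np.round(mid - ca).astype(int)
        sb = np.round(mid - cb).astype(int)
        da = ndimage.shift(_signed_distance_2d(a), sa, order=0, mode="nearest")
        db = ndimage.shift(_signed_distance_2d(b), sb, order=0, mode="nearest")
        return (da + db) / 2.0 > 0
    # degenerate pair: one neighbour empty -> shrink the non-empty region
    # towards extinction; midpoint = erosion to half the maximal depth
    r = a if a.any() else b
    d = ndimage.distance_transform_edt(r)
    return d > d.max() / 2.0


def interpolate_contours(stack: SparseSliceStack) -> VoxelGrid:
    """Fill unannotated slices of a binary contour stack morphologically.

    Annotated slices pass through unchanged; each filled slice is
    geometrically intermediate between its two annotated neighbours.
    Slices outside the annotated span are left empty.
    """
    if stack.payload_kind != "contour":
        raise TypeError(f"expected contour payload, got {stack.payload_kind!r}")
    if not stack.grid.is_binary():
        raise TypeError("contour interpolation requires a binary payload")
    vals = stack.grid.values.astype(np.uint8)
    out = np.zeros_like(vals)
    sl = list(stack.annotated_slices)
    for k in sl:
        out[:, :, k] = vals[:, :, k]
    for lo, hi in zip(sl[:-1], sl[1:]):
        out[:, :, lo + 1] = _interp_slice_pair(vals[:, :, lo], vals[:, :, hi])
    return stack.grid.copy_with(out)


# ----------------------------------------------------------------------
# linear density interpolation and volumetric conversion
# ----------------------------------------------------------------------
def interpolate_density(
    stack: SparseSliceStack, support: VoxelGrid | None = None
) -> VoxelGrid:
    """Fill unannotated slices of a density stack by slice-wise averaging.

    Each filled voxel is the arithmetic mean of the two flanking annotated
    slices at the same in-plane position, hence always within their range.

    If ``support`` (a binary tissue mask, e.g. the prostate) is given, the
    mean is weighted by the flanking slices' support: positions where only
    one neighbour lies in tissue take that neighbour's value instead of
    averaging real density with the zero recorded outside the tissue.
    """
    if stack.payload_kind != "density":
        raise TypeError(f"expected density payload, got {stack.payload_kind!r}")
    vals = np.asarray(stack.grid.values, dtype=float)
    if vals.min() < 0:
        raise ValueError("density values must be non-negative")
    sup = None
    if support is not None:
        stack.grid.require_aligned(support, what="density interpolation support")
        sup = support.values.astype(bool)
    out = np.zeros_like(vals)
    sl = list(stack.annotated_slices)
    for k in sl:
        out[:, :, k] = vals[:, :, k]
    for lo, hi in zip(sl[:-1], sl[1:]):
        if sup is None:
            out[:, :, lo + 1] = 0.5 * (vals[:, :, lo] + vals[:, :, hi])
        else:
            w_lo = sup[:, :, lo].astype(float)
            w_hi = sup[:, :, hi].astype(float)
            wsum = w_lo + w_hi
            num = w_lo * vals[:, :, lo] + w_hi * vals[:, :, hi]
            out[:, :, lo + 1] = np.where(wsum > 0, num / np.maximum(wsum, 1), 0.0)
    return stack.grid.copy_with(out)


def to_volumetric(density: VoxelGrid, exponent: float = 1.5) -> VoxelGrid:
    """Convert cross-sectional density (cells/mm^2) to volumetric (cells/mm^3).

    Applies an elementwise power law with default exponent 3/2; monotone,
    so the ordering of voxel values is preserved.
    """
    if exponent <= 0:
        raise ValueError(f"exponent must be positive, got {exponent}")
    vals = np.asarray(density.values, dtype=float)
    if vals.min() < 0:
        raise ValueError("density values must be non-negative")
    return density.copy_with(np.power(vals, exponent))


# ----------------------------------------------------------------------
# probabilistic graded-lesion interpolation
# ----------------------------------------------------------------------
def interpolate_lesions(
    stacks: dict[int, SparseSliceStack]
) -> dict[int, VoxelGrid]:
    """Probabilistic interpolation of per-grade binary lesion annotations.

    Each grade keeps its own output volume.  Annotated lesion voxels carry
    value 1.  On a filled slice, each flanking annotated slice contributes
    0.5 at the in-plane positions its lesion covers; contributions add and
    are capped at 1.  A voxel covered by the same grade on both flanks
    therefore carries 1; one covered by two different grades carries 0.5
    in each grade's volume.

    Raises
    ------
    ValueError
        If two grades overlap at a single annotated-slice voxel (each
        annotated lesion voxel belongs to exactly one grade).
    """
    if not stacks:
        return {}
    grades = sorted(stacks)
    ref = stacks[grades[0]]
    for g in grades[1:]:
        ref.grid.require_aligned(stacks[g].grid, what="lesion interpolation")
        if stacks[g].annotated_slices != ref.annotated_slices:
            raise ValueError("all grade stacks must share annotated_slices")
    for g in grades:
        if stacks[g].payload_kind != "lesion_grade":
            raise TypeError(f"grade {g}: expected lesion_grade payload")
        if not stacks[g].grid.is_binary():
            raise TypeError(f"grade {g}: lesion annotations must be binary")

    sl = list(ref.annotated_slices)
    # one grade per annotated lesion voxel
    overlap = None
    for k in sl:
        cover = np.zeros(ref.grid.shape[:2], dtype=int)
        for g in grades:
            cover += stacks[g].grid.values[:, :, k].astype(bool)
        if np.any(cover > 1):
            overlap = k
            break
    if overlap is not None:
        raise ValueError(
            f"overlapping lesion grades on annotated slice {overlap}; "
            "each annotated lesion voxel must carry exactly one grade"
        )

    out: dict[int, VoxelGrid] = {}
    for g in grades:
        vals = stacks[g].grid.values.astype(float)
        filled = np.zeros_like(vals)
        for k in sl:
            filled[:, :, k] = vals[:, :, k]
        for lo, hi in zip(sl[:-1], sl[1:]):
            contrib = 0.5 * vals[:, :, lo] + 0.5 * vals[:, :, hi]
            filled[:, :, lo + 1] = np.minimum(contrib, 1.0)
        out[g] = stacks[g].grid.copy_with(filled)
    return out


# ----------------------------------------------------------------------
# whole-patient convenience
# ----------------------------------------------------------------------
def fill_patient(ds, density_exponent: float = 1.5):
    """Apply all three interpolation schemes to one patient in place-copy.

    Returns a new :class:`~voxatlas.dataset.PatientDataset` whose lesion
    maps and density are filled across the annotated span, density
    converted to volumetric units, and whose validity mask marks in-gland
    voxels on slices within [first, last] annotated slice.  Slices beyond
    the annotated span receive no values and are invalid.
    """
    from .dataset import PatientDataset  # local import to avoid cycle

    sl = list(ds.annotated_slices)
    dens = interpolate_density(
        SparseSliceStack(ds.density, sl, "density"), support=ds.prostate_mask)
    dens = to_volumetric(dens, exponent=density_exponent)
    lesion_stacks = {
        g: SparseSliceStack(m, sl, "lesion_grade") for g, m in ds.lesion_maps.items()
    }
    lesions = interpolate_lesions(lesion_stacks)

    validity = np.zeros(ds.prostate_mask.shape, dtype=np.uint8)
    validity[:, :, sl[0]: sl[-1] + 1] = 1
    validity &= ds.prostate_mask.values.astype(np.uint8)
    # a filled in-gland voxel with no tissue on either flanking annotated
    # slice carries no density sample: mark it invalid
    gland = ds.prostate_mask.values.astype(bool)
    for lo, hi in zip(sl[:-1], sl[1:]):
        no_support = ~(gland[:, :, lo] | gland[:, :, hi])
        validity[:, :, lo + 1][no_support] = 0

    return PatientDataset(
        prostate_mask=ds.prostate_mask,
        pz_mask=ds.pz_mask,
        urethra_mask=ds.urethra_mask,
        lesion_maps=lesions,
        density=dens,
        annotated_slices=sl,
        validity_mask=ds.prostate_mask.copy_with(validity),
        mri=ds.mri,
        density_is_volumetric=True,
        patient_id=ds.patient_id,
        meta=dict(ds.meta, filled=True),
    )
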
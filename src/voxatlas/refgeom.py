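"""Consensus reference geometry.

The reference prostate is built by rigidly aligning every patient's
gland — centroid to the origin, principal moments to the coordinate
axes, with the rotation initialised from the imaging axes so no axis is
flipped — and keeping the voxels covered by at least half (a
configurable fraction) of the aligned volumes.  The reference peripheral
zone is the analogous consensus of PZ masks after the whole-gland
registration stage, intersected with the reference prostate.  A splined
tube of fixed radius through per-slice urethra centroids provides the
reference urethra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .config import PipelineConfig
from .grid import GridAlignmentError, VoxelGrid
from .dpreg import (
    TransformChain,
    compose_and_apply,
    distance_preserving_register,
    mask_moments,
    similarity_register,
    _principal_frame,
)

__all__ = [
    "RigidAlignment",
    "ReferenceGeometry",
    "principal_axis_align",
    "consensus_volume",
    "urethra_tube",
    "make_reference_grid",
    "build_reference",
]


@dataclass
class RigidAlignment:
    """Rigid map ``y = rotation @ (x − pivot)``: centroid to the origin,
    principal moments to the reference axes, determinant +1."""

    rotation: np.ndarray
    pivot: np.ndarray

    @property
    def translation(self) -> np.ndarray:
        return -self.rotation @ self.pivot

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, dtype=float) - self.pivot) @ self.rotation.T

    def apply_inverse(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=float) @ self.rotation + self.pivot


def make_reference_grid(extent_mm: float, spacing: float) -> VoxelGrid:
    """Isotropic grid centred on the origin covering ±extent_mm/2."""
    n = int(np.ceil(extent_mm / spacing)) + 1
    sp = np.full(3, float(spacing))
    origin = -(n - 1) * sp / 2.0
    return VoxelGrid(np.zeros((n, n, n), dtype=np.uint8), sp, origin)


def principal_axis_align(
    mask: VoxelGrid, target_grid: VoxelGrid | None = None
) -> tuple[RigidAlignment, VoxelGrid]:
    """Rigidly align a binary mask to the principal-moment frame.

    The transformed mask has its centroid at the origin (within half a
    voxel) and a diagonal second-moment matrix.  The rotation is chosen
    as the principal-axis frame nearest the imaging axes (per-axis sign
    fixed, determinant +1), so near-axis-aligned shapes get a rotation
    close to identity and no axis is ever flipped.
    """
    if not mask.values.astype(bool).any():
        raise ValueError("cannot align an empty mask")
    centroid, cov = mask_moments(mask)
    frame, _ = _principal_frame(cov)
    align = RigidAlignment(rotation=frame.T, pivot=centroid)

    if target_grid is None:
        extent = float(np.max(np.asarray(mask.shape) * mask.spacing))
        target_grid = make_reference_grid(extent, float(mask.spacing.min()))
    pts = target_grid.physical_coordinates().reshape(-1, 3)
    src = align.apply_inverse(pts)
    idx = mask.physical_to_index(src)
    vals = ndimage.map_coordinates(
        mask.values.astype(np.uint8),
        [idx[:, a] for a in range(3)],
        order=0, mode="constant", cval=0,
    ).reshape(target_grid.shape)
    return align, target_grid.copy_with(vals)


def consensus_volume(masks: list[VoxelGrid], fraction: float = 0.5) -> VoxelGrid:
    """Voxels covered by at least ``fraction`` of the aligned masks.

    A voxel covered by exactly ``fraction × n`` masks is included ("half
    or more" is ≥).  Permutation-invariant and monotone in the mask list.
    """
    if len(masks) < 2:
        raise ValueError("consensus requires at least two masks")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    ref = masks[0]
    for m in masks[1:]:
        ref.require_aligned(m, what="consensus volume")
    counts = np.zeros(ref.shape, dtype=np.int32)
    for m in masks:
        counts += m.values.astype(bool)
    threshold = fraction * len(masks)
    out = (counts >= threshold - 1e-9).astype(np.uint8)
    return ref.copy_with(out)


def urethra_tube(
    centreline: np.ndarray, radius: float, template: VoxelGrid
) -> VoxelGrid:
    """Binary tube of given radius (mm) around a cubic spline through the
    centreline points, rasterised on the template grid."""
    pts = np.asarray(centreline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ValueError("centreline must be an (n>=3, 3) point array")
    if radius <= 0:
        raise ValueError("radius must be positive")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg < 1e-9):
        raise ValueError("degenerate centreline: coincident consecutive points")
    t = np.concatenate([[0.0], np.cumsum(seg)])
    spline = CubicSpline(t, pts, axis=0)
    # sample densely enough that polyline error << voxel size
    n_samp = max(200, int(t[-1] / (0.25 * float(template.spacing.min()))))
    samples = spline(np.linspace(0.0, t[-1], n_samp))

    vox = template.physical_coordinates().reshape(-1, 3)
    tree = cKDTree(samples)
    dist, _ = tree.query(vox, k=1)
    tube = (dist <= radius).reshape(template.shape).astype(np.uint8)
    return template.copy_with(tube)


def urethra_centreline_from_mask(mask: VoxelGrid) -> np.ndarray:
    """Per-slice centroids (mm) of a urethra mask, ordered along z."""
    m = mask.values.astype(bool)
    pts = []
    for k in range(mask.shape[2]):
        sl = m[:, :, k]
        if sl.any():
            i, j = np.argwhere(sl).mean(axis=0)
            pts.append(mask.index_to_physical(np.array([i, j, float(k)])))
    if len(pts) < 3:
        raise ValueError("urethra mask spans fewer than three slices")
    return np.asarray(pts)


# ----------------------------------------------------------------------
# full reference construction
# ----------------------------------------------------------------------
@dataclass
class ReferenceGeometry:
    """Reference prostate / PZ / urethra plus per-patient stage-1 chains."""

    grid: VoxelGrid
    prostate: VoxelGrid
    pz: VoxelGrid
    urethra: VoxelGrid | None
    alignments: list[RigidAlignment]
    chains: list[TransformChain]  # similarity + whole-gland deformable
    meta: dict = field(default_factory=dict)


def build_reference(cohort: list, config: PipelineConfig) -> ReferenceGeometry:
    """Construct the reference geometry from a cohort.

    1. Principal-axis align all prostate masks; consensus (fraction from
       config) defines the reference prostate.
    2. Register each patient to it (anisotropic similarity + whole-gland
       distance-preserving deformable stage); warp the PZ masks through
       these chains; their consensus, intersected with the reference
       prostate, defines the reference PZ.
    3. Spline per-slice centroids of the aggregated warped urethra masks
       into a tube of config.urethra_radius.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    extents = []
    for ds in cohort:
        m = ds.prostate_mask
        bbox = np.argwhere(m.values.astype(bool))
        size = (bbox.max(axis=0) - bbox.min(axis=0) + 1) * m.spacing
        extents.append(size.max())
    extent = float(np.max(extents)) * 1.3 + 8.0
    grid = make_reference_grid(extent, config.iso_spacing)

    alignments, aligned = [], []
    for ds in cohort:
        al, am = principal_axis_align(ds.prostate_mask, target_grid=grid)
        alignments.append(al)
        aligned.append(am)
    prostate = consensus_volume(aligned, config.consensus_fraction)
    if not prostate.values.any():
        raise ValueError("empty consensus prostate; pathological cohort")

    chains, warped_pz, urethra_sum = [], [], np.zeros(grid.shape)
    for ds in cohort:
        sim = similarity_register(ds.prostate_mask, prostate)
        chain1 = TransformChain([sim])
        moving = compose_and_apply(chain1, ds.prostate_mask, grid, mode="nearest")
        disp = distance_preserving_register(moving, prostate, config=config.demons)
        chain = TransformChain([sim, disp])
        chains.append(chain)
        warped_pz.append(compose_and_apply(chain, ds.pz_mask, grid, mode="nearest"))
        u = compose_and_apply(chain, ds.urethra_mask, grid, mode="nearest")
        urethra_sum += u.values

    pz = consensus_volume(warped_pz, config.consensus_fraction)
    pz = pz.copy_with((pz.values.astype(bool)
                       & prostate.values.astype(bool)).astype(np.uint8))

    urethra = None
    usum = grid.copy_with((urethra_sum >= max(1.0, 0.25 * len(cohort)))
                          .astype(np.uint8))
    try:
        centreline = urethra_centreline_from_mask(usum)
        urethra = urethra_tube(centreline, config.urethra_radius, grid)
    except ValueError:
        pass  # cohort without usable urethra data

    return ReferenceGeometry(
        grid=grid,
        prostate=prostate,
        pz=pz,
        urethra=urethra,
        alignments=alignments,
        chains=chains,
        meta={
            "n_patients": len(cohort),
            "consensus_fraction": config.consensus_fraction,
            "iso_spacing": config.iso_spacing,
        },
    )
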
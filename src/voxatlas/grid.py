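"""Voxel grid data model.

A :class:`VoxelGrid` is the universal carrier for every volume in the
pipeline: MRI intensities, binary masks, probabilistic lesion labels,
cell-density maps, displacement-field components.  It couples a 3D array
with the physical-space metadata (spacing, origin, direction cosines)
needed to place each voxel in millimetre coordinates.

Conventions
-----------
* Array axes are ordered ``(x, y, z)``; axial slices are indexed along the
  third axis, so slice ``k`` sits at physical ``z = origin_z + k * spacing_z``
  (for identity orientation).
* Voxel indexing is 0-based; the physical position of voxel ``(i, j, k)`` is
  ``origin + direction @ (spacing * (i, j, k))`` — i.e. ``origin`` is the
  centre of the first voxel.
* Masks are ``{0, 1}`` integer grids; "inside" means value 1 at the voxel
  centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk

__all__ = ["VoxelGrid", "GridAlignmentError"]


class GridAlignmentError(ValueError):
    """Raised when an operation requires aligned grids but they differ."""


def _identity_direction() -> np.ndarray:
    return np.eye(3)


@dataclass
class VoxelGrid:
    """A 3D scalar field with physical-space metadata.

    Parameters
    ----------
    values
        3D array, axis order (x, y, z).
    spacing
        Per-axis voxel size in mm, strictly positive.
    origin
        Physical position (mm) of the centre of voxel (0, 0, 0).
    direction
        3x3 orthonormal direction-cosine matrix, determinant +1.
    """

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=_identity_direction)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if not np.all(self.spacing > 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix must be orthonormal")
        if np.linalg.det(self.direction) < 0:
            raise ValueError("direction matrix must have determinant +1 (no flips)")

    # ------------------------------------------------------------------
    # basic properties
    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def copy_with(self, values: np.ndarray) -> "VoxelGrid":
        """New grid with the same geometry but different values."""
        if np.asarray(values).shape != self.values.shape:
            raise ValueError("copy_with requires values of identical shape")
        return replace(self, values=np.asarray(values))

    def like(self, values: np.ndarray) -> "VoxelGrid":
        """New grid with this grid's geometry and an arbitrary-shape array."""
        return VoxelGrid(np.asarray(values), self.spacing.copy(),
                         self.origin.copy(), self.direction.copy())

    # ------------------------------------------------------------------
    # alignment
    # ------------------------------------------------------------------
    def same_geometry(self, other: "VoxelGrid", atol: float = 1e-5) -> bool:
        """True iff spacing, origin, direction and shape all match."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )

    def require_aligned(self, other: "VoxelGrid", what: str = "operation") -> None:
        if not self.same_geometry(other):
            raise GridAlignmentError(
                f"{what} requires aligned grids: "
                f"shapes {self.shape} vs {other.shape}, "
                f"spacing {self.spacing} vs {other.spacing}, "
                f"origin {self.origin} vs {other.origin}"
            )

    # ------------------------------------------------------------------
    # coordinate transforms
    # ------------------------------------------------------------------
    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map (continuous) voxel indices, shape (..., 3), to mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return self.origin + (idx * self.spacing) @ self.direction.T

    def physical_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map mm coordinates, shape (..., 3), to continuous voxel indices."""
        pts = np.asarray(pts, dtype=float)
        return ((pts - self.origin) @ self.direction) / self.spacing

    def physical_coordinates(self) -> np.ndarray:
        """Dense (nx, ny, nz, 3) array of voxel-centre positions in mm."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
        )
        return self.index_to_physical(idx)

    # ------------------------------------------------------------------
    # SimpleITK bridge
    # ------------------------------------------------------------------
    def to_sitk(self) -> sitk.Image:
        # SimpleITK arrays are indexed (z, y, x); transpose reverses axis order.
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.values.T))
        img.SetSpacing(tuple(self.spacing))
        img.SetOrigin(tuple(self.origin))
        img.SetDirection(tuple(self.direction.ravel()))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "VoxelGrid":
        values = sitk.GetArrayFromImage(img).T
        return cls(
            values=values,
            spacing=np.asarray(img.GetSpacing()),
            origin=np.asarray(img.GetOrigin()),
            direction=np.asarray(img.GetDirection()).reshape(3, 3),
        )

    # ------------------------------------------------------------------
    # convenience predicates
    # ------------------------------------------------------------------
    def is_binary(self) -> bool:
        return bool(np.isin(np.unique(self.values), (0, 1)).all())

    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))
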
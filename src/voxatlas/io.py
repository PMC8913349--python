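"""File I/O and resampling for :class:`~voxatlas.grid.VoxelGrid`.

NIfTI (``.nii``/``.nii.gz``) and MetaImage (``.mha``/``.mhd``) are the two
supported on-disk formats; both are read and written through SimpleITK so
spacing, origin and direction cosines survive the round trip.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .grid import VoxelGrid

__all__ = ["read_image", "write_image", "resample_isotropic", "ImageFormatError"]

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


class ImageFormatError(IOError):
    """Unreadable, truncated or unsupported image file."""


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise ImageFormatError(
            f"unsupported image format for {path!s}; "
            f"expected one of {_SUPPORTED_SUFFIXES}"
        )


def read_image(path: str | Path) -> VoxelGrid:
    """Read a NIfTI or MetaImage volume, preserving header geometry.

    Raises
    ------
    ImageFormatError
        If the file does not exist, has an unsupported extension, or cannot
        be parsed (e.g. truncated).
    """
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"image file not found: {path!s}")
    _check_suffix(path)
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # sitk raises bare RuntimeError on bad files
        raise ImageFormatError(f"failed to read image {path!s}: {exc}") from exc
    if img.GetDimension() != 3:
        raise ImageFormatError(
            f"{path!s}: expected a 3D volume, got {img.GetDimension()}D"
        )
    return VoxelGrid.from_sitk(img)


def write_image(grid: VoxelGrid, path: str | Path) -> Path:
    """Write a grid to NIfTI or MetaImage, chosen by file extension."""
    path = Path(path)
    _check_suffix(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(grid.to_sitk(), str(path))
    return path


def resample_isotropic(
    grid: VoxelGrid, spacing: float, mode: str = "linear"
) -> VoxelGrid:
    """Resample a grid to isotropic voxels of the given size (mm).

    ``mode="nearest"`` is for binary masks (output stays binary);
    ``mode="linear"`` is for probabilistic or density maps (output stays
    within the input value range by convexity).  Physical extent is
    preserved to within one voxel.
    """
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    if mode not in ("nearest", "linear"):
        raise ValueError(f"mode must be 'nearest' or 'linear', got {mode!r}")

    new_spacing = np.full(3, float(spacing))
    # identity shortcut: same spacing + nearest is the identity on values
    if mode == "nearest" and np.allclose(grid.spacing, new_spacing):
        return grid.copy_with(grid.values.copy())

    old_extent = grid.spacing * np.asarray(grid.shape)
    new_size = np.maximum(1, np.ceil(old_extent / new_spacing - 1e-6)).astype(int)
    # keep the physical face of the volume fixed: first voxel centre moves
    # by half the spacing difference along each (direction-frame) axis
    shift = (new_spacing - grid.spacing) / 2.0
    new_origin = grid.origin + grid.direction @ shift

    img = grid.to_sitk()
    interp = sitk.sitkNearestNeighbor if mode == "nearest" else sitk.sitkLinear
    out = sitk.Resample(
        img,
        [int(n) for n in new_size],
        sitk.Transform(),
        interp,
        tuple(new_origin),
        tuple(new_spacing),
        img.GetDirection(),
        0.0,
        img.GetPixelID(),
        True,  # nearest-neighbour extrapolation at the half-voxel border
    )
    return VoxelGrid.from_sitk(out)


def sphere_volume(radius_mm: float) -> float:
    """Analytic sphere volume, mm^3 — handy for resampling sanity checks."""
    return 4.0 / 3.0 * math.pi * radius_mm**3
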
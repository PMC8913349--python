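"""Per-patient dataset container and cohort directory I/O.

A :class:`PatientDataset` bundles everything the pipeline knows about one
subject: binary anatomy masks (prostate, peripheral zone, urethra),
per-Gleason-grade probabilistic lesion maps, a cell-density map, the list
of axial slice indices that carry histology-derived data, and a validity
mask marking voxels with usable data.  Before slice interpolation, lesion
and density values exist only on the annotated slices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grid import VoxelGrid
from . import io as vio

__all__ = ["PatientDataset", "write_patient", "read_patient",
           "write_cohort", "read_cohort"]


@dataclass
class PatientDataset:
    """One subject's co-registered volumes plus annotation metadata.

    All member grids must be pairwise aligned; the peripheral zone must be
    contained in the prostate, lesion values in [0, 1] with support inside
    the prostate, density non-negative, and ``annotated_slices`` strictly
    increasing.
    """

    prostate_mask: VoxelGrid
    pz_mask: VoxelGrid
    urethra_mask: VoxelGrid
    lesion_maps: dict[int, VoxelGrid]
    density: VoxelGrid
    annotated_slices: list[int]
    validity_mask: VoxelGrid
    mri: VoxelGrid | None = None
    density_is_volumetric: bool = False
    patient_id: str = ""
    meta: dict = field(default_factory=dict)

    # ------------------------------------------------------------------
    def grids(self) -> list[tuple[str, VoxelGrid]]:
        out = [
            ("prostate_mask", self.prostate_mask),
            ("pz_mask", self.pz_mask),
            ("urethra_mask", self.urethra_mask),
            ("density", self.density),
            ("validity_mask", self.validity_mask),
        ]
        out += [(f"lesion_g{g}", m) for g, m in self.lesion_maps.items()]
        if self.mri is not None:
            out.append(("mri", self.mri))
        return out

    def validate(self) -> None:
        """Check every dataset invariant; raise ValueError on violation."""
        ref = self.prostate_mask
        for name, g in self.grids():
            ref.require_aligned(g, what=f"PatientDataset ({name})")
        for name in ("prostate_mask", "pz_mask", "urethra_mask", "validity_mask"):
            if not getattr(self, name).is_binary():
                raise ValueError(f"{name} must be binary")
        pro = self.prostate_mask.values.astype(bool)
        if np.any(self.pz_mask.values.astype(bool) & ~pro):
            raise ValueError("pz_mask must be contained in prostate_mask")
        for g, m in self.lesion_maps.items():
            v = m.values
            if v.min() < 0 or v.max() > 1:
                raise ValueError(f"lesion map grade {g} has values outside [0, 1]")
            if np.any((v > 0) & ~pro):
                raise ValueError(f"lesion map grade {g} has support outside prostate")
        if self.density.values.min() < 0:
            raise ValueError("density must be non-negative")
        sl = np.asarray(self.annotated_slices)
        if sl.size and not np.all(np.diff(sl) > 0):
            raise ValueError("annotated_slices must be strictly increasing")
        if sl.size and (sl.min() < 0 or sl.max() >= ref.shape[2]):
            raise ValueError("annotated_slices out of grid range")

    def annotated_mask_1d(self) -> np.ndarray:
        """Boolean per-slice flag of shape (nz,), True on annotated slices."""
        out = np.zeros(self.prostate_mask.shape[2], dtype=bool)
        out[list(self.annotated_slices)] = True
        return out


# ----------------------------------------------------------------------
# cohort directory layout
# ----------------------------------------------------------------------
_VOLUMES = ("prostate_mask", "pz_mask", "urethra_mask", "density",
            "validity_mask", "mri")


def write_patient(ds: PatientDataset, outdir: str | Path,
                  fmt: str = "nii.gz") -> Path:
    """Write one patient's volumes plus a JSON sidecar with metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in _VOLUMES:
        grid = getattr(ds, name)
        if grid is None:
            continue
        vio.write_image(grid, outdir / f"{name}.{fmt}")
    for grade, m in ds.lesion_maps.items():
        vio.write_image(m, outdir / f"lesion_g{grade}.{fmt}")
    sidecar = {
        "patient_id": ds.patient_id,
        "annotated_slices": [int(s) for s in ds.annotated_slices],
        "grades": sorted(int(g) for g in ds.lesion_maps),
        "density_is_volumetric": ds.density_is_volumetric,
        "meta": ds.meta,
    }
    (outdir / "patient.json").write_text(json.dumps(sidecar, indent=2))
    return outdir


def read_patient(indir: str | Path) -> PatientDataset:
    indir = Path(indir)
    sidecar = json.loads((indir / "patient.json").read_text())

    def load(name: str, required: bool = True) -> VoxelGrid | None:
        for fmt in ("nii.gz", "nii", "mha", "mhd"):
            p = indir / f"{name}.{fmt}"
            if p.exists():
                return vio.read_image(p)
        if required:
            raise FileNotFoundError(f"missing volume {name} in {indir}")
        return None

    lesion_maps = {int(g): load(f"lesion_g{g}") for g in sidecar["grades"]}
    return PatientDataset(
        prostate_mask=load("prostate_mask"),
        pz_mask=load("pz_mask"),
        urethra_mask=load("urethra_mask"),
        lesion_maps=lesion_maps,
        density=load("density"),
        annotated_slices=list(sidecar["annotated_slices"]),
        validity_mask=load("validity_mask"),
        mri=load("mri", required=False),
        density_is_volumetric=sidecar.get("density_is_volumetric", False),
        patient_id=sidecar.get("patient_id", indir.name),
        meta=sidecar.get("meta", {}),
    )


def write_cohort(cohort: list[PatientDataset], outdir: str | Path,
                 truth: dict | None = None) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, ds in enumerate(cohort):
        pid = ds.patient_id or f"patient_{i:03d}"
        write_patient(ds, outdir / pid)
    if truth is not None:
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    return outdir


def read_cohort(indir: str | Path) -> list[PatientDataset]:
    indir = Path(indir)
    pdirs = sorted(p for p in indir.iterdir()
                   if p.is_dir() and (p / "patient.json").exists())
    if not pdirs:
        raise FileNotFoundError(f"no patient directories under {indir}")
    return [read_patient(p) for p in pdirs]
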
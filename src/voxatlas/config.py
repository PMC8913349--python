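"""Pipeline configuration.

All physically meaningful defaults of the atlas pipeline live here:
isotropic working resolution, consensus fraction, urethra radius,
cross-sectional-to-volumetric density exponent, and the demons
registration schedule.  Configs round-trip through YAML so every CLI
stage can write a resolved-config sidecar for reproducibility.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["DemonsConfig", "PipelineConfig"]


@dataclass
class DemonsConfig:
    """Parameters of the log-domain symmetric-forces demons stages.

    ``pyramid_shrinks`` and ``iterations`` are matched per multiresolution
    level (coarse to fine).  Smoothing widths are in voxels of the working
    grid; ``sigma_update`` regularises each velocity update (fluid-like),
    ``sigma_total`` the accumulated velocity (diffusion-like).
    """

    pyramid_shrinks: tuple[int, ...] = (4, 2, 1)
    iterations: tuple[int, ...] = (50, 30, 20)
    sigma_update: float = 1.5
    sigma_total: float = 0.5
    max_step: float = 1.0  # voxels; caps the per-iteration update magnitude
    pin_band: float = 3.0  # voxels over which the boundary pin ramps to 1

    def __post_init__(self) -> None:
        if len(self.pyramid_shrinks) != len(self.iterations):
            raise ValueError("pyramid_shrinks and iterations must have equal length")
        if any(s <= 0 for s in self.pyramid_shrinks):
            raise ValueError("pyramid shrink factors must be positive")
        if self.sigma_update < 0 or self.sigma_total < 0:
            raise ValueError("smoothing widths must be non-negative")


@dataclass
class PipelineConfig:
    """Top-level configuration for the atlas pipeline.

    Attributes
    ----------
    iso_spacing
        Isotropic working/reference resolution, mm (default 0.8).
    consensus_fraction
        Fraction of aligned cohort masks that must cover a voxel for it to
        enter the consensus reference volume; "half or more" -> 0.5, with
        the threshold attained counting as inside.
    urethra_radius
        Radius of the splined reference urethra tube, mm.
    density_exponent
        Exponent converting cross-sectional (cells/mm^2) to volumetric
        (cells/mm^3) cell density; default 3/2.
    min_samples_fit / min_samples_kl
        Minimum per-voxel sample counts for density-model fitting and for
        KDE/KL model evaluation.
    max_eval_voxels
        Cap on the number of voxels entering the per-voxel KL evaluation
        (a seeded random subsample is used above the cap; 0 = no cap).
    """

    iso_spacing: float = 0.8
    consensus_fraction: float = 0.5
    urethra_radius: float = 1.5
    density_exponent: float = 1.5
    min_samples_fit: int = 3
    min_samples_kl: int = 5
    max_eval_voxels: int = 4000
    rng_seed: int = 0
    demons: DemonsConfig = field(default_factory=DemonsConfig)

    def __post_init__(self) -> None:
        if self.iso_spacing <= 0:
            raise ValueError("iso_spacing must be positive")
        if not (0.0 < self.consensus_fraction <= 1.0):
            raise ValueError("consensus_fraction must lie in (0, 1]")
        if self.urethra_radius <= 0:
            raise ValueError("urethra_radius must be positive")
        if self.density_exponent <= 0:
            raise ValueError("density_exponent must be positive")
        if isinstance(self.demons, dict):
            self.demons = DemonsConfig(**self.demons)

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["demons"]["pyramid_shrinks"] = list(self.demons.pyramid_shrinks)
        d["demons"]["iterations"] = list(self.demons.iterations)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "demons" in d and isinstance(d["demons"], dict):
            dem = dict(d["demons"])
            for key in ("pyramid_shrinks", "iterations"):
                if key in dem:
                    dem[key] = tuple(dem[key])
            d["demons"] = DemonsConfig(**dem)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
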
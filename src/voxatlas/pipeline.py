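"""End-to-end atlas pipeline: fill → reference → register → aggregate.

Thin orchestration over the per-stage modules; every step is also usable
on its own.  The atlas produced here is the package's main product: a
reference-space grid where each voxel stores the sampling frequency, the
tumour-probability model and the two cell-density models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .dataset import PatientDataset
from .dpreg import (
    TransformChain,
    compose_and_apply,
    distance_preserving_register,
)
from .grid import VoxelGrid
from .refgeom import ReferenceGeometry, build_reference
from .slicefill import fill_patient
from .voxstats import (
    CellDensityModel,
    ModelFitReport,
    TumourProbabilityModel,
    evaluate_models,
    fit_density_model,
    sampling_frequency,
    tumour_probability,
)

__all__ = ["Atlas", "register_cohort", "warp_cohort", "build_atlas"]


@dataclass
class Atlas:
    """The voxelised statistical atlas and its evaluation reports."""

    reference: ReferenceGeometry
    n_map: VoxelGrid
    tumour: TumourProbabilityModel
    density_normal: CellDensityModel
    density_lognormal: CellDensityModel
    reports: tuple[ModelFitReport, ModelFitReport] | None = None
    meta: dict = field(default_factory=dict)


def register_cohort(
    cohort: list[PatientDataset],
    reference: ReferenceGeometry,
    config: PipelineConfig,
) -> list[TransformChain]:
    """Add the pinned-boundary PZ stage to every patient's stage-1 chain."""
    chains = []
    for ds, chain1 in zip(cohort, reference.chains):
        moving_pz = compose_and_apply(chain1, ds.pz_mask, reference.grid,
                                      mode="nearest")
        if moving_pz.values.any() and reference.pz.values.any():
            disp2 = distance_preserving_register(
                moving_pz,
                reference.pz,
                pin_boundary_of=reference.prostate,
                config=config.demons,
            )
            chains.append(TransformChain(list(chain1.stages) + [disp2]))
        else:
            chains.append(TransformChain(list(chain1.stages)))
    return chains


def warp_cohort(
    cohort: list[PatientDataset],
    chains: list[TransformChain],
    reference: ReferenceGeometry,
):
    """Warp validity, lesion and density volumes into the reference space.

    Density is warped with mask-weighted (normalised-convolution) linear
    interpolation: the density multiplied by its validity support and the
    support itself are both warped linearly and divided, so voxels near
    the edge of the sampled region are not diluted by the zeros outside
    it.  Validity itself is warped nearest-neighbour and gates inclusion.
    """
    validity, lesions, densities = [], [], []
    for ds, chain in zip(cohort, chains):
        valid_nn = compose_and_apply(chain, ds.validity_mask, reference.grid,
                                     mode="nearest")
        validity.append(valid_nn)
        lesions.append({
            g: compose_and_apply(chain, m, reference.grid, mode="linear")
            for g, m in ds.lesion_maps.items()
        })
        support = ds.validity_mask.copy_with(
            ds.validity_mask.values.astype(np.float32))
        weighted = ds.density.copy_with(
            ds.density.values * support.values)
        num = compose_and_apply(chain, weighted, reference.grid, mode="linear")
        den = compose_and_apply(chain, support, reference.grid, mode="linear")
        w = den.values
        dens = np.where(w > 0.5, num.values / np.maximum(w, 1e-6), 0.0)
        densities.append(reference.grid.copy_with(dens.astype(np.float32)))
    return validity, lesions, densities


def build_atlas(
    cohort: list[PatientDataset],
    config: PipelineConfig | None = None,
    fill: bool = True,
    evaluate: bool = True,
) -> Atlas:
    """Run the full pipeline on a cohort of (sparse) patient datasets."""
    if config is None:
        config = PipelineConfig()
    if fill:
        cohort = [fill_patient(ds, density_exponent=config.density_exponent)
                  for ds in cohort]
    reference = build_reference(cohort, config)
    chains = register_cohort(cohort, reference, config)
    validity, lesions, densities = warp_cohort(cohort, chains, reference)

    n_map = sampling_frequency(validity)
    tumour = tumour_probability(lesions, n_map)
    normal = fit_density_model(densities, validity, kind="normal",
                               min_samples=config.min_samples_fit)
    lognormal = fit_density_model(densities, validity, kind="lognormal",
                                  min_samples=config.min_samples_fit)
    reports = None
    if evaluate:
        reports = evaluate_models(
            densities, validity, normal, lognormal,
            min_samples=config.min_samples_kl,
            max_eval_voxels=config.max_eval_voxels,
            rng_seed=config.rng_seed,
        )
    return Atlas(
        reference=reference,
        n_map=n_map,
        tumour=tumour,
        density_normal=normal,
        density_lognormal=lognormal,
        reports=reports,
        meta={"n_patients": len(cohort), "config": config.to_dict()},
    )
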
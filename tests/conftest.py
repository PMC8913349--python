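"""Shared fixtures: small geometric shapes and phantom-cohort atlases.

The cohort-scale fixtures are session-scoped because registration of
tens to hundreds of phantom patients is the dominant cost of the suite;
they are built once and shared by the statistical tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from scipy import ndimage

from voxatlas.config import DemonsConfig, PipelineConfig
from voxatlas.grid import VoxelGrid
from voxatlas.phantom import PhantomSpec, cohort_truth, generate_cohort
from voxatlas.pipeline import build_atlas


def make_ball(n: int, radius: float, spacing: float = 1.0,
              centre=(0.0, 0.0, 0.0), radii=None, rot=None) -> VoxelGrid:
    """Binary ellipsoid mask on an n^3 grid centred on the origin."""
    ax = (np.arange(n) - (n - 1) / 2) * spacing
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([xx - centre[0], yy - centre[1], zz - centre[2]], axis=-1)
    if rot is not None:
        pts = pts @ rot
    if radii is None:
        radii = (radius, radius, radius)
    u = pts / np.asarray(radii, dtype=float)
    m = ((u**2).sum(axis=-1) <= 1.0).astype(np.uint8)
    origin = (-(n - 1) / 2 * spacing,) * 3
    return VoxelGrid(m, (spacing,) * 3, origin)


def resample_truth(truth: dict, key: str, reference: VoxelGrid,
                   scale: float = 1.0) -> np.ndarray:
    """Linearly sample a canonical-space truth field on the reference grid."""
    tg = truth["grid"]
    pts = reference.physical_coordinates().reshape(-1, 3)
    idx = tg.physical_to_index(pts)
    vals = ndimage.map_coordinates(
        truth[key].values, [idx[:, a] for a in range(3)], order=1)
    return vals.reshape(reference.shape) * scale


def fast_pipeline_config(**kw) -> PipelineConfig:
    """Working-resolution pipeline settings used for cohort-scale runs."""
    defaults = dict(
        iso_spacing=2.0,
        demons=DemonsConfig(pyramid_shrinks=(4, 2), iterations=(30, 15)),
        max_eval_voxels=1500,
    )
    defaults.update(kw)
    return PipelineConfig(**defaults)


def build_phantom_atlas(spec: PhantomSpec, evaluate: bool,
                        **config_kw):
    cfg = fast_pipeline_config(rng_seed=spec.rng_seed, **config_kw)
    cohort = generate_cohort(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        atlas = build_atlas(cohort, cfg, evaluate=evaluate)
    return cohort, atlas


@pytest.fixture(scope="session")
def small_cohort():
    spec = PhantomSpec(n_patients=6, in_plane_spacing=2.0, rng_seed=5)
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def small_atlas(small_cohort):
    spec, cohort = small_cohort
    cfg = fast_pipeline_config(rng_seed=spec.rng_seed, max_eval_voxels=200)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        atlas = build_atlas(cohort, cfg, evaluate=False)
    return spec, cohort, atlas


@pytest.fixture(scope="session")
def recovery_atlas():
    """200-patient phantom atlas plus exact generator truth."""
    spec = PhantomSpec(n_patients=200, in_plane_spacing=2.0, rng_seed=42)
    cohort, atlas = build_phantom_atlas(spec, evaluate=False)
    return spec, atlas, cohort_truth(spec)


@pytest.fixture(scope="session")
def lognormal_atlas_60():
    """60-patient cohort with log-normal densities, with KL evaluation."""
    spec = PhantomSpec(n_patients=60, in_plane_spacing=2.0, rng_seed=60)
    _, atlas = build_phantom_atlas(spec, evaluate=True)
    return spec, atlas


@pytest.fixture(scope="session")
def normal_atlas_60():
    """Mirrored control: normal-generated densities, linear-scaling
    volumetric conversion so normality survives the pipeline."""
    spec = PhantomSpec(n_patients=60, in_plane_spacing=2.0, rng_seed=61,
                       density_family="normal")
    _, atlas = build_phantom_atlas(spec, evaluate=True, density_exponent=1.0)
    return spec, atlas
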
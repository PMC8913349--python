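"""Synthetic patient-cohort generator ("phantom").

Generates cohorts with the statistical and sampling structure of an
ex-vivo prostate histology study, so every downstream pipeline stage can
be exercised and validated without any external data:

* an ellipsoid-like prostate gland with per-patient anisotropic scaling
  (default ±20%), rotation (default ±15°) and a small translation;
* a posterior-crescent peripheral zone (PZ) and a smooth urethra curve;
* tumour lesions seeded preferentially in the posterolateral PZ, each
  carrying a Gleason grade;
* log-normally distributed cell density (cells/mm^2), multiplied inside
  lesions, with long-range spatial smoothness so that slice interpolation
  and registration resampling approximately preserve per-voxel marginals;
* histology-style sparse annotation: data exist only on every second
  2.5 mm axial slice, with a margin excluded at the gland apex and base.

Lesions are spherical blobs with random radii whose centres follow a
marked Poisson process (Poisson count, i.i.d. seeds from a
posterolateral/whole-gland mixture).  This makes the latent per-voxel
lesion-coverage probability available in closed form,

    p(x) = 1 − exp(−λ · Σ_R w_R (f ⋆ 1_{B_R})(x)),

which :func:`cohort_truth` returns exactly — the basis of all
parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from scipy.spatial import cKDTree

from .dataset import PatientDataset
from .grid import VoxelGrid

__all__ = ["PhantomSpec", "generate_cohort", "generate_patient", "cohort_truth"]


@dataclass
class PhantomSpec:
    """Parameters of the synthetic cohort.

    Defaults emulate the study geometry: 2.5 mm axial slices with
    histology every 5 mm, apex/base sections excluded, ~40% of patients
    with at least one posterolateral-PZ focus (via ``lesion_rate`` ×
    ``pz_posterolateral_weight``), and log-normal baseline cell density.
    """

    n_patients: int = 10
    gland_radii: tuple[float, float, float] = (20.0, 16.0, 18.0)  # mm (LR, AP, SI)
    gland_scale_jitter: float = 0.2  # per-axis uniform scale ±20%
    rotation_max_deg: float = 15.0
    translation_max: float = 3.0  # mm
    pz_fraction: float = 0.35  # radial thickness fraction of posterior crescent
    lesion_rate: float = 1.2  # expected lesions per patient (Poisson)
    pz_posterolateral_weight: float = 0.45  # per-lesion posterolateral seed prob
    lesion_radii: tuple[float, ...] = (4.0, 6.0, 8.0)  # mm, uniform choice
    lateral_offset_frac: float = 0.25  # |x| > frac·r_x defines "lateral"
    grades: tuple[int, ...] = (3, 4, 5)
    density_family: str = "lognormal"  # {lognormal | normal}
    density_log_mean: float = 7.0  # log(cells/mm^2); e^7 ≈ 1100 cells/mm^2
    density_log_sd: float = 0.17  # per-voxel inter-patient spread, log space
    density_mean: float = 1100.0  # cells/mm^2, used when family == "normal"
    density_sd: float = 300.0
    lesion_density_multiplier: float = 2.0
    density_smooth_inplane: float = 3.0  # mm, GRF correlation scale
    density_smooth_axial: float = 9.0  # mm; long so adjacent slices correlate
    slice_spacing: float = 2.5  # mm
    in_plane_spacing: float = 1.0  # mm
    histology_interval: float = 5.0  # mm between annotated slices
    apex_base_margin: float = 5.0  # mm of gland excluded from annotation
    grid_margin: float = 6.0  # mm of air around the largest gland
    canonical_spacing: float = 1.5  # mm, seed/truth grid resolution
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not (0.0 < self.pz_fraction < 1.0):
            raise ValueError("pz_fraction must lie in (0, 1)")
        for name in ("pz_posterolateral_weight",):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        step = self.histology_interval / self.slice_spacing
        if abs(step - round(step)) > 1e-9 or round(step) < 1:
            raise ValueError(
                "histology_interval must be a positive integer multiple of "
                f"slice_spacing; got {self.histology_interval}/{self.slice_spacing}"
            )
        if self.density_family not in ("lognormal", "normal"):
            raise ValueError(f"unknown density_family {self.density_family!r}")

    @property
    def slice_step(self) -> int:
        return int(round(self.histology_interval / self.slice_spacing))


# ----------------------------------------------------------------------
# geometry helpers
# ----------------------------------------------------------------------
def _patient_grid(spec: PhantomSpec) -> VoxelGrid:
    r = np.asarray(spec.gland_radii)
    half = r.max() * (1.0 + spec.gland_scale_jitter) + spec.grid_margin
    sp = np.array([spec.in_plane_spacing, spec.in_plane_spacing,
                   spec.slice_spacing])
    shape = (np.ceil(2 * half / sp)).astype(int) + 1
    origin = -(shape - 1) * sp / 2.0
    return VoxelGrid(np.zeros(tuple(shape), dtype=np.uint8), sp, origin)


def _canonical_grid(spec: PhantomSpec) -> VoxelGrid:
    r = np.asarray(spec.gland_radii)
    half = r.max() + max(spec.lesion_radii) + spec.canonical_spacing
    sp = np.full(3, spec.canonical_spacing)
    shape = (np.ceil(2 * half / sp)).astype(int) + 1
    origin = -(shape - 1) * sp / 2.0
    return VoxelGrid(np.zeros(tuple(shape), dtype=np.uint8), sp, origin)


def _canonical_regions(spec: PhantomSpec, grid: VoxelGrid):
    """Gland / PZ / posterolateral-PZ boolean masks in canonical space."""
    r = np.asarray(spec.gland_radii)
    pts = grid.physical_coordinates()
    u = pts / r  # unit-ball coordinates
    rho = np.sqrt((u**2).sum(axis=-1))
    gland = rho <= 1.0
    pz = gland & (rho >= 1.0 - spec.pz_fraction) & (pts[..., 1] > 0)
    pl = pz & (np.abs(pts[..., 0]) > spec.lateral_offset_frac * r[0])
    return gland, pz, pl


def _rotation_matrix(angles_rad: np.ndarray) -> np.ndarray:
    ax, ay, az = angles_rad
    cx, sx = math.cos(ax), math.sin(ax)
    cy, sy = math.cos(ay), math.sin(ay)
    cz, sz = math.cos(az), math.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _urethra_curve(spec: PhantomSpec, n: int = 200) -> np.ndarray:
    """Smooth canonical-space urethra centreline, (n, 3) mm."""
    r = np.asarray(spec.gland_radii)
    t = np.linspace(-0.8, 0.8, n)
    x = 0.10 * r[0] * np.sin(1.5 * t)
    y = r[1] * (-0.25 + 0.08 * np.cos(1.2 * t))
    z = r[2] * t
    return np.stack([x, y, z], axis=1)


def _smooth_unit_field(rng: np.random.Generator, shape, sigma_vox) -> np.ndarray:
    """Stationary Gaussian random field with (near-)unit marginal variance.

    White noise filtered with a separable Gaussian (circular boundary so
    the field is stationary), normalised by the exact l2 norm of the
    discrete kernel so the marginal variance is analytically 1.
    """
    noise = rng.standard_normal(shape).astype(np.float64)
    out = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="wrap")
    norm = 1.0
    for ax, s in enumerate(sigma_vox):
        n = shape[ax]
        imp = np.zeros(n)
        imp[n // 2] = 1.0
        k = ndimage.gaussian_filter1d(imp, sigma=s, mode="wrap")
        norm *= float((k**2).sum())
    return out / math.sqrt(norm)


# ----------------------------------------------------------------------
# per-patient generation
# ----------------------------------------------------------------------
def _sample_lesions(spec: PhantomSpec, rng: np.random.Generator,
                    seed_sets: tuple[np.ndarray, np.ndarray]):
    """Draw (seed_xyz, radius, grade, is_posterolateral) for one patient."""
    pl_pts, gl_pts = seed_sets
    k = int(rng.poisson(spec.lesion_rate))
    lesions = []
    for _ in range(k):
        is_pl = bool(rng.random() < spec.pz_posterolateral_weight)
        pts = pl_pts if is_pl else gl_pts
        seed = pts[int(rng.integers(len(pts)))]
        radius = float(spec.lesion_radii[int(rng.integers(len(spec.lesion_radii)))])
        grade = int(spec.grades[int(rng.integers(len(spec.grades)))])
        lesions.append((seed, radius, grade, is_pl))
    return lesions


def generate_patient(spec: PhantomSpec, seed: int,
                     patient_id: str = "",
                     seed_sets=None) -> PatientDataset:
    """Generate one synthetic patient; pure function of (spec, seed)."""
    rng = np.random.default_rng(seed)
    grid = _patient_grid(spec)
    r = np.asarray(spec.gland_radii)

    if seed_sets is None:
        cgrid = _canonical_grid(spec)
        _, _, pl = _canonical_regions(spec, cgrid)
        gland_c, _, _ = _canonical_regions(spec, cgrid)
        pts_c = cgrid.physical_coordinates()
        seed_sets = (pts_c[pl], pts_c[gland_c])

    # anatomy transform: x_patient = centre + R diag(s) x_canonical
    s = rng.uniform(1 - spec.gland_scale_jitter, 1 + spec.gland_scale_jitter, 3)
    ang = np.deg2rad(rng.uniform(-spec.rotation_max_deg,
                                 spec.rotation_max_deg, 3))
    rot = _rotation_matrix(ang)
    centre = rng.uniform(-spec.translation_max, spec.translation_max, 3)

    pts = grid.physical_coordinates()  # (nx,ny,nz,3), patient mm
    canon = (pts - centre) @ rot / s  # inverse map to canonical mm
    u = canon / r
    rho = np.sqrt((u**2).sum(axis=-1))
    gland = rho <= 1.0
    pz = gland & (rho >= 1.0 - spec.pz_fraction) & (canon[..., 1] > 0)

    # urethra tube, fixed 1.5 mm radius in patient space
    curve_c = _urethra_curve(spec)
    curve_p = centre + (curve_c * s) @ rot.T
    tree = cKDTree(curve_p)
    dist, _ = tree.query(pts[gland], k=1)
    urethra = np.zeros(grid.shape, dtype=bool)
    urethra[gland] = dist <= 1.5

    # lesions
    lesions = _sample_lesions(spec, rng, seed_sets)
    grade_vol = np.zeros(grid.shape, dtype=np.int16)
    for seed_xyz, radius, grade, _ in lesions:
        d2 = ((canon - seed_xyz) ** 2).sum(axis=-1)
        cover = (d2 <= radius**2) & gland
        # highest grade wins where lesions of different grades overlap
        grade_vol[cover] = np.maximum(grade_vol[cover], grade)
    any_lesion = grade_vol > 0

    # cell density (cross-sectional, cells/mm^2)
    sp = grid.spacing
    sigma_vox = (spec.density_smooth_inplane / sp[0],
                 spec.density_smooth_inplane / sp[1],
                 spec.density_smooth_axial / sp[2])
    g = _smooth_unit_field(rng, grid.shape, sigma_vox)
    mult = spec.lesion_density_multiplier
    if spec.density_family == "lognormal":
        logc = spec.density_log_mean + spec.density_log_sd * g
        logc = logc + math.log(mult) * any_lesion
        density = np.exp(logc)
    else:
        density = np.maximum(spec.density_mean + spec.density_sd * g, 0.0)
        density = density * np.where(any_lesion, mult, 1.0)
    density = density * gland

    # histology-style sparse annotation along the slice axis
    gland_z = np.where(gland.any(axis=(0, 1)))[0]
    z_mm = grid.origin[2] + np.arange(grid.shape[2]) * sp[2]
    lo_mm = z_mm[gland_z[0]] + spec.apex_base_margin
    hi_mm = z_mm[gland_z[-1]] - spec.apex_base_margin
    eligible = [int(k) for k in range(grid.shape[2]) if lo_mm <= z_mm[k] <= hi_mm]
    if len(eligible) < 3:
        raise ValueError("gland too thin for the requested apex/base margin")
    annotated = eligible[:: spec.slice_step]
    if len(annotated) < 2:
        raise ValueError("fewer than two annotated slices; reduce margins")

    ann = np.zeros(grid.shape[2], dtype=bool)
    ann[annotated] = True
    density = density * ann[None, None, :]
    lesion_maps = {}
    for grade in spec.grades:
        m = ((grade_vol == grade) & ann[None, None, :]).astype(np.uint8)
        lesion_maps[int(grade)] = grid.copy_with(m)

    validity = (gland & ann[None, None, :]).astype(np.uint8)

    return PatientDataset(
        prostate_mask=grid.copy_with(gland.astype(np.uint8)),
        pz_mask=grid.copy_with(pz.astype(np.uint8)),
        urethra_mask=grid.copy_with(urethra.astype(np.uint8)),
        lesion_maps=lesion_maps,
        density=grid.copy_with(density.astype(np.float32)),
        annotated_slices=list(annotated),
        validity_mask=grid.copy_with(validity),
        mri=None,
        density_is_volumetric=False,
        patient_id=patient_id,
        meta={
            "scales": s.tolist(),
            "rotation_deg": np.rad2deg(ang).tolist(),
            "centre": centre.tolist(),
            "n_lesions": len(lesions),
            "n_posterolateral": int(sum(1 for L in lesions if L[3])),
            "lesion_grades": [int(L[2]) for L in lesions],
        },
    )


def generate_cohort(spec: PhantomSpec) -> list[PatientDataset]:
    """Generate the full cohort; deterministic given the spec (incl. seed)."""
    master = np.random.default_rng(spec.rng_seed)
    seeds = master.integers(0, 2**31 - 1, size=spec.n_patients)
    cgrid = _canonical_grid(spec)
    gland_c, _, pl_c = _canonical_regions(spec, cgrid)
    pts_c = cgrid.physical_coordinates()
    seed_sets = (pts_c[pl_c], pts_c[gland_c])
    return [
        generate_patient(spec, int(seeds[i]), patient_id=f"patient_{i:03d}",
                         seed_sets=seed_sets)
        for i in range(spec.n_patients)
    ]


# ----------------------------------------------------------------------
# ground truth
# ----------------------------------------------------------------------
def _ball_kernel(radius_mm: float, spacing: float) -> np.ndarray:
    n = int(math.ceil(radius_mm / spacing))
    ax = np.arange(-n, n + 1) * spacing
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    return (xx**2 + yy**2 + zz**2 <= radius_mm**2).astype(float)


def cohort_truth(spec: PhantomSpec) -> dict:
    """Exact latent fields of the generator, independent of the RNG seed.

    Returns a dict with the canonical-space grids:

    * ``lesion_probability`` — per-voxel probability that a patient has a
      lesion (any grade) at that canonical location;
    * ``log_density_mean`` / ``log_density_var`` / ``log_density_mu4`` —
      per-voxel mean, variance and central fourth moment of the log
      cell-density distribution across patients (Bernoulli lesion mixture
      of two normals), for the log-normal density family;
    * ``density_mean`` / ``density_var`` — linear-space analogues for the
      truncated-normal family (ignoring the truncation at 0);
    * ``gland_mask`` — the canonical gland;

    plus the scalar generator parameters.
    """
    grid = _canonical_grid(spec)
    gland, pz, pl = _canonical_regions(spec, grid)
    n_pl = int(pl.sum())
    n_gl = int(gland.sum())
    if n_gl == 0:
        raise ValueError("degenerate spec: empty gland")

    w = spec.pz_posterolateral_weight
    seed_mass = np.zeros(grid.shape)
    if n_pl > 0:
        seed_mass[pl] += w / n_pl
    seed_mass[gland] += (1.0 - w) / n_gl

    m = np.zeros(grid.shape)
    for radius in spec.lesion_radii:
        kern = _ball_kernel(radius, spec.canonical_spacing)
        m += signal.fftconvolve(seed_mass, kern, mode="same") / len(spec.lesion_radii)
    m = np.clip(m, 0.0, None) * spec.lesion_rate
    p = (1.0 - np.exp(-m)) * gland

    a = math.log(spec.lesion_density_multiplier)
    s2 = spec.density_log_sd**2
    mean_log = spec.density_log_mean + a * p
    var_log = s2 + a**2 * p * (1 - p)
    # central 4th moment of the two-component normal mixture
    q = 1 - p
    d1, d2 = -a * p, a * q
    mu4 = (q * (3 * s2**2 + 6 * s2 * d1**2 + d1**4)
           + p * (3 * s2**2 + 6 * s2 * d2**2 + d2**4))

    mult = spec.lesion_density_multiplier
    mean_lin = spec.density_mean * (1 + (mult - 1) * p)
    var_lin = (spec.density_sd**2
               + (mult - 1) ** 2 * spec.density_mean**2 * p * (1 - p))

    return {
        "grid": grid,
        "gland_mask": grid.copy_with(gland.astype(np.uint8)),
        "pz_mask": grid.copy_with(pz.astype(np.uint8)),
        "lesion_probability": grid.copy_with(p),
        "log_density_mean": grid.copy_with(mean_log),
        "log_density_var": grid.copy_with(var_log),
        "log_density_mu4": grid.copy_with(mu4),
        "density_mean": grid.copy_with(mean_lin * gland),
        "density_var": grid.copy_with(var_lin * gland),
        "params": {
            "lesion_rate": spec.lesion_rate,
            "pz_posterolateral_weight": spec.pz_posterolateral_weight,
            "density_log_mean": spec.density_log_mean,
            "density_log_sd": spec.density_log_sd,
            "lesion_density_multiplier": spec.lesion_density_multiplier,
            "density_family": spec.density_family,
        },
    }
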
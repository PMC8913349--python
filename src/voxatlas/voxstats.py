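"""Voxel-level statistical models of the atlas.

Once every patient's lesion and density data are warped to the reference
geometry, each reference voxel x holds up to n(x) samples, where n(x) is
the number of patients with valid (histology-sampled) data there.

* **Tumour probability.**  The frequency of tumour occurrence F(x) in a
  sample of size n(x) is binomial, F ~ B(n, p), approximated by a normal
  N(μ = n·p, σ² = n·p·(1−p)).  The probabilistic lesion labels make the
  per-patient "occurrence" a weight in [0, 1]; p is the weight sum over
  the sampling frequency.  Relative uncertainty is the coefficient of
  variation CV = σ/μ = sqrt((1−p)/(n·p)).
* **Cell density.**  Per voxel, the cohort's density samples c_i are fit
  with (1) a normal and (2) a log-normal model, both with 1/n
  (maximum-likelihood) variance.  Model suitability is judged against a
  Gaussian kernel density estimate (Scott's-rule bandwidth) of the
  empirical distribution via the Kullback–Leibler divergence in bits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import VoxelGrid

__all__ = [
    "TumourProbabilityModel",
    "CellDensityModel",
    "ModelFitReport",
    "KernelDensity1D",
    "sampling_frequency",
    "tumour_probability",
    "fit_density_model",
    "kde_estimate",
    "kl_divergence",
    "evaluate_models",
]


# ----------------------------------------------------------------------
# sampling frequency
# ----------------------------------------------------------------------
def sampling_frequency(warped_validity_masks: list[VoxelGrid]) -> VoxelGrid:
    """Per-voxel count of patients with valid data; integer ≤ cohort size."""
    if not warped_validity_masks:
        raise ValueError("empty cohort: no validity masks")
    ref = warped_validity_masks[0]
    n = np.zeros(ref.shape, dtype=np.int32)
    for m in warped_validity_masks:
        ref.require_aligned(m, what="sampling frequency")
        n += m.values.astype(bool)
    return ref.copy_with(n)


# ----------------------------------------------------------------------
# tumour probability model
# ----------------------------------------------------------------------
@dataclass
class TumourProbabilityModel:
    """Per-voxel binomial/normal tumour-occurrence model.

    ``sigma2`` is n·p·(1−p) (frequency scale); ``rate_var`` is the
    sampling-frequency-normalised variance p·(1−p)/n (rate scale).
    ``cv`` is defined where n>0 and p>0 and NaN-flagged elsewhere.
    """

    n: VoxelGrid
    p: VoxelGrid
    mu: VoxelGrid
    sigma2: VoxelGrid
    rate_var: VoxelGrid
    cv: VoxelGrid
    per_grade_p: dict[int, VoxelGrid] = field(default_factory=dict)


def tumour_probability(
    warped_lesion_maps: list[dict[int, VoxelGrid]],
    n_map: VoxelGrid,
) -> TumourProbabilityModel:
    """Aggregate per-patient graded lesion weights into the tumour model.

    Each patient's any-grade tumour weight is min(1, Σ_grades weight);
    p = Σ_patients weight / n where n > 0.  μ = n·p, σ² = n·p·(1−p),
    CV = sqrt((1−p)/(n·p)).
    """
    if not warped_lesion_maps:
        raise ValueError("no lesion maps supplied")
    n = n_map.values.astype(float)
    weight_sum = np.zeros(n_map.shape)
    grade_sums: dict[int, np.ndarray] = {}
    for patient in warped_lesion_maps:
        any_w = np.zeros(n_map.shape)
        for g, m in patient.items():
            n_map.require_aligned(m, what="tumour probability")
            v = m.values.astype(float)
            if v.min() < -1e-9 or v.max() > 1 + 1e-9:
                raise ValueError("lesion weights must lie in [0, 1]")
            any_w += v
            grade_sums.setdefault(g, np.zeros(n_map.shape))
            grade_sums[g] += v
        weight_sum += np.minimum(any_w, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, weight_sum / np.maximum(n, 1), 0.0)
        p = np.clip(p, 0.0, 1.0)
        mu = n * p
        sigma2 = n * p * (1.0 - p)
        rate_var = np.where(n > 0, p * (1.0 - p) / np.maximum(n, 1), np.nan)
        cv = np.where((n > 0) & (p > 0),
                      np.sqrt((1.0 - p) / np.maximum(n * p, 1e-300)), np.nan)
    per_grade = {
        g: n_map.copy_with(
            np.where(n > 0, np.clip(s / np.maximum(n, 1), 0, 1), 0.0))
        for g, s in grade_sums.items()
    }
    return TumourProbabilityModel(
        n=n_map,
        p=n_map.copy_with(p),
        mu=n_map.copy_with(mu),
        sigma2=n_map.copy_with(sigma2),
        rate_var=n_map.copy_with(rate_var),
        cv=n_map.copy_with(cv),
        per_grade_p=per_grade,
    )


def binomial_cv(n: float, p: float) -> float:
    """Closed-form coefficient of variation sqrt((1−p)/(n·p))."""
    if n <= 0 or p <= 0:
        return float("nan")
    return float(np.sqrt((1.0 - p) / (n * p)))


# ----------------------------------------------------------------------
# cell-density models
# ----------------------------------------------------------------------
@dataclass
class CellDensityModel:
    """Per-voxel normal or log-normal density model (1/n variance).

    For the normal kind, ``mu``/``sigma2`` are in density units; CV =
    sqrt(σ²)/μ where μ>0.  For the log-normal kind they are in log
    units; CV = sqrt(exp(σ²) − 1), a closed form free of n.  ``n`` is the
    per-voxel count actually used (zero-density samples are excluded
    from the log fit); ``fitted`` flags voxels meeting the minimum-sample
    rule.
    """

    kind: str
    mu: VoxelGrid
    sigma2: VoxelGrid
    n: VoxelGrid
    cv: VoxelGrid
    fitted: VoxelGrid


def _stack_samples(warped_density_maps, warped_validity_masks):
    dens = np.stack([m.values for m in warped_density_maps], axis=0)
    valid = np.stack([m.values.astype(bool) for m in warped_validity_masks],
                     axis=0)
    return dens, valid


def fit_density_model(
    warped_density_maps: list[VoxelGrid],
    warped_validity_masks: list[VoxelGrid],
    kind: str = "lognormal",
    min_samples: int = 3,
) -> CellDensityModel:
    """Fit per-voxel density models over valid cohort samples.

    Mean and variance use the 1/n maximum-likelihood forms.  The
    log-normal fit works on log samples, with zero-density samples
    excluded at that voxel (count adjusted accordingly).  Voxels with
    fewer than ``min_samples`` usable samples are flagged unfitted.
    """
    if kind not in ("normal", "lognormal"):
        raise ValueError(f"unknown model kind {kind!r}")
    if len(warped_density_maps) != len(warped_validity_masks):
        raise ValueError("density maps and validity masks must pair up")
    ref = warped_density_maps[0]
    for m in list(warped_density_maps) + list(warped_validity_masks):
        ref.require_aligned(m, what="density model fit")
    dens, valid = _stack_samples(warped_density_maps, warped_validity_masks)

    if kind == "lognormal":
        usable = valid & (dens > 0)
        with np.errstate(divide="ignore"):
            x = np.where(usable, np.log(np.maximum(dens, 1e-300)), 0.0)
    else:
        usable = valid
        x = np.where(usable, dens, 0.0)

    n = usable.sum(axis=0).astype(float)
    n_safe = np.maximum(n, 1.0)
    mu = x.sum(axis=0) / n_safe
    sigma2 = (x**2).sum(axis=0) / n_safe - mu**2
    sigma2 = np.maximum(sigma2, 0.0)  # guard tiny negative round-off
    fitted = n >= min_samples
    mu = np.where(fitted, mu, np.nan)
    sigma2 = np.where(fitted, sigma2, np.nan)

    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        if kind == "lognormal":
            cv = np.sqrt(np.expm1(sigma2))
        else:
            cv = np.where(mu > 0, np.sqrt(sigma2) / mu, np.nan)

    return CellDensityModel(
        kind=kind,
        mu=ref.copy_with(mu),
        sigma2=ref.copy_with(sigma2),
        n=ref.copy_with(n),
        cv=ref.copy_with(cv),
        fitted=ref.copy_with(fitted.astype(np.uint8)),
    )


# ----------------------------------------------------------------------
# KDE and KL divergence
# ----------------------------------------------------------------------
class KernelDensity1D:
    """Gaussian-kernel density estimate with the 1D Scott's-rule bandwidth
    h = σ̂ · n^(−1/5), σ̂ the sample standard deviation."""

    def __init__(self, samples: np.ndarray):
        x = np.asarray(samples, dtype=float).ravel()
        if x.size < 2:
            raise ValueError("KDE requires at least two samples")
        sd = float(np.std(x, ddof=1))
        if sd == 0.0:
            raise ValueError("all samples identical: degenerate KDE bandwidth")
        self.samples = x
        self.n = x.size
        self.bandwidth = sd * self.n ** (-1.0 / 5.0)

    def __call__(self, grid: np.ndarray) -> np.ndarray:
        g = np.asarray(grid, dtype=float)
        z = (g[..., None] - self.samples) / self.bandwidth
        k = np.exp(-0.5 * z**2) / np.sqrt(2 * np.pi)
        return k.sum(axis=-1) / (self.n * self.bandwidth)


def kde_estimate(samples) -> KernelDensity1D:
    """Scott's-rule Gaussian KDE of a 1D sample."""
    return KernelDensity1D(np.asarray(samples))


def _default_grid(samples: np.ndarray, bandwidth: float,
                  n_points: int = 512) -> np.ndarray:
    lo = max(0.0, float(np.min(samples)) - 4.0 * bandwidth)
    hi = float(np.max(samples)) + 4.0 * bandwidth
    return np.linspace(lo, hi, n_points)


def kl_divergence(
    empirical, model, grid: np.ndarray, floor: float = 1e-30
) -> float:
    """KL divergence D(empirical ‖ model) in bits on an evaluation grid.

    Both densities are renormalised (trapezoid rule) on the grid before
    integrating empirical·log2(empirical/model).  The model density is
    floored inside the integrand; if the floor is hit where the empirical
    density is non-negligible, the (capped) contribution triggers a
    warning.
    """
    f = np.asarray(empirical(grid) if callable(empirical) else empirical,
                   dtype=float)
    g = np.asarray(model(grid) if callable(model) else model, dtype=float)
    zf = np.trapezoid(f, grid)
    zg = np.trapezoid(g, grid)
    if zf <= 0 or zg <= 0:
        raise ValueError("densities must have positive mass on the grid")
    f = f / zf
    g = g / zg
    if np.any((g < floor) & (f > 1e-12)):
        warnings.warn("model density underflows where the empirical density "
                      "is positive; contribution capped", RuntimeWarning)
    integrand = np.where(f > 0, f * np.log2(np.maximum(f, floor)
                                            / np.maximum(g, floor)), 0.0)
    return float(np.trapezoid(integrand, grid))


# ----------------------------------------------------------------------
# per-voxel model evaluation
# ----------------------------------------------------------------------
@dataclass
class ModelFitReport:
    """Per-voxel KL divergence of one density model vs the empirical KDE."""

    kind: str
    dkl_map: VoxelGrid
    evaluated_mask: VoxelGrid
    mean: float
    sd: float
    histogram: tuple[np.ndarray, np.ndarray]  # (bin_edges, counts)


def _model_pdf(kind: str, mu: float, sigma2: float):
    sd = np.sqrt(max(sigma2, 1e-300))
    if kind == "normal":
        def pdf(c):
            return (np.exp(-0.5 * ((c - mu) / sd) ** 2)
                    / (sd * np.sqrt(2 * np.pi)))
    else:
        def pdf(c):
            c = np.asarray(c, dtype=float)
            out = np.zeros_like(c)
            pos = c > 0
            out[pos] = (np.exp(-0.5 * ((np.log(c[pos]) - mu) / sd) ** 2)
                        / (c[pos] * sd * np.sqrt(2 * np.pi)))
            return out
    return pdf


def evaluate_models(
    warped_density_maps: list[VoxelGrid],
    warped_validity_masks: list[VoxelGrid],
    normal_model: CellDensityModel,
    lognormal_model: CellDensityModel,
    min_samples: int = 5,
    max_eval_voxels: int = 0,
    rng_seed: int = 0,
    n_grid: int = 512,
) -> tuple[ModelFitReport, ModelFitReport]:
    """Per-voxel KL divergence of both density models against the KDE.

    Voxels need ``min_samples`` valid positive samples and a fitted model
    of both kinds; both reports share the same evaluated mask.  If
    ``max_eval_voxels`` > 0, a seeded random subsample of that size is
    evaluated instead of every eligible voxel.
    """
    dens, valid = _stack_samples(warped_density_maps, warped_validity_masks)
    usable = valid & (dens > 0)
    n = usable.sum(axis=0)
    eligible = ((n >= min_samples)
                & (normal_model.fitted.values > 0)
                & (lognormal_model.fitted.values > 0))
    # KDE needs spread; degenerate all-equal voxels are excluded
    idx = np.argwhere(eligible)
    if idx.size == 0:
        raise ValueError("no voxels eligible for model evaluation")
    if max_eval_voxels and len(idx) > max_eval_voxels:
        rng = np.random.default_rng(rng_seed)
        sel = rng.choice(len(idx), size=max_eval_voxels, replace=False)
        idx = idx[np.sort(sel)]

    ref = warped_density_maps[0]
    dkl_n = np.full(ref.shape, np.nan)
    dkl_l = np.full(ref.shape, np.nan)
    evaluated = np.zeros(ref.shape, dtype=np.uint8)
    for i, j, k in idx:
        samples = dens[usable[:, i, j, k], i, j, k]
        if np.std(samples, ddof=1) == 0:
            continue
        kde = KernelDensity1D(samples)
        grid = _default_grid(samples, kde.bandwidth, n_grid)
        f = kde(grid)
        pdf_n = _model_pdf("normal", normal_model.mu.values[i, j, k],
                           normal_model.sigma2.values[i, j, k])
        pdf_l = _model_pdf("lognormal", lognormal_model.mu.values[i, j, k],
                           lognormal_model.sigma2.values[i, j, k])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            dkl_n[i, j, k] = kl_divergence(f, pdf_n(grid), grid)
            dkl_l[i, j, k] = kl_divergence(f, pdf_l(grid), grid)
        evaluated[i, j, k] = 1

    mask = evaluated.astype(bool)
    if not mask.any():
        raise ValueError("no voxels could be evaluated")
    reports = []
    for kind, dkl in (("normal", dkl_n), ("lognormal", dkl_l)):
        vals = dkl[mask]
        counts, edges = np.histogram(vals, bins=50)
        reports.append(ModelFitReport(
            kind=kind,
            dkl_map=ref.copy_with(dkl),
            evaluated_mask=ref.copy_with(evaluated),
            mean=float(vals.mean()),
            sd=float(vals.std()),
            histogram=(edges, counts),
        ))
    return reports[0], reports[1]
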
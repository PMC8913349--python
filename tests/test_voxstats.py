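"""Voxel-level statistics: tumour probability, density models, KDE/KL."""

import numpy as np
import pytest
from scipy import stats

from voxatlas.grid import GridAlignmentError, VoxelGrid
from voxatlas.voxstats import (
    KernelDensity1D,
    _default_grid,
    binomial_cv,
    evaluate_models,
    fit_density_model,
    kde_estimate,
    kl_divergence,
    sampling_frequency,
    tumour_probability,
)


def grids(n_patients, shape=(3, 3, 3), value=1):
    base = VoxelGrid(np.zeros(shape, dtype=np.uint8), (1, 1, 1))
    return [base.copy_with(np.full(shape, value, dtype=np.uint8))
            for _ in range(n_patients)]


class TestSamplingFrequency:
    def test_counts_valid_patients(self):
        masks = grids(7)
        masks[0].values[0, 0, 0] = 0
        n = sampling_frequency(masks)
        assert n.values[0, 0, 0] == 6
        assert n.values[1, 1, 1] == 7
        assert n.values.max() <= 7

    def test_empty_cohort_and_misalignment(self):
        with pytest.raises(ValueError):
            sampling_frequency([])
        a = VoxelGrid(np.ones((3, 3, 3), dtype=np.uint8), (1, 1, 1))
        b = VoxelGrid(np.ones((3, 3, 3), dtype=np.uint8), (2, 2, 2))
        with pytest.raises(GridAlignmentError):
            sampling_frequency([a, b])

    def test_tapered_sampling_towards_apex_base(self, small_atlas):
        """n(x) decreases towards the gland poles along the slice axis."""
        _, _, atlas = small_atlas
        n = atlas.n_map.values
        prof = np.array([n[:, :, k].max() for k in range(n.shape[2])])
        ks = np.where(prof > 0)[0]
        peak = prof.max()
        assert prof[ks[0]] < peak and prof[ks[-1]] < peak
        k_peak = int(np.argmax(prof))
        assert np.all(np.diff(prof[ks[0]:k_peak + 1]) >= 0) or \
            prof[ks[0]:k_peak].min() < peak


class TestTumourProbability:
    def test_all_patients_lesion_gives_p_one(self):
        n_map = VoxelGrid(np.full((2, 2, 2), 10, dtype=np.int32), (1, 1, 1))
        lesions = [{3: n_map.copy_with(np.ones((2, 2, 2)))} for _ in range(10)]
        model = tumour_probability(lesions, n_map)
        assert model.p.values[0, 0, 0] == 1.0
        assert model.sigma2.values[0, 0, 0] == 0.0
        assert model.cv.values[0, 0, 0] == 0.0

    def test_worked_arithmetic_n63(self):
        """n = 63 with summed weights 25.2 gives p = 0.4, CV ~ 0.1543."""
        n_map = VoxelGrid(np.full((1, 1, 1), 63, dtype=np.int32), (1, 1, 1))
        w = 25.2 / 63.0
        lesions = [{4: n_map.copy_with(np.full((1, 1, 1), w))}
                   for _ in range(63)]
        model = tumour_probability(lesions, n_map)
        assert model.p.values[0, 0, 0] == pytest.approx(0.4, abs=1e-9)
        assert model.cv.values[0, 0, 0] == pytest.approx(
            np.sqrt(0.6 / 25.2), abs=1e-9)
        assert model.cv.values[0, 0, 0] == pytest.approx(0.1543, abs=2e-4)
        # sigma2 equals n p (1-p) recomputed independently
        assert model.sigma2.values[0, 0, 0] == pytest.approx(
            63 * 0.4 * 0.6, abs=1e-9)
        # rate-scale variance p(1-p)/n
        assert model.rate_var.values[0, 0, 0] == pytest.approx(
            0.4 * 0.6 / 63, abs=1e-12)

    def test_p_zero_flagged_undefined(self):
        n_map = VoxelGrid(np.full((2, 2, 2), 5, dtype=np.int32), (1, 1, 1))
        lesions = [{3: n_map.copy_with(np.zeros((2, 2, 2)))} for _ in range(5)]
        model = tumour_probability(lesions, n_map)
        assert np.isnan(model.cv.values).all()
        assert model.p.values.max() == 0.0

    def test_weights_capped_across_grades(self):
        n_map = VoxelGrid(np.full((1, 1, 1), 4, dtype=np.int32), (1, 1, 1))
        lesions = [{3: n_map.copy_with(np.full((1, 1, 1), 0.7)),
                    4: n_map.copy_with(np.full((1, 1, 1), 0.7))}
                   for _ in range(4)]
        model = tumour_probability(lesions, n_map)
        assert model.p.values[0, 0, 0] == 1.0  # min(1, 1.4) per patient

    def test_sigma2_identity_random(self):
        rng = np.random.default_rng(0)
        shape = (4, 4, 4)
        n_map = VoxelGrid(rng.integers(1, 20, shape).astype(np.int32),
                          (1, 1, 1))
        lesions = [{3: n_map.copy_with(rng.uniform(0, 1, shape))}
                   for _ in range(8)]
        model = tumour_probability(lesions, n_map)
        np.testing.assert_allclose(
            model.sigma2.values,
            n_map.values * model.p.values * (1 - model.p.values), atol=1e-9)


class TestBinomialCV:
    @pytest.mark.parametrize("n", [10, 63, 200])
    @pytest.mark.parametrize("p", [0.1, 0.4, 0.9])
    def test_closed_form_matches_monte_carlo(self, n, p):
        """CV = sqrt((1-p)/(n p)) vs the empirical CV of binomial draws."""
        rng = np.random.default_rng(1000 + n + int(p * 10))
        draws = rng.binomial(n, p, size=100_000)
        emp_cv = draws.std() / draws.mean()
        assert abs(emp_cv - binomial_cv(n, p)) / binomial_cv(n, p) < 0.02


class TestDensityModels:
    def make_inputs(self, samples, shape=(1, 1, 1)):
        base = VoxelGrid(np.zeros(shape), (1, 1, 1))
        dens = [base.copy_with(np.full(shape, s, dtype=float)) for s in samples]
        valid = [base.copy_with(np.ones(shape, dtype=np.uint8)) for _ in samples]
        return dens, valid

    def test_degenerate_all_equal(self):
        dens, valid = self.make_inputs([50.0] * 5)
        nm = fit_density_model(dens, valid, kind="normal")
        lm = fit_density_model(dens, valid, kind="lognormal")
        assert nm.mu.values[0, 0, 0] == pytest.approx(50.0)
        assert nm.sigma2.values[0, 0, 0] == pytest.approx(0.0, abs=1e-9)
        assert lm.mu.values[0, 0, 0] == pytest.approx(np.log(50.0))
        assert lm.sigma2.values[0, 0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_lognormal_one_over_n_form(self):
        """Samples {e^1, e^3}: mu = 2, sigma2 = 1 with the 1/n variance."""
        dens, valid = self.make_inputs([np.e, np.e**3])
        lm = fit_density_model(dens, valid, kind="lognormal", min_samples=2)
        assert lm.mu.values[0, 0, 0] == pytest.approx(2.0, abs=1e-9)
        assert lm.sigma2.values[0, 0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_zero_samples_excluded_from_log_fit(self):
        dens, valid = self.make_inputs([np.e, np.e**3, 0.0])
        lm = fit_density_model(dens, valid, kind="lognormal", min_samples=2)
        assert lm.n.values[0, 0, 0] == 2
        assert lm.mu.values[0, 0, 0] == pytest.approx(2.0, abs=1e-9)

    def test_min_samples_flags_unfit(self):
        dens, valid = self.make_inputs([10.0, 20.0])
        m = fit_density_model(dens, valid, kind="normal", min_samples=3)
        assert m.fitted.values[0, 0, 0] == 0
        assert np.isnan(m.mu.values[0, 0, 0])

    def test_lognormal_cv_closed_form(self):
        rng = np.random.default_rng(3)
        dens, valid = self.make_inputs(rng.uniform(10, 1000, 8))
        lm = fit_density_model(dens, valid, kind="lognormal")
        np.testing.assert_allclose(
            lm.cv.values, np.sqrt(np.expm1(lm.sigma2.values)), atol=1e-12)

    def test_unknown_kind_rejected(self):
        dens, valid = self.make_inputs([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            fit_density_model(dens, valid, kind="gamma")


class TestKDE:
    def test_scotts_rule_worked_example(self):
        """32 samples with sample sd 2 give bandwidth 2 * 32^(-1/5) = 1."""
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 32)
        x = (x - x.mean()) / x.std(ddof=1) * 2.0 + 10.0
        kde = kde_estimate(x)
        assert kde.bandwidth == pytest.approx(1.0, abs=1e-9)

    def test_integrates_to_one(self):
        rng = np.random.default_rng(5)
        x = rng.lognormal(3, 0.4, 200)
        kde = kde_estimate(x)
        grid = np.linspace(x.min() - 5 * kde.bandwidth,
                           x.max() + 5 * kde.bandwidth, 4096)
        mass = np.trapezoid(kde(grid), grid)
        assert abs(mass - 1.0) < 1e-3

    def test_consistency_standard_normal(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 10_000)
        kde = kde_estimate(x)
        grid = np.linspace(-6, 6, 2001)
        f = kde(grid)
        mean = np.trapezoid(grid * f, grid) / np.trapezoid(f, grid)
        assert abs(mean) < 0.05

    def test_two_samples_symmetric_mixture(self):
        """Two samples {0, 10}: equal-weight kernel mixture symmetric
        about 5 (Scott's n=2 bandwidth is broad, so the modes can merge,
        but the symmetry and the kernel centres are exact)."""
        kde = kde_estimate([0.0, 10.0])
        grid = np.linspace(-10, 20, 3001)
        f = kde(grid)
        np.testing.assert_allclose(f, f[::-1], atol=1e-12)
        h = kde.bandwidth
        expected_at_0 = (np.exp(0.0) + np.exp(-0.5 * (10 / h) ** 2)) \
            / (2 * h * np.sqrt(2 * np.pi))
        assert kde(np.array([0.0]))[0] == pytest.approx(expected_at_0)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            kde_estimate([3.0, 3.0, 3.0])
        with pytest.raises(ValueError):
            kde_estimate([1.0])

    def test_matches_scipy_oracle(self):
        """Independent cross-check against scipy's Scott-rule KDE."""
        rng = np.random.default_rng(7)
        x = rng.gamma(4, 50, 100)
        ours = kde_estimate(x)
        # scipy uses the same n^(-1/5) factor on the data std (ddof=1)
        ref = stats.gaussian_kde(x, bw_method="scott")
        grid = np.linspace(x.min(), x.max(), 200)
        np.testing.assert_allclose(ours(grid), ref(grid), rtol=1e-6)


class TestKLDivergence:
    def test_self_divergence_zero(self):
        pdf = stats.norm(5, 2).pdf
        grid = np.linspace(-5, 15, 2001)
        assert abs(kl_divergence(pdf, pdf, grid)) < 1e-6

    def test_gaussian_pair_closed_form(self):
        """Unit-variance normals one mean apart: 1/(2 ln 2) ~ 0.7213 bits."""
        f = stats.norm(0, 1).pdf
        g = stats.norm(1, 1).pdf
        grid = np.linspace(-10, 11, 4001)
        expected = 1.0 / (2.0 * np.log(2.0))
        assert kl_divergence(f, g, grid) == pytest.approx(expected, rel=0.01)

    def test_non_negative_random_pairs(self):
        rng = np.random.default_rng(8)
        grid = np.linspace(0.01, 30, 2001)
        for _ in range(10):
            f = stats.lognorm(s=rng.uniform(0.2, 0.8),
                              scale=rng.uniform(2, 8)).pdf
            g = stats.norm(rng.uniform(2, 8), rng.uniform(1, 4)).pdf
            assert kl_divergence(f, g, grid) >= -1e-6


class TestEvaluateModels:
    def test_reports_share_evaluated_mask(self):
        rng = np.random.default_rng(9)
        shape = (3, 3, 3)
        base = VoxelGrid(np.zeros(shape), (1, 1, 1))
        dens = [base.copy_with(rng.lognormal(5, 0.3, shape)) for _ in range(12)]
        valid = [base.copy_with(np.ones(shape, dtype=np.uint8))
                 for _ in range(12)]
        nm = fit_density_model(dens, valid, kind="normal")
        lm = fit_density_model(dens, valid, kind="lognormal")
        rep_n, rep_l = evaluate_models(dens, valid, nm, lm, min_samples=5)
        np.testing.assert_array_equal(rep_n.evaluated_mask.values,
                                      rep_l.evaluated_mask.values)
        assert rep_n.evaluated_mask.values.sum() == np.prod(shape)
        # all KL values non-negative where evaluated
        for rep in (rep_n, rep_l):
            vals = rep.dkl_map.values[rep.evaluated_mask.values.astype(bool)]
            assert np.all(vals >= -1e-6)
            # summary recomputable from the map and mask
            assert rep.mean == pytest.approx(float(vals.mean()))
            assert rep.sd == pytest.approx(float(vals.std()))

    def test_no_eligible_voxels_raises(self):
        base = VoxelGrid(np.zeros((2, 2, 2)), (1, 1, 1))
        dens = [base.copy_with(np.full((2, 2, 2), 9.0)) for _ in range(2)]
        valid = [base.copy_with(np.ones((2, 2, 2), dtype=np.uint8))
                 for _ in range(2)]
        nm = fit_density_model(dens, valid, kind="normal", min_samples=2)
        lm = fit_density_model(dens, valid, kind="lognormal", min_samples=2)
        with pytest.raises(ValueError):
            evaluate_models(dens, valid, nm, lm, min_samples=5)
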
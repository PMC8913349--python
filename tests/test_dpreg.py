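"""Distance maps, similarity registration, demons and transform chains."""

import warnings

import numpy as np
import pytest
from scipy import ndimage

from voxatlas.config import DemonsConfig
from voxatlas.grid import GridAlignmentError, VoxelGrid
from voxatlas.dpreg import (
    AnisotropicSimilarity,
    TransformChain,
    compose_and_apply,
    dice,
    distance_preserving_register,
    normalised_distance_map,
    similarity_register,
    _warp_image,
)
from voxatlas.phantom import _rotation_matrix
from tests.conftest import make_ball

FAST = DemonsConfig(pyramid_shrinks=(4, 2), iterations=(40, 20))


def nd_preservation_fraction(mov, fix, disp, region=None):
    """Fraction of in-region points whose moving-ND value, sampled at the
    mapped location, matches the fixed ND within 0.1."""
    nd_m = normalised_distance_map(mov).values.values
    nd_f = normalised_distance_map(fix).values.values
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in mov.shape],
                               indexing="ij"), axis=-1).astype(float)
    pts = idx + disp.field / mov.spacing
    nd_at = ndimage.map_coordinates(nd_m, [pts[..., a] for a in range(3)],
                                    order=1)
    if region is None:
        region = fix.values.astype(bool)
    return float((np.abs(nd_at - nd_f)[region] <= 0.1).mean())


class TestNormalisedDistanceMap:
    def test_sphere_centre_and_boundary(self):
        g = make_ball(41, 15.0)
        nd = normalised_distance_map(g).values.values
        assert nd[20, 20, 20] == pytest.approx(1.0, abs=1e-6)
        # boundary shell value near 0 (within a voxel of the surface)
        pts = g.physical_coordinates()
        rr = np.sqrt((pts**2).sum(axis=-1))
        shell = np.abs(rr - 15.0) < 0.5
        assert np.abs(nd[shell]).max() <= 2.0 / 15.0 + 1e-6

    def test_sphere_half_depth_shell(self):
        g = make_ball(41, 15.0)
        nd = normalised_distance_map(g).values.values
        pts = g.physical_coordinates()
        rr = np.sqrt((pts**2).sum(axis=-1))
        shell = np.abs(rr - 7.5) < 0.5
        assert abs(nd[shell].mean() - 0.5) < 0.05

    def test_far_exterior_clipped(self):
        g = make_ball(61, 10.0)
        nd = normalised_distance_map(g).values.values
        assert nd[0, 0, 0] == -1.0
        assert nd.min() == -1.0

    def test_degenerate_masks_rejected(self):
        empty = VoxelGrid(np.zeros((6, 6, 6), dtype=np.uint8), (1, 1, 1))
        full = VoxelGrid(np.ones((6, 6, 6), dtype=np.uint8), (1, 1, 1))
        with pytest.raises(ValueError):
            normalised_distance_map(empty)
        with pytest.raises(ValueError):
            normalised_distance_map(full)


class TestSimilarityRegister:
    def test_identity_when_identical(self):
        g = make_ball(41, None, radii=(14, 10, 12))
        sim = similarity_register(g, g)
        np.testing.assert_allclose(sim.scales, 1.0, atol=1e-6)
        np.testing.assert_allclose(sim.rotation, np.eye(3), atol=1e-6)
        np.testing.assert_allclose(sim.translation, 0.0, atol=1e-6)

    def test_known_scale_recovery(self):
        mov = make_ball(49, None, radii=(14, 10, 12))
        fix = make_ball(49, None, radii=(14 * 1.2, 10 * 1.0, 12 * 0.8))
        sim = similarity_register(mov, fix)
        np.testing.assert_allclose(sim.scales, [1.2, 1.0, 0.8], rtol=0.02)

    def test_known_translation_recovery(self):
        mov = make_ball(49, None, radii=(14, 10, 12))
        fix = make_ball(49, None, radii=(14, 10, 12), centre=(5, 0, 0))
        sim = similarity_register(mov, fix)
        assert np.abs(sim.translation - [5, 0, 0]).max() < 0.5

    def test_random_similarity_recovery_20_cases(self):
        """Scales within 2%, rotations within 2 deg, translations within
        0.5 mm across 20 seeded random ellipsoid pairs."""
        rng = np.random.default_rng(101)
        # axis lengths stay distinct under the scale jitter, so the
        # principal frames (hence the rotation) are well conditioned
        radii = np.array([18.0, 10.0, 14.0])
        for _ in range(20):
            s = rng.uniform(0.9, 1.1, 3)
            ang = np.deg2rad(rng.uniform(-12, 12, 3))
            rot = _rotation_matrix(ang)
            t = rng.uniform(-3, 3, 3)
            mov = make_ball(55, None, radii=radii)
            # fixed shape: rotate the scaled ellipsoid by rot, shift by t
            fix = make_ball(55, None, radii=radii * s, rot=rot, centre=t)
            sim = similarity_register(mov, fix)
            assert np.abs(sim.scales - s).max() / s.min() < 0.02
            # rotation error as an angle; the mask built with pts @ rot is
            # the ellipsoid rotated by rot, so the true rotation is rot
            r_err = sim.rotation @ rot.T
            angle = np.degrees(np.arccos(
                np.clip((np.trace(r_err) - 1) / 2, -1, 1)))
            assert angle < 2.0
            assert np.abs(sim.translation - t).max() < 0.5

    def test_dice_never_degraded(self):
        mov = make_ball(49, None, radii=(14, 10, 12), centre=(4, -3, 2))
        fix = make_ball(49, None, radii=(15, 11, 12))
        sim = similarity_register(mov, fix)
        chain = TransformChain([sim])
        warped = compose_and_apply(chain, mov, fix, mode="nearest")
        assert dice(warped, fix) >= dice(mov, fix)


class TestDemons:
    def test_identity_case_no_motion(self):
        g = make_ball(33, 10.0)
        disp = distance_preserving_register(g, g, config=FAST)
        assert disp.magnitude().max() <= 0.1 * g.spacing.min()

    def test_sphere_growth_shell_correspondence(self):
        mov, fix = make_ball(41, 8.0), make_ball(41, 12.0)
        disp = distance_preserving_register(mov, fix, config=FAST)
        # the ND=0.5 shell of the moving sphere maps near fixed ND 0.5
        nd_f = normalised_distance_map(fix).values.values
        idx = np.stack(np.meshgrid(*[np.arange(41)] * 3, indexing="ij"),
                       axis=-1).astype(float)
        pts = idx + disp.field / mov.spacing
        nd_m = normalised_distance_map(mov).values.values
        nd_at = ndimage.map_coordinates(nd_m, [pts[..., a] for a in range(3)],
                                        order=1)
        shell = np.abs(nd_f - 0.5) < 0.05
        frac = (np.abs(nd_at[shell] - 0.5) <= 0.1).mean()
        assert frac >= 0.95

    def test_jacobian_positive(self):
        mov, fix = make_ball(41, 8.0), make_ball(41, 12.0)
        disp = distance_preserving_register(mov, fix, config=FAST)
        jac = disp.jacobian_determinant()
        gland = fix.values.astype(bool)
        assert (jac[gland] > 0).mean() >= 0.999

    def test_pinned_boundary_stays_fixed(self):
        n = 49
        gland = make_ball(n, 20.0)
        pts = gland.physical_coordinates()
        rr = np.sqrt((pts**2).sum(axis=-1))
        mk = lambda v: gland.copy_with(v.astype(np.uint8))
        mov = mk((rr <= 20) & (rr >= 20 * 0.70) & (pts[..., 1] > 0))
        fix = mk((rr <= 20) & (rr >= 20 * 0.55) & (pts[..., 1] > 0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            disp = distance_preserving_register(
                mov, fix, pin_boundary_of=gland,
                config=DemonsConfig(pyramid_shrinks=(4, 2, 1),
                                    iterations=(40, 25, 15)))
        warped = _warp_image(mov.values.astype(np.float32),
                             disp.field / gland.spacing) > 0.5
        assert dice(warped, fix.values) >= 0.95
        inside = ndimage.distance_transform_edt(gland.values)
        outside = ndimage.distance_transform_edt(1 - gland.values)
        border = np.where(gland.values.astype(bool), inside, outside) <= 1.0
        assert disp.magnitude()[border].max() <= 0.1 * gland.spacing.min()

    def test_grid_mismatch_rejected(self):
        a = make_ball(21, 6.0, spacing=1.0)
        b = make_ball(21, 6.0, spacing=2.0)
        with pytest.raises(GridAlignmentError):
            distance_preserving_register(a, b, config=FAST)


class TestComposeAndApply:
    def test_identity_chain_resamples(self):
        g = make_ball(25, 8.0)
        chain = TransformChain([AnisotropicSimilarity.identity()])
        out = compose_and_apply(chain, g, g, mode="nearest")
        np.testing.assert_array_equal(out.values, g.values)

    def test_linear_mode_keeps_probabilities_bounded(self):
        rng = np.random.default_rng(12)
        g = make_ball(25, 8.0)
        prob = g.copy_with(rng.uniform(0, 1, g.shape))
        sim = AnisotropicSimilarity(
            centre=np.zeros(3), scales=np.array([1.1, 0.9, 1.0]),
            rot_moving=np.eye(3), rot_fixed=_rotation_matrix(
                np.deg2rad([0, 0, 10])),
            translation=np.array([1.0, -2.0, 0.5]))
        out = compose_and_apply(TransformChain([sim]), prob, g, mode="linear")
        assert out.values.min() >= -1e-6
        assert out.values.max() <= 1.0 + 1e-6

    def test_masking_contract_density_vs_validity(self, small_atlas):
        """Warped density is zero (missing) wherever warped validity is 0
        outside the patient's sampled support."""
        spec, cohort, atlas = small_atlas
        from voxatlas.pipeline import warp_cohort
        from voxatlas.slicefill import fill_patient
        filled = [fill_patient(ds) for ds in cohort[:2]]
        chains = atlas.reference.chains[:2]
        validity, lesions, densities = warp_cohort(
            filled, chains, atlas.reference)
        for v, d in zip(validity, densities):
            far_invalid = ~ndimage.binary_dilation(
                v.values.astype(bool), iterations=2)
            assert np.all(d.values[far_invalid] == 0)

    def test_chain_roundtrip_through_similarity(self):
        """Mapping reference points through a one-stage chain inverts the
        forward similarity transform."""
        sim = AnisotropicSimilarity(
            centre=np.array([1.0, 2.0, 3.0]),
            scales=np.array([1.2, 0.8, 1.0]),
            rot_moving=np.eye(3),
            rot_fixed=_rotation_matrix(np.deg2rad([5, -5, 15])),
            translation=np.array([2.0, 0.0, -1.0]))
        rng = np.random.default_rng(13)
        pts = rng.uniform(-10, 10, (50, 3))
        chain = TransformChain([sim])
        back = chain.map_reference_points(sim.apply(pts))
        np.testing.assert_allclose(back, pts, atol=1e-9)
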
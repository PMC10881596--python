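"""Level-set primitives and the full prior-constrained evolution."""

from dataclasses import replace

import numpy as np
import pytest

from edemaseg import (BinaryMask, ContourVanished, DensityImage,
                      GrayscaleMask, LevelSetParams, LevelSetState,
                      apply_mask, build_histogram, compute_energy,
                      compute_prior_term, curvature, evolve_step, init_phi,
                      reinitialize, run_segmentation, smoothed_delta,
                      smoothed_heaviside)
from edemaseg.levelset import region_means, sharp_heaviside, _signed_distance
from edemaseg.phantoms import PhantomSpec, generate_phantom, generate_training_pairs

from _oracles import curvature_brute, evolve_step_brute, region_means_brute
from conftest import dsc


def random_state_on(support, rng, shape=(8, 8)):
    """A valid state on random data: both phi signs present in the support."""
    phi = rng.normal(0, 3, shape)
    supp = support.as_bool()
    s = phi[supp]
    if (s >= 0).all():
        phi[np.argwhere(supp)[0][0], np.argwhere(supp)[0][1]] = -1.0
    if (phi[supp] < 0).all():
        phi[np.argwhere(supp)[-1][0], np.argwhere(supp)[-1][1]] = 1.0
    return phi


class TestHeavisideDelta:
    def test_heaviside_limits_and_symmetry(self):
        assert smoothed_heaviside(0.0, 1.5) == 0.5
        assert smoothed_heaviside(150.0, 1.5) == pytest.approx(1.0, abs=1e-2)
        assert smoothed_heaviside(-150.0, 1.5) == pytest.approx(0.0, abs=1e-2)

    def test_sharp_mode_ties_count_as_inside(self):
        assert sharp_heaviside(0.1) == 1.0
        assert sharp_heaviside(-0.1) == 0.0
        assert sharp_heaviside(0.0) == 1.0

    def test_delta_closed_form_and_symmetry(self):
        eps = 1.5
        assert smoothed_delta(0.0, eps) == pytest.approx(1 / (np.pi * eps))
        z = np.linspace(0.1, 20, 50)
        np.testing.assert_allclose(smoothed_delta(z, eps),
                                   smoothed_delta(-z, eps))

    def test_delta_integrates_to_one(self):
        eps = 1.5
        z = np.linspace(-150 * eps, 150 * eps, 200_001)
        integral = np.trapezoid(smoothed_delta(z, eps), z)
        assert integral == pytest.approx(1.0, abs=0.01)

    def test_delta_is_derivative_of_heaviside(self):
        eps, h = 1.5, 1e-5
        z = np.linspace(-5, 5, 41)
        fd = (smoothed_heaviside(z + h, eps) - smoothed_heaviside(z - h, eps)) / (2 * h)
        np.testing.assert_allclose(fd, smoothed_delta(z, eps), rtol=1e-6)


class TestCurvature:
    def test_circle_curvature_magnitude(self):
        n, R = 101, 25.0
        rr, cc = np.mgrid[0:n, 0:n]
        r = np.hypot(rr - n // 2, cc - n // 2)
        phi = R - r  # positive inside the disc
        kappa = curvature(phi)
        band = np.abs(r - R) < 1.0
        np.testing.assert_allclose(kappa[band], -1.0 / R, rtol=0.15)

    def test_planar_phi_has_zero_curvature(self):
        # flat interface; tolerance reflects the 1e-8 gradient regularizer
        phi = np.tile(np.arange(20, dtype=float), (20, 1))
        assert np.abs(curvature(phi)[1:-1, 1:-1]).max() < 1e-6

    def test_sign_flip_negates_curvature(self):
        rng = np.random.default_rng(0)
        phi = rng.normal(0, 2, (12, 12))
        np.testing.assert_allclose(curvature(-phi), -curvature(phi), atol=1e-9)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        phi = rng.normal(0, 2, (9, 9))
        np.testing.assert_allclose(curvature(phi), curvature_brute(phi),
                                   atol=1e-12)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            curvature(np.zeros((2, 5)))


class TestInitPhi:
    def test_distance_to_centered_disc(self):
        n, r = 64, 10.0
        rr, cc = np.mgrid[0:n, 0:n]
        disc = np.hypot(rr - n / 2, cc - n / 2) <= r
        img_vals = np.where(disc, 0.0, -100.0)
        image = DensityImage(values=img_vals)
        mask = BinaryMask(values=np.ones((n, n), dtype=np.uint8))
        state = init_phi(image, mask, mode="threshold")
        center = state.phi[n // 2, n // 2]
        assert center == pytest.approx(r, abs=1.5)

    def test_empty_mask_rejected(self):
        image = DensityImage(values=np.zeros((8, 8)))
        mask = BinaryMask(values=np.zeros((8, 8), dtype=np.uint8))
        with pytest.raises(ValueError):
            init_phi(image, mask, mode="threshold")

    def test_checkerboard_creates_both_regions(self):
        image = DensityImage(values=np.full((64, 64), -100.0))
        mask = BinaryMask(values=np.ones((64, 64), dtype=np.uint8))
        state = init_phi(image, mask, mode="checkerboard")
        assert (state.phi >= 0).any() and (state.phi < 0).any()

    def test_empty_threshold_seed_falls_back_to_checkerboard(self):
        image = DensityImage(values=np.full((64, 64), -300.0))  # below window
        mask = BinaryMask(values=np.ones((64, 64), dtype=np.uint8))
        state = init_phi(image, mask, mode="threshold")
        assert (state.phi >= 0).any()


class TestRegionMeans:
    def test_sharp_two_phase_exact(self):
        values = np.where(np.arange(16).reshape(4, 4) < 8, 10.0, -100.0)
        support = BinaryMask(values=np.ones((4, 4), dtype=np.uint8))
        gm = GrayscaleMask(values=values, support=support)
        phi = np.where(values == 10.0, 1.0, -1.0)
        assert region_means(gm, phi) == (10.0, -100.0)

    def test_uniform_image_gives_equal_means(self):
        support = BinaryMask(values=np.ones((4, 4), dtype=np.uint8))
        gm = GrayscaleMask(values=np.full((4, 4), 7.0), support=support)
        phi = np.where(np.arange(16).reshape(4, 4) < 5, 1.0, -1.0)
        c1, c2 = region_means(gm, phi)
        assert c1 == c2 == 7.0

    @pytest.mark.parametrize("epsilon", [None, 1.5])
    def test_matches_weighted_mean_oracle(self, epsilon):
        rng = np.random.default_rng(2)
        supp_arr = np.ones((3, 3), dtype=np.uint8)
        supp_arr[0, 0] = 0
        support = BinaryMask(values=supp_arr)
        values = rng.normal(-50, 40, (3, 3))
        values[0, 0] = 0.0
        gm = GrayscaleMask(values=values, support=support)
        phi = rng.normal(0, 2, (3, 3))
        got = region_means(gm, phi, epsilon=epsilon)
        want = region_means_brute(values, phi, support.as_bool(), epsilon)
        assert got == pytest.approx(want, abs=1e-12)


class TestPriorTerm:
    def make_gm(self, values):
        support = BinaryMask(values=np.ones(values.shape, dtype=np.uint8))
        return GrayscaleMask(values=values, support=support)

    def test_background_matching_prior_scores_near_zero(self, prior):
        rng = np.random.default_rng(3)
        values = rng.normal(prior.adipose_mean, prior.adipose_std, (110, 110))
        gm = self.make_gm(values)
        phi = np.full((110, 110), -1.0)
        phi[0, 0] = 1.0
        params = LevelSetParams()
        f = compute_prior_term(gm, LevelSetState(phi=phi),
                               prior.fitted_histogram, params)
        assert f < 0.05

    def test_mixture_background_scores_higher_than_pure(self, prior):
        rng = np.random.default_rng(4)
        pure = rng.normal(-100, 15, (100, 100))
        mixed = pure.copy()
        mixed[:50] = rng.normal(0, 15, (50, 100))
        params = LevelSetParams()
        phi = np.full((100, 100), -1.0)
        phi[0, 0] = 1.0
        f_pure = compute_prior_term(self.make_gm(pure),
                                    LevelSetState(phi=phi),
                                    prior.fitted_histogram, params)
        f_mixed = compute_prior_term(self.make_gm(mixed),
                                     LevelSetState(phi=phi),
                                     prior.fitted_histogram, params)
        assert f_mixed > f_pure

    def test_empty_background_rejected(self, prior):
        gm = self.make_gm(np.zeros((4, 4)))
        state = LevelSetState(phi=np.ones((4, 4)))
        with pytest.raises(ValueError, match="background"):
            compute_prior_term(gm, state, prior.fitted_histogram,
                               LevelSetParams())

    def test_zero_variance_background_returns_zero_with_warning(self, prior):
        # one value per bin -> a perfectly flat background histogram
        edges = prior.fitted_histogram.bin_edges
        centers = 0.5 * (edges[:-1] + edges[1:])
        gm = self.make_gm(centers.reshape(8, 8))
        phi = np.full((8, 8), -1.0)  # everything is background
        with pytest.warns(UserWarning, match="zero-variance"):
            f = compute_prior_term(gm, LevelSetState(phi=phi),
                                   prior.fitted_histogram, LevelSetParams())
        assert f == 0.0


class TestEvolveStep:
    def test_zero_force_fixed_point_preserves_signs(self, prior):
        # two constant phases already matching the sign regions, alpha=beta=0
        values = np.where(np.arange(64).reshape(8, 8) < 32, 0.0, -100.0)
        support = BinaryMask(values=np.ones((8, 8), dtype=np.uint8))
        gm = GrayscaleMask(values=values, support=support)
        phi = np.where(values == 0.0, 1.0, -1.0)
        params = LevelSetParams(alpha=0.0, beta=0.0)
        state = LevelSetState(phi=phi, C1=0.0, C2=-100.0)
        new = evolve_step(state, gm, prior.fitted_histogram, params)
        np.testing.assert_array_equal(np.sign(new.phi), np.sign(phi))

    def test_matches_direct_pde_evaluation(self, prior):
        rng = np.random.default_rng(7)
        supp_arr = np.ones((8, 8), dtype=np.uint8)
        support = BinaryMask(values=supp_arr)
        values = rng.normal(-60, 40, (8, 8))
        gm = GrayscaleMask(values=values, support=support)
        phi = random_state_on(support, rng)
        params = LevelSetParams()
        state = LevelSetState(phi=phi, C1=-10.0, C2=-90.0)
        got = evolve_step(state, gm, prior.fitted_histogram, params)
        want, f_want = evolve_step_brute(
            phi, values, support.as_bool(), -10.0, -90.0,
            prior.fitted_histogram.counts, params.n_bins,
            *params.hist_range, params.alpha, params.beta, params.dt,
            params.epsilon)
        np.testing.assert_allclose(got.phi, want, atol=1e-12)
        assert got.F_value == pytest.approx(f_want, abs=1e-12)
        assert got.iteration == state.iteration + 1

    def test_requires_updated_means(self, prior):
        support = BinaryMask(values=np.ones((8, 8), dtype=np.uint8))
        gm = GrayscaleMask(values=np.zeros((8, 8)), support=support)
        phi = np.where(np.arange(64).reshape(8, 8) < 32, 1.0, -1.0)
        with pytest.raises(ValueError, match="C1/C2"):
            evolve_step(LevelSetState(phi=phi), gm, prior.fitted_histogram,
                        LevelSetParams())


class TestEnergy:
    def test_uniform_image_leaves_only_length_term(self, prior):
        support = BinaryMask(values=np.ones((16, 16), dtype=np.uint8))
        gm = GrayscaleMask(values=np.full((16, 16), -80.0), support=support)
        phi = _signed_distance(np.arange(256).reshape(16, 16) < 128)
        params = LevelSetParams(alpha=0.0, beta=2.0)
        state = LevelSetState(phi=phi, C1=-80.0, C2=-80.0)
        e = compute_energy(state, gm, prior.fitted_histogram, params, F=0.0)
        e0 = compute_energy(state, gm, prior.fitted_histogram,
                            replace(params, beta=0.0), F=0.0)
        assert e0 == 0.0 and e > 0.0

    def test_perfect_two_phase_zero_energy(self, prior):
        values = np.where(np.arange(64).reshape(8, 8) < 32, 0.0, -100.0)
        support = BinaryMask(values=np.ones((8, 8), dtype=np.uint8))
        gm = GrayscaleMask(values=values, support=support)
        phi = np.where(values == 0.0, 1.0, -1.0)
        params = LevelSetParams(alpha=0.0, beta=0.0)
        state = LevelSetState(phi=phi, C1=0.0, C2=-100.0)
        assert compute_energy(state, gm, prior.fitted_histogram, params,
                              F=0.0) == 0.0


class TestReinitialize:
    def test_sign_pattern_preserved_on_arbitrary_phi(self):
        rng = np.random.default_rng(8)
        phi = rng.normal(0, 5, (64, 64))
        out = reinitialize(phi)
        np.testing.assert_array_equal(out >= 0, phi >= 0)

    def test_unit_gradient_after_reinit_of_smooth_contour(self):
        # distorted-circle contour: the rebuilt phi is a unit-slope distance
        # field away from medial-axis ridges
        n = 101
        rr, cc = np.mgrid[0:n, 0:n]
        r = np.hypot(rr - n // 2, cc - n // 2)
        theta = np.arctan2(rr - n // 2, cc - n // 2)
        phi = 28.0 + 5.0 * np.sin(3 * theta) - r
        out = reinitialize(3.0 * phi)  # badly scaled on purpose
        gy, gx = np.gradient(out)
        gnorm = np.hypot(gy, gx)
        assert np.mean((gnorm > 0.5) & (gnorm < 1.5)) >= 0.95

    def test_single_sign_rejected(self):
        with pytest.raises(ContourVanished):
            reinitialize(np.ones((8, 8)))


class TestRunSegmentation:
    def test_default_phantom_dsc_above_090(self, default_spec, prior):
        s = generate_phantom(default_spec, 42)
        mask, trace = run_segmentation(s.image, s.adipose_mask, prior)
        assert dsc(mask.as_bool(), s.edema_mask.as_bool()) > 0.90
        assert trace["converged"]

    def test_output_contained_in_adipose_mask(self, default_spec, prior):
        s = generate_phantom(default_spec, 43)
        mask, _ = run_segmentation(s.image, s.adipose_mask, prior)
        assert not (mask.as_bool() & ~s.adipose_mask.as_bool()).any()

    def test_edema_free_phantom_specificity(self, default_spec, prior):
        spec = replace(default_spec, edema_blob_count=0)
        s = generate_phantom(spec, 11)
        mask, _ = run_segmentation(s.image, s.adipose_mask, prior)
        assert mask.count < 0.01 * s.adipose_mask.count

    def test_exact_recovery_without_forces_or_noise(self, prior):
        spec = PhantomSpec(adipose_std=0.0, edema_std=0.0, noise_std=0.0)
        s = generate_phantom(spec, 5)
        params = LevelSetParams(alpha=0.0, beta=0.0)
        mask, _ = run_segmentation(s.image, s.adipose_mask, prior, params)
        np.testing.assert_array_equal(mask.values, s.edema_mask.values)

    def test_bit_identical_determinism(self, default_spec, prior):
        s = generate_phantom(default_spec, 44)
        m1, _ = run_segmentation(s.image, s.adipose_mask, prior)
        m2, _ = run_segmentation(s.image, s.adipose_mask, prior)
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_trace_records_iterations(self, default_spec, prior):
        s = generate_phantom(default_spec, 45)
        _, trace = run_segmentation(s.image, s.adipose_mask, prior)
        assert len(trace["rows"]) == trace["iterations"]
        row = trace["rows"][0]
        assert set(row) == {"iteration", "C1", "C2", "F", "energy",
                            "changed_frac"}
        assert len(trace["checkpoint_energies"]) >= 2
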
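"""Segmentation, ring extraction, plane fitting, and correction."""

import numpy as np
import pytest
from scipy import ndimage

from densebrain import (
    PlaneFit,
    apply_correction,
    extract_outer_ring,
    fit_plane_ols,
    fit_plane_wrapped,
    segment_hemispheres,
    wrap_to_pi,
)
from densebrain.motion import plane_image


def _plane_on(ring, a, b, c):
    ny, nx = ring.parent.shape
    cy, cx = ring.centroid
    Y, X = np.mgrid[0:ny, 0:nx]
    return a * (X - cx) + b * (Y - cy) + c


class TestSegmentHemispheres:
    def test_phantom_round_trip(self, phantom_default):
        """Segmenting the phantom's own magnitude recovers its masks."""
        _, magnitude, masks, _ = phantom_default
        left, right = segment_hemispheres(magnitude)
        np.testing.assert_array_equal(left, masks[0])
        np.testing.assert_array_equal(right, masks[1])

    def test_masks_disjoint(self, phantom_default):
        _, magnitude, _, _ = phantom_default
        left, right = segment_hemispheres(magnitude)
        assert not (left & right).any()

    def test_all_zero_image_errors(self):
        with pytest.raises(ValueError, match="empty foreground"):
            segment_hemispheres(np.zeros((20, 20)))

    def test_explicit_threshold(self, phantom_default):
        _, magnitude, masks, _ = phantom_default
        left, right = segment_hemispheres(magnitude, threshold_method=0.5)
        np.testing.assert_array_equal(left | right, masks[0] | masks[1])


class TestExtractOuterRing:
    def test_full_square_ring_is_border(self):
        mask = np.zeros((5, 5), bool)
        mask[1:4, 1:4] = True  # 3x3 block
        ring = extract_outer_ring(mask)
        assert ring.n_voxels == 8
        assert not ring.ring[2, 2]

    def test_disk_matches_brute_force_morphology(self):
        """Oracle: erosion computed by explicit 4-neighbour shifts."""
        Y, X = np.mgrid[0:25, 0:25]
        mask = (X - 12) ** 2 + (Y - 12) ** 2 <= 10**2
        ring = extract_outer_ring(mask)
        shifted = [
            np.roll(mask, 1, axis=0),
            np.roll(mask, -1, axis=0),
            np.roll(mask, 1, axis=1),
            np.roll(mask, -1, axis=1),
        ]
        eroded = mask & shifted[0] & shifted[1] & shifted[2] & shifted[3]
        oracle_ring = mask & ~eroded
        np.testing.assert_array_equal(ring.ring, oracle_ring)

    def test_every_ring_voxel_touches_outside(self, phantom_default):
        _, _, masks, _ = phantom_default
        mask = masks[0] | masks[1]
        ring = extract_outer_ring(mask)
        outside = ~mask
        padded = np.pad(outside, 1, constant_values=True)
        for r, c in zip(*np.nonzero(ring.ring)):
            neigh = padded[r : r + 3, c : c + 3]
            assert neigh.any()

    def test_single_voxel_warns(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        with pytest.warns(UserWarning, match="degenerate"):
            ring = extract_outer_ring(mask)
        np.testing.assert_array_equal(ring.ring, mask)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            extract_outer_ring(np.zeros((4, 4), bool))


class TestFitPlaneOLS:
    def test_constant_phase(self, small_ring):
        img = np.full(small_ring.parent.shape, 0.37)
        fit = fit_plane_ols(img, small_ring)
        assert fit.slope_x == pytest.approx(0.0, abs=1e-12)
        assert fit.slope_y == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.37, abs=1e-12)

    def test_exact_plane_recovery(self, small_ring):
        img = _plane_on(small_ring, 0.10, 0.20, 0.30)
        fit = fit_plane_ols(img, small_ring)
        np.testing.assert_allclose(
            fit.coeffs, [0.10, 0.20, 0.30], atol=1e-10
        )

    def test_consistency_with_ring_size(self):
        """Coefficient error under i.i.d. noise shrinks for a larger ring."""
        rng = np.random.default_rng(5)
        errs = []
        for radius in (6, 24):
            n = 2 * radius + 6
            Y, X = np.mgrid[0:n, 0:n]
            c = (n - 1) / 2
            mask = (X - c) ** 2 + (Y - c) ** 2 <= radius**2
            ring = extract_outer_ring(mask)
            truth = np.array([0.05, -0.03, 0.2])
            img = _plane_on(ring, *truth)
            trial_errs = []
            for _ in range(60):
                noisy = img + rng.normal(0, 0.3, img.shape)
                fit = fit_plane_ols(noisy, ring)
                trial_errs.append(np.abs(fit.coeffs - truth).max())
            errs.append(np.mean(trial_errs))
        assert errs[1] < errs[0]

    def test_underdetermined_rejected(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 1:4] = True  # collinear
        with pytest.warns(UserWarning):
            ring = extract_outer_ring(mask)
        with pytest.raises(ValueError, match="underdetermined"):
            fit_plane_ols(np.zeros((5, 5)), ring)


class TestFitPlaneWrapped:
    def test_agrees_with_ols_when_no_wraps(self, small_ring):
        # exact wrap-free plane: both fitters recover it, so they agree
        img = _plane_on(small_ring, 0.03, -0.02, 0.4)
        ols = fit_plane_ols(img, small_ring)
        wrapped = fit_plane_wrapped(img, small_ring)
        np.testing.assert_allclose(wrapped.coeffs, ols.coeffs, atol=1e-6)

    def test_close_to_ols_under_small_noise(self, small_ring):
        # with noise the cosine objective deviates from least squares only
        # at third order in the residual: coefficients stay close
        rng = np.random.default_rng(6)
        img = _plane_on(small_ring, 0.03, -0.02, 0.4)
        img = img + rng.normal(0, 0.05, img.shape)
        assert np.abs(img[small_ring.ring]).max() < np.pi  # wrap-free
        ols = fit_plane_ols(img, small_ring)
        wrapped = fit_plane_wrapped(img, small_ring)
        np.testing.assert_allclose(wrapped.coeffs, ols.coeffs, atol=1e-4)

    def test_recovers_plane_that_wraps_where_ols_fails(self, small_ring):
        """Plane crossing two wrap boundaries across the ring: the
        wrap-aware fit recovers the truth; OLS on the wrapped values
        cannot."""
        truth = np.array([0.38, 0.30, 0.5])
        img = wrap_to_pi(_plane_on(small_ring, *truth))
        # phase excursion across the circular ring spans > 2 pi, so the
        # wrapped image shows two fringe discontinuities
        radius = small_ring.half_extents()[0] - 0.5
        excursion = 2 * radius * np.hypot(truth[0], truth[1])
        assert excursion > 2 * np.pi
        fit = fit_plane_wrapped(img, small_ring)
        np.testing.assert_allclose(fit.coeffs, truth, atol=1e-4)
        ols = fit_plane_ols(img, small_ring)
        assert np.abs(ols.coeffs - truth).max() > 0.05

    def test_objective_beats_random_draws(self, small_ring):
        """J at the fit is a lower bound over 10^4 random plane draws."""
        rng = np.random.default_rng(7)
        truth = np.array([0.2, -0.15, 1.0])
        img = wrap_to_pi(
            _plane_on(small_ring, *truth)
            + rng.normal(0, 0.2, small_ring.parent.shape)
        )
        fit = fit_plane_wrapped(img, small_ring)
        x, y = small_ring.coords()
        phi = img[small_ring.ring]
        rx, ry = small_ring.half_extents()
        draws_a = rng.uniform(-np.pi / rx, np.pi / rx, 10_000)
        draws_b = rng.uniform(-np.pi / ry, np.pi / ry, 10_000)
        draws_c = rng.uniform(-np.pi, np.pi, 10_000)
        r = (
            phi[None, :]
            - draws_a[:, None] * x
            - draws_b[:, None] * y
            - draws_c[:, None]
        )
        J_draws = (1 - np.cos(r)).sum(axis=1)
        assert fit.objective <= J_draws.min() + 1e-9

    def test_matches_brute_force_minimizer(
        self, small_ring, brute_wrapped_oracle
    ):
        rng = np.random.default_rng(8)
        rx, ry = small_ring.half_extents()
        for _ in range(5):
            truth = [
                rng.uniform(-0.8 * np.pi / rx, 0.8 * np.pi / rx),
                rng.uniform(-0.8 * np.pi / ry, 0.8 * np.pi / ry),
                rng.uniform(-np.pi, np.pi),
            ]
            img = wrap_to_pi(
                _plane_on(small_ring, *truth)
                + rng.normal(0, 0.3, small_ring.parent.shape)
            )
            fit = fit_plane_wrapped(img, small_ring)
            _, j_brute = brute_wrapped_oracle(img, small_ring)
            assert abs(fit.objective - j_brute) < 1e-6

    def test_objective_never_worse_than_grid(self, small_ring):
        rng = np.random.default_rng(9)
        img = wrap_to_pi(rng.uniform(-np.pi, np.pi, small_ring.parent.shape))
        refined = fit_plane_wrapped(img, small_ring)
        grid_only = fit_plane_wrapped(img, small_ring, refine=False)
        assert refined.objective <= grid_only.objective + 1e-12

    def test_squared_objective_variant(self, small_ring):
        img = _plane_on(small_ring, 0.05, -0.04, 0.3)
        fit = fit_plane_wrapped(img, small_ring, objective="squared")
        np.testing.assert_allclose(
            fit.coeffs, [0.05, -0.04, 0.3], atol=1e-6
        )

    def test_non_finite_phase_rejected(self, small_ring):
        img = np.zeros(small_ring.parent.shape)
        img[small_ring.ring] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_plane_wrapped(img, small_ring)


class TestApplyCorrection:
    def test_zero_fit_is_identity(self, small_ring):
        rng = np.random.default_rng(10)
        img = rng.uniform(-1, 1, small_ring.parent.shape)
        fit = PlaneFit(0.0, 0.0, 0.0, 0.0, "ols")
        np.testing.assert_array_equal(
            apply_correction(img, fit, small_ring, "real"), img
        )

    def test_complex_domain_removes_integer_wrap_field(self, small_ring):
        """phi = plane + 2 pi k(v): complex-domain subtraction returns
        exactly zero, whatever the integer field k."""
        rng = np.random.default_rng(11)
        fit = PlaneFit(0.11, -0.07, 0.9, 0.0, "wrapped")
        k = rng.integers(-3, 4, small_ring.parent.shape)
        img = plane_image(fit, small_ring) + 2 * np.pi * k
        out = apply_correction(img, fit, small_ring, "complex")
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_real_leaves_ledges_complex_does_not(self, small_ring):
        """Wrapped input: real-domain subtraction keeps 2-pi ledges, the
        complex-domain subtraction stays within (-pi, pi]."""
        fit = PlaneFit(0.50, 0.40, 0.0, 0.0, "wrapped")
        img = wrap_to_pi(plane_image(fit, small_ring))
        real_out = apply_correction(img, fit, small_ring, "real")
        cplx_out = apply_correction(img, fit, small_ring, "complex")
        inside = small_ring.parent
        assert np.abs(real_out[inside]).max() > np.pi  # residual ledges
        assert np.abs(cplx_out[inside]).max() < 1e-9

    def test_idempotence_under_planar_contamination(self, small_ring):
        """Adding any plane and re-correcting returns the original output."""
        rng = np.random.default_rng(12)
        img = rng.normal(0, 0.05, small_ring.parent.shape)
        base_fit = fit_plane_ols(img, small_ring)
        base_out = apply_correction(img, base_fit, small_ring, "real")
        plane = _plane_on(small_ring, 0.04, -0.06, 0.8)
        contaminated = img + plane
        fit2 = fit_plane_ols(contaminated, small_ring)
        out2 = apply_correction(contaminated, fit2, small_ring, "real")
        np.testing.assert_allclose(out2, base_out, atol=1e-6)

    def test_unknown_domain_rejected(self, small_ring):
        fit = PlaneFit(0.0, 0.0, 0.0, 0.0, "ols")
        with pytest.raises(ValueError, match="unknown correction domain"):
            apply_correction(np.zeros((16, 16)), fit, small_ring, "quat")


class TestRingCircularMeanAfterCorrection:
    def test_ring_phase_mean_small_after_complex_fit(self, scheme):
        """After complex-fit correction of simulated bulk motion (zero
        noise), the circular mean of ring phase per image is < 1e-3 rad."""
        from densebrain import (
            BulkMotionParams,
            PhantomConfig,
            generate_phantom,
            simulate_acquisition,
        )

        config = PhantomConfig()
        _, masks, truth = generate_phantom(config)
        bulk = BulkMotionParams.random(10, 0.3, 0.15, seed=13)
        series = simulate_acquisition(truth, bulk, scheme, config)
        ring = truth.ring
        phase = np.angle(series.data)
        for e, t in ((0, 1), (3, 5), (6, 9)):
            fit = fit_plane_wrapped(phase[e, t], ring)
            corrected = apply_correction(phase[e, t], fit, ring, "complex")
            z = np.exp(1j * corrected[ring.ring]).mean()
            assert abs(np.angle(z)) < 1e-3
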
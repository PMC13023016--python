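"""Phantom geometry, ground-truth invariants, and the acquisition simulator."""

import numpy as np
import pytest

from densebrain import (
    BulkMotionParams,
    EncodingScheme,
    PhantomConfig,
    generate_phantom,
    generate_ppg,
    make_smooth_background,
    rmssd,
    simulate_acquisition,
    wrap_to_pi,
)
from densebrain.encoding import encode_series


class TestGeneratePhantom:
    def test_ring_voxels_are_stationary(self, phantom_default):
        _, _, _, truth = phantom_default
        mag = np.linalg.norm(truth.u, axis=1)  # (n_frames, ny, nx)
        assert np.all(mag[:, truth.ring.ring] == 0.0)

    def test_net_zero_cycle(self, phantom_default):
        _, _, _, truth = phantom_default
        assert np.all(truth.u[0] == 0.0)
        assert np.all(truth.u[-1] == 0.0)

    def test_peak_p2p_equals_configured_peak(self, phantom_default):
        """Sampled pulse peaks at exactly 1, so the largest voxelwise
        peak-to-peak equals the norm of the configured per-axis peaks."""
        config, _, _, truth = phantom_default
        mag = np.linalg.norm(truth.u, axis=1)
        expected = np.linalg.norm(config.peak_displacement_mm)
        assert mag.max() == pytest.approx(expected, abs=1e-9)

    def test_interior_exceeds_periphery(self, phantom_default):
        _, _, masks, truth = phantom_default
        mag = np.linalg.norm(truth.u, axis=1).max(axis=0)
        combined = masks[0] | masks[1]
        peak_voxel = np.unravel_index(np.argmax(mag), mag.shape)
        # the deepest voxels move the most; they are interior (not on ring)
        assert not truth.ring.ring[peak_voxel]
        assert mag[combined].max() > 10 * mag[truth.ring.ring].max() + 1e-12

    def test_hemispheres_disjoint_with_midline_gap(self, phantom_default):
        _, _, masks, _ = phantom_default
        left, right = masks
        assert not (left & right).any()
        gap_col = left.shape[1] // 2
        assert not (left | right)[:, gap_col].any()

    def test_determinism(self):
        config = PhantomConfig(noise_sd=0.05, seed=11)
        out1 = generate_phantom(config)
        out2 = generate_phantom(config)
        np.testing.assert_array_equal(out1[2].u, out2[2].u)
        s1 = simulate_acquisition(out1[2], config=config)
        s2 = simulate_acquisition(out2[2], config=config)
        np.testing.assert_array_equal(s1.data, s2.data)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(grid_size=(8, 8))
        with pytest.raises(ValueError):
            PhantomConfig(peak_displacement_mm=(0.3, 0.1, 0.1))  # >= 1/(2 ke)
        # explicitly requested wrap testing lifts the amplitude limit
        PhantomConfig(peak_displacement_mm=(0.3, 0.1, 0.1), allow_wraps=True)


class TestSimulateAcquisition:
    def test_noiseless_phase_is_wrapped_encoding(self, phantom_default, scheme):
        config, _, _, truth = phantom_default
        series = simulate_acquisition(truth, None, scheme, config)
        expected = wrap_to_pi(encode_series(truth.u, scheme))
        combined = truth.combined_mask()
        got = np.angle(series.data)[:, :, combined]
        np.testing.assert_allclose(got, expected[:, :, combined], atol=1e-10)

    def test_quarter_sensitivity_translation_gives_half_pi(self, scheme):
        """Translation of 0.1238 mm along an encoding direction (a quarter
        of the 0.495 mm sensitivity) adds a constant pi/2 phase offset."""
        config = PhantomConfig()
        _, _, truth = generate_phantom(config)
        truth.u[:] = 0.0  # isolate the bulk-motion phase
        delta = 0.1238 * scheme.directions[0]
        trans = np.zeros((10, 3))
        trans[1] = delta
        bulk = BulkMotionParams(trans, np.zeros(10))
        series = simulate_acquisition(truth, bulk, scheme, config)
        combined = truth.combined_mask()
        phase = np.angle(series.data[0, 1])[combined]
        expected = 2 * np.pi * scheme.ke * 0.1238
        np.testing.assert_allclose(phase, expected, atol=1e-10)
        assert expected == pytest.approx(np.pi / 2, rel=3e-3)

    def test_rotation_plane_matches_ols_oracle(self, scheme):
        """The closed-form rotation plane must agree with a brute-force OLS
        plane fit to the simulated noiseless ring phase."""
        config = PhantomConfig()
        _, _, truth = generate_phantom(config)
        truth.u[:] = 0.0
        rot = np.zeros(10)
        rot[2] = 0.05  # small: no wraps anywhere on the ring
        bulk = BulkMotionParams(np.zeros((10, 3)), rot)
        series = simulate_acquisition(truth, bulk, scheme, config)
        x, y = truth.ring.coords()
        A = np.column_stack([x, y, np.ones_like(x)])
        for e in (0, 3, 5):
            phi = np.angle(series.data[e, 2])[truth.ring.ring]
            coef, *_ = np.linalg.lstsq(A, phi, rcond=None)
            np.testing.assert_allclose(
                coef, truth.bulk_planes[2, e], atol=1e-6
            )

    def test_bulk_motion_adds_exactly_a_plane(self, phantom_default, scheme):
        """Phase difference between motion and no-motion simulations is a
        plane per (frame, encoding): OLS plane-regression residual ~ 0.

        Motion amplitudes are kept small enough that the difference phase
        never wraps, so plain least squares is a valid independent check.
        """
        config, _, _, truth = phantom_default
        base = simulate_acquisition(truth, None, scheme, config)
        bulk = BulkMotionParams.random(10, 0.02, 0.02, seed=7)
        moved = simulate_acquisition(truth, bulk, scheme, config)
        combined = truth.combined_mask()
        rows, cols = np.nonzero(combined)
        A = np.column_stack([cols, rows, np.ones_like(cols, dtype=float)])
        diff = np.angle(moved.data * np.conj(base.data))
        for e, t in ((0, 1), (4, 6), (7, 9)):
            phi = diff[e, t][combined]
            coef, *_ = np.linalg.lstsq(A, phi, rcond=None)
            assert np.abs(phi - A @ coef).max() < 1e-10

    def test_rotation_beyond_small_angle_rejected(self, phantom_default):
        config, _, _, truth = phantom_default
        rot = np.zeros(10)
        rot[1] = 6.0
        bulk = BulkMotionParams(np.zeros((10, 3)), rot)
        with pytest.raises(ValueError, match="small-angle"):
            simulate_acquisition(truth, bulk, config=config)

    def test_frame0_motion_must_be_zero(self):
        trans = np.zeros((10, 3))
        trans[0] = [0.1, 0, 0]
        with pytest.raises(ValueError, match="reference frame"):
            BulkMotionParams(trans, np.zeros(10))

    def test_background_phase_present_in_raw_phase(self, scheme):
        bg = make_smooth_background((60, 60), amplitude=0.7, seed=1)
        config = PhantomConfig(background_phase=bg)
        _, _, truth = generate_phantom(config)
        series = simulate_acquisition(truth, None, scheme, config)
        combined = truth.combined_mask()
        phase0 = np.angle(series.data[0, 0])[combined]
        np.testing.assert_allclose(phase0, bg[combined], atol=1e-10)


class TestGeneratePPG:
    def test_zero_jitter_constant_rr(self):
        trace = generate_ppg(800.0, 0.0, n_beats=10, seed=0)
        np.testing.assert_allclose(trace.rr_intervals_ms, 800.0)
        assert rmssd(trace) == 0.0

    def test_rmssd_of_iid_jitter(self):
        """RMSSD of i.i.d. normal RR intervals is sigma * sqrt(2)."""
        trace = generate_ppg(800.0, 25.0, n_beats=10_001, seed=12)
        assert rmssd(trace) == pytest.approx(25.0 * np.sqrt(2), rel=0.03)

    def test_minimum_beats(self):
        with pytest.raises(ValueError):
            generate_ppg(800.0, 0.0, n_beats=2)
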
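"""Drift correction, B0 estimation/re-centring, erosion, exclusions."""

import numpy as np
import pytest

from qmtcest.preprocessing import (drift_correct, erode_mask,
                                   exclude_b0_outliers, fit_b0_lowb1,
                                   fit_b0_wassr, normalize_maps, recenter)
from qmtcest.qmt import MTParams, two_pool_z
from qmtcest.relaxometry import eq1_signal

WASSR = np.round(np.arange(-1.0, 1.001, 0.1), 10)
LOW = np.round(np.arange(-6.0, 6.001, 0.2), 10)


class TestDriftCorrect:
    def test_constant_references_divide_only(self):
        frames = np.array([0.8, 0.9, 0.7, 0.8, 0.6, 0.8])
        refs = np.array([0, 2, 5])
        frames[refs] = 0.8
        z, model = drift_correct(frames, refs)
        assert model.slope == pytest.approx(0.0, abs=1e-14)
        assert np.allclose(z, frames / 0.8)

    def test_closed_form_slope_three_references(self):
        frames = np.zeros(13)
        frames[[0, 6, 12]] = [1.00, 0.98, 0.96]
        _, model = drift_correct(frames, [0, 6, 12])
        assert model.slope == pytest.approx(-1.0 / 300.0, rel=1e-12)

    def test_inverts_generator_drift(self):
        rng = np.random.default_rng(0)
        z_true = rng.uniform(0.4, 1.0, 19)
        refs = np.arange(0, 19, 6)
        z_true[refs] = 1.0
        slope = 2e-4
        drifted = z_true * (1.0 + slope * np.arange(19))
        z, _ = drift_correct(drifted, refs)
        assert np.allclose(z, z_true, atol=1e-10)

    def test_requires_two_references(self):
        with pytest.raises(ValueError):
            drift_correct(np.ones(5), [2])

    def test_nonpositive_reference_flags_nan(self):
        frames = np.zeros((4, 2))
        frames[:, 0] = [1.0, 0.9, 1.0, 1.0]
        frames[:, 1] = [-1.0, 0.5, -1.0, 0.4]   # bad voxel
        z, _ = drift_correct(frames, [0, 2])
        assert np.all(np.isfinite(z[:, 0]))
        assert np.all(np.isnan(z[:, 1]))


class TestB0Fits:
    def test_wassr_symmetric_spectrum_centred(self):
        z = eq1_signal(WASSR, 0.1, 2000.0, 44.0)
        assert fit_b0_wassr(WASSR, z).shift_ppm == pytest.approx(0.0,
                                                                 abs=1e-6)

    def test_wassr_recovers_generator_shift(self):
        z = eq1_signal(WASSR - 0.12, 0.1, 2000.0, 44.0)
        assert fit_b0_wassr(WASSR, z).shift_ppm == pytest.approx(0.12,
                                                                 abs=0.005)

    def test_wassr_monte_carlo_mean(self):
        rng = np.random.default_rng(5)
        z = eq1_signal(WASSR - 0.1, 0.1, 2000.0, 44.0)
        shifts = [fit_b0_wassr(WASSR, z + rng.normal(0, 0.01, z.shape)).shift_ppm
                  for _ in range(100)]
        se = np.std(shifts) / np.sqrt(len(shifts))
        assert abs(np.mean(shifts) - 0.1) < 2 * max(se, 1e-3)

    def test_wassr_needs_points_in_window(self):
        with pytest.raises(ValueError):
            fit_b0_wassr(np.array([-2.0, -1.5, 1.5, 2.0]), np.ones(4))

    def test_lowb1_symmetric_and_shifted(self):
        p = MTParams.from_mt_effect(47.0, 1.8, 7.8)
        z0 = two_pool_z(LOW, 2.0, p, 2200.0)
        assert fit_b0_lowb1(LOW, z0).shift_ppm == pytest.approx(0.0, abs=1e-3)
        z_s = two_pool_z(LOW - 0.15, 2.0, p, 2200.0)
        assert fit_b0_lowb1(LOW, z_s).shift_ppm == pytest.approx(0.15,
                                                                 abs=0.01)

    def test_lowb1_monte_carlo_mean(self):
        rng = np.random.default_rng(6)
        p = MTParams.from_mt_effect(47.0, 1.8, 7.8)
        z = two_pool_z(LOW - 0.1, 2.0, p, 2200.0)
        shifts = [fit_b0_lowb1(LOW, z + rng.normal(0, 0.01, z.shape)).shift_ppm
                  for _ in range(50)]
        se = np.std(shifts) / np.sqrt(len(shifts))
        assert abs(np.mean(shifts) - 0.1) < 2 * max(se, 2e-3)


class TestRecenter:
    def test_zero_shift_identity(self):
        z = eq1_signal(WASSR, 0.1, 2000.0, 44.0)
        assert np.allclose(recenter(WASSR, z, 0.0), z)

    def test_whole_step_shift_moves_one_sample(self):
        z = np.sin(WASSR)
        out = recenter(WASSR, z, 0.1)
        interior = slice(0, -1)
        assert np.allclose(out[interior], z[1:], atol=1e-12)
        assert np.isnan(out[-1])

    def test_half_step_midpoint_average(self):
        grid = np.arange(5, dtype=float)
        z = np.array([0.0, 1.0, 0.0, 1.0, 0.0])
        out = recenter(grid, z, 0.5)
        assert np.allclose(out[:-1], 0.5)
        assert np.isnan(out[-1])


class TestErode:
    def test_block_erodes_to_centre(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[2:5, 2:5] = True
        out = erode_mask(mask)
        expected = np.zeros_like(mask)
        expected[3, 3] = True
        assert np.array_equal(out, expected)

    def test_full_image_shrinks_one_pixel_per_side(self):
        mask = np.ones((6, 8), dtype=bool)
        out = erode_mask(mask)
        expected = np.zeros_like(mask)
        expected[1:-1, 1:-1] = True
        assert np.array_equal(out, expected)

    def test_random_mask_matches_neighbourhood_oracle(self):
        rng = np.random.default_rng(2)
        mask = rng.random((16, 16)) > 0.4
        out = erode_mask(mask)
        padded = np.pad(mask, 1, constant_values=False)
        for i in range(16):
            for j in range(16):
                keep = padded[i:i + 3, j:j + 3].all()
                assert out[i, j] == keep


class TestExclusionsAndNormalization:
    def test_all_zero_shifts_valid(self):
        assert exclude_b0_outliers(np.zeros((3, 3))).all()

    def test_boundary_half_ppm_retained(self):
        """Exactly 0.5 ppm stays (only strictly greater shifts go)."""
        shifts = np.array([[0.5, -0.5, 0.500001]])
        assert exclude_b0_outliers(shifts).tolist() == [[True, True, False]]

    def test_mixed_shifts(self):
        shifts = np.array([0.2, 0.6, -0.7, 0.4])
        assert exclude_b0_outliers(shifts).tolist() == [True, False, False,
                                                        True]

    def test_nan_invalid(self):
        assert not exclude_b0_outliers(np.array([np.nan]))[0]

    def test_normalize_maps(self):
        t1n, t2n = normalize_maps(np.array([2000.0, 0.0, 4400.0]),
                                  np.array([300.0, 150.0, 330.0]))
        assert np.allclose(t1n, [0.5, 0.0, 1.1])
        assert np.allclose(t2n, [1.0, 0.5, 1.1])   # may exceed 1, no clipping
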
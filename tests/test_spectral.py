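"""ROI-mean extraction, MSC, normalization and first derivatives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from podfusion.errors import DegenerateInputError, EmptyROIError, ShapeError
from podfusion.spectral import (
    Spectrum,
    default_wavelengths,
    first_derivative,
    msc_apply,
    msc_correct,
    msc_fit,
    normalize_spectrum,
    roi_mean_spectrum,
)


def spectrum(values):
    values = np.asarray(values, dtype=float)
    return Spectrum(np.linspace(400.0, 900.0, values.size), values)


class TestRoiMeanSpectrum:
    def test_constant_cube_gives_constant_spectrum(self):
        cube = np.full((4, 5, 10), 3.25)
        mask = np.zeros((4, 5), dtype=bool)
        mask[1, 2] = mask[3, 3] = True
        out = roi_mean_spectrum(cube, mask)
        assert np.allclose(out.reflectance, 3.25)

    def test_two_pixel_mask_averages_pairwise(self, rng):
        cube = rng.uniform(size=(3, 3, 8))
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, 0] = mask[2, 1] = True
        out = roi_mean_spectrum(cube, mask)
        assert np.allclose(out.reflectance, (cube[0, 0] + cube[2, 1]) / 2)

    def test_matches_bruteforce_loop_mean(self, rng):
        cube = rng.uniform(size=(5, 5, 12))
        mask = rng.uniform(size=(5, 5)) > 0.5
        mask[0, 0] = True  # guarantee non-empty
        expected = np.zeros(12)
        count = 0
        for i in range(5):
            for j in range(5):
                if mask[i, j]:
                    expected += cube[i, j]
                    count += 1
        assert np.allclose(roi_mean_spectrum(cube, mask).reflectance, expected / count)

    def test_permutation_invariant_in_pixel_order(self, rng):
        cube = rng.uniform(size=(4, 4, 6))
        mask = np.ones((4, 4), dtype=bool)
        perm = rng.permutation(16)
        shuffled = cube.reshape(16, 6)[perm].reshape(4, 4, 6)
        assert np.allclose(
            roi_mean_spectrum(cube, mask).reflectance,
            roi_mean_spectrum(shuffled, mask).reflectance,
        )

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyROIError):
            roi_mean_spectrum(np.ones((2, 2, 5)), np.zeros((2, 2), dtype=bool))


class TestMSC:
    def test_identical_samples_fit_identity(self):
        x = np.tile(np.linspace(0.1, 0.9, 30), (5, 1))
        model = msc_fit(x)
        assert np.allclose(model.intercepts, 0.0, atol=1e-12)
        assert np.allclose(model.slopes, 1.0)

    def test_exact_affine_sample_recovers_coefficients(self):
        t = np.linspace(0.1, 0.9, 40)
        x = np.vstack([t, 2.0 * t + 3.0])
        model = msc_fit(x)
        # sample 1 = 2t + 3; the ideal is the row mean 1.5t + 1.5, so the OLS
        # slope/intercept against the ideal are (b, a) = (4/3, 1)
        assert np.allclose(model.slopes[1], 2.0 / 1.5)
        assert np.allclose(model.intercepts[1], 3.0 - (2.0 / 1.5) * 1.5)

    def test_fit_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(size=(10, 60))
        model = msc_fit(x)
        ideal = x.mean(axis=0)
        design = np.column_stack([np.ones_like(ideal), ideal])
        for i in range(10):
            a, b = np.linalg.solve(design.T @ design, design.T @ x[i])
            assert abs(model.intercepts[i] - a) <= 1e-10 * max(1, abs(a))
            assert abs(model.slopes[i] - b) <= 1e-10 * abs(b)

    def test_apply_identity_and_affine_inversion(self):
        t = np.linspace(0.2, 0.8, 25)
        s = spectrum(t)
        assert np.allclose(msc_apply(s, 0.0, 1.0).reflectance, t)
        distorted = spectrum(2.0 * t + 3.0)
        assert np.allclose(msc_apply(distorted, 3.0, 2.0).reflectance, t)

    def test_refit_after_correction_gives_unit_slopes(self, rng):
        # each corrected spectrum re-regressed on the original ideal must be
        # the identity: correction divides out exactly the fitted (a, b)
        x = rng.uniform(size=(8, 50))
        corrected, model = msc_correct(x)
        ideal_c = model.ideal - model.ideal.mean()
        denom = ideal_c @ ideal_c
        for row in corrected:
            slope = (row - row.mean()) @ ideal_c / denom
            intercept = row.mean() - slope * model.ideal.mean()
            assert abs(slope - 1.0) < 1e-10
            assert abs(intercept) < 1e-10

    def test_affine_family_collapses(self, rng):
        t = np.linspace(0.1, 0.7, 80)
        b = np.exp(rng.normal(0, 0.2, 20))
        a = rng.normal(0, 0.05, 20)
        x = b[:, None] * t + a[:, None]
        corrected, _ = msc_correct(x)
        assert np.abs(corrected - corrected[0]).max() < 1e-10

    def test_near_zero_slope_raises(self):
        with pytest.raises(DegenerateInputError):
            msc_apply(spectrum(np.linspace(0, 1, 10)), 0.0, 1e-12)

    def test_constant_ideal_raises(self):
        with pytest.raises(DegenerateInputError):
            msc_fit(np.ones((4, 20)))


class TestNormalize:
    def test_three_point_example(self):
        out = normalize_spectrum(spectrum([0.0, 5.0, 10.0]))
        assert np.allclose(out.reflectance, [0.0, 0.5, 1.0])

    def test_idempotent_on_normalized_input(self, rng):
        v = rng.uniform(size=30)
        v[0], v[1] = 0.0, 1.0
        once = normalize_spectrum(spectrum(v))
        assert np.allclose(once.reflectance, v)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=40, unique=True))
    def test_argmax_preserved(self, values):
        s = spectrum(sorted(values, key=lambda _: hash(str(_))))
        out = normalize_spectrum(s)
        assert out.reflectance.argmax() == s.reflectance.argmax()
        assert out.reflectance.min() == 0.0 and out.reflectance.max() == 1.0

    def test_constant_raises(self):
        with pytest.raises(DegenerateInputError):
            normalize_spectrum(spectrum(np.full(10, 0.3)))


class TestFirstDerivative:
    def test_linear_ramp_constant_slope(self):
        wl = default_wavelengths(50)
        s = Spectrum(wl, 0.004 * wl + 1.0)
        assert np.allclose(first_derivative(s).reflectance, 0.004)

    def test_constant_gives_zero(self):
        assert np.allclose(first_derivative(spectrum(np.full(20, 2.0))).reflectance, 0.0)

    def test_quadratic_exact_on_interior(self):
        wl = default_wavelengths(40)
        s = Spectrum(wl, 3.0 * wl**2 - 2.0 * wl + 5.0)
        d = first_derivative(s).reflectance
        assert np.allclose(d[1:-1], (6.0 * wl - 2.0)[1:-1], rtol=1e-12)

    def test_too_short_raises(self):
        with pytest.raises(ShapeError):
            first_derivative(Spectrum(np.array([1.0, 2.0]), np.array([0.0, 1.0])))

    def test_nonuniform_grid_raises(self):
        wl = np.array([1.0, 2.0, 4.0, 8.0])
        with pytest.raises(ShapeError):
            first_derivative(Spectrum(wl, np.ones(4)))


class TestSpectrumValidation:
    def test_decreasing_wavelengths_rejected(self):
        with pytest.raises(ShapeError):
            Spectrum(np.array([3.0, 2.0, 1.0]), np.ones(3))

    def test_nonfinite_reflectance_rejected(self):
        with pytest.raises(ShapeError):
            Spectrum(np.array([1.0, 2.0]), np.array([np.nan, 1.0]))
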
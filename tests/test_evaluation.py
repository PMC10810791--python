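"""Metrics (MSE/SNR/PSNR/SSIM), edge-sigmoid resolution, decay slope."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ramanoise import (decay_slope, evaluate_spectra, fit_edge_sigmoid, mse,
                       psnr, resolution_over_lines, snr_db, snr_linear, ssim)
from ramanoise.errors import ParameterError, ShapeError
from ramanoise.evaluation import LOGISTIC_FWHM_CONST


def logistic(x, i1, i2, a, b):
    return i2 + (i1 - i2) / (1.0 + np.exp(-a * (x - b)))


class TestMse:
    def test_identical_vectors_give_zero(self, rng):
        x = rng.normal(size=50)
        assert mse(x, x) == 0.0

    def test_constant_offset_example(self):
        assert mse(np.zeros(100), np.full(100, 0.1)) == pytest.approx(0.01, rel=1e-12)

    def test_matches_loop_oracle(self, rng):
        x, y = rng.normal(size=37), rng.normal(size=37)
        acc = 0.0
        for xi, yi in zip(x, y):
            acc += abs(yi - xi) ** 2
        assert mse(x, y) == pytest.approx(acc / 37, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            mse(np.zeros(3), np.zeros(4))


class TestSnr:
    def test_uniform_residual_example(self):
        x = np.ones(100)
        assert snr_db(x, x + 0.1) == pytest.approx(20.0, abs=1e-10)

    def test_doubling_residual_costs_six_db(self, rng):
        x = rng.normal(size=64)
        r = rng.normal(size=64)
        drop = snr_db(x, x + r) - snr_db(x, x + 2 * r)
        assert drop == pytest.approx(20 * np.log10(2), abs=1e-9)

    def test_matches_loop_oracle(self, rng):
        x, y = rng.normal(size=23), rng.normal(size=23)
        sig = sum(v * v for v in x)
        resid = sum((b - a) ** 2 for a, b in zip(x, y))
        assert snr_db(x, y) == pytest.approx(10 * np.log10(sig / resid), abs=1e-10)

    def test_identical_input_flagged_infinite(self, rng):
        x = rng.normal(size=10)
        with pytest.warns(RuntimeWarning):
            assert snr_db(x, x) == np.inf

    @settings(deadline=None, max_examples=30)
    @given(c=st.floats(0.1, 100.0), seed=st.integers(0, 1000))
    def test_residual_scaling_law(self, c, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=32) + 3
        y = x + rng.normal(size=32)
        lhs = snr_db(x, y) + 20 * np.log10(c)
        rhs = snr_db(x, x + (y - x) / c)
        assert lhs == pytest.approx(rhs, abs=1e-8)


class TestPsnr:
    def test_uniform_offset_example(self):
        X = np.zeros((8, 8))
        X[0, 0] = 1.0  # joint max 1 -> already normalized
        Y = X + 0.1
        # normalization divides by 1.1; compare against the direct formula
        Xn, Yn = X / 1.1, Y / 1.1
        expected = 10 * np.log10(1.0 / np.mean((Yn - Xn) ** 2))
        assert psnr(X, Y) == pytest.approx(expected, abs=1e-10)

    def test_unnormalized_uniform_offset_is_20db(self):
        X = np.random.default_rng(0).uniform(size=(16, 16))
        assert psnr(X, X + 0.1, normalize=False) == pytest.approx(20.0, abs=1e-10)

    def test_decreases_with_offset(self):
        X = np.random.default_rng(1).uniform(size=(16, 16))
        values = [psnr(X, X + d, normalize=False) for d in (0.05, 0.1, 0.2, 0.4)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_identical_images_flagged(self):
        X = np.random.default_rng(2).uniform(size=(8, 8))
        with pytest.warns(RuntimeWarning):
            assert psnr(X, X) == np.inf


class TestSsim:
    def test_self_similarity_is_one(self):
        X = np.random.default_rng(0).uniform(size=(32, 32))
        assert ssim(X, X) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        X, Y = rng.uniform(size=(32, 32)), rng.uniform(size=(32, 32))
        assert ssim(X, Y) == pytest.approx(ssim(Y, X), abs=1e-12)

    def test_global_window_matches_direct_formula(self):
        """8x8 toy pair against a one-shot evaluation of the SSIM formula."""
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(8, 8))
        Y = np.clip(X + rng.normal(0, 0.1, size=(8, 8)), 0, 1)
        c1, c2 = 0.01 ** 2, 0.03 ** 2
        ux, uy = X.mean(), Y.mean()
        vx, vy = X.var(ddof=1), Y.var(ddof=1)
        vxy = np.sum((X - ux) * (Y - uy)) / (X.size - 1)
        direct = ((2 * ux * uy + c1) * (2 * vxy + c2)) / \
                 ((ux**2 + uy**2 + c1) * (vx + vy + c2))
        assert ssim(X, Y, window="global", data_range=1.0) == \
            pytest.approx(direct, abs=1e-10)

    def test_matches_skimage_reference(self):
        """Independent cross-check against scikit-image's implementation."""
        from skimage.metrics import structural_similarity

        rng = np.random.default_rng(3)
        X = rng.uniform(size=(48, 48))
        Y = np.clip(X + rng.normal(0, 0.15, size=(48, 48)), 0, 1)
        ref = structural_similarity(X, Y, gaussian_weights=True, sigma=1.5,
                                    win_size=11, data_range=1.0,
                                    use_sample_covariance=True)
        assert ssim(X, Y, data_range=1.0) == pytest.approx(ref, abs=5e-4)


class TestEdgeSigmoid:
    def test_noiseless_edge_recovers_analytic_fwhm(self):
        x = np.linspace(-10, 10, 81)
        y = logistic(x, 5.0, 1.0, 1.0, 0.4)
        fit = fit_edge_sigmoid(x, y)
        assert fit.success
        assert fit.fwhm == pytest.approx(LOGISTIC_FWHM_CONST, rel=0.01)
        assert fit.fwhm == pytest.approx(2 * np.log(3 + 2 * np.sqrt(2)), rel=1e-9)

    def test_doubled_steepness_halves_fwhm(self):
        x = np.linspace(-10, 10, 81)
        f1 = fit_edge_sigmoid(x, logistic(x, 4, 0, 1.0, 0.0))
        f2 = fit_edge_sigmoid(x, logistic(x, 4, 0, 2.0, 0.0))
        assert f2.fwhm == pytest.approx(f1.fwhm / 2, rel=1e-6)

    def test_falling_edge_supported(self):
        x = np.linspace(-10, 10, 81)
        fit = fit_edge_sigmoid(x, logistic(x, 1.0, 6.0, -0.8, -1.0))
        assert fit.success
        assert fit.fwhm == pytest.approx(LOGISTIC_FWHM_CONST / 0.8, rel=0.01)

    def test_noisy_recovery_within_ten_percent(self):
        """5% additive noise: mean recovered FWHM within 10% over 100 seeds."""
        x = np.linspace(-8, 8, 65)
        truth = LOGISTIC_FWHM_CONST / 1.0
        widths = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = logistic(x, 3.0, 1.0, 1.0, 0.0) + rng.normal(0, 0.05 * 2.0, size=x.size)
            fit = fit_edge_sigmoid(x, y)
            if fit.success:
                widths.append(fit.fwhm)
        assert len(widths) >= 95
        assert abs(np.mean(widths) - truth) / truth < 0.10

    def test_invariant_to_offset_and_scale(self):
        x = np.linspace(-10, 10, 81)
        y = logistic(x, 4.0, 1.0, 0.7, 0.2)
        f0 = fit_edge_sigmoid(x, y)
        f1 = fit_edge_sigmoid(x, 5.0 * y + 11.0)
        assert f1.fwhm == pytest.approx(f0.fwhm, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ParameterError):
            fit_edge_sigmoid(np.arange(5), np.arange(5.0))


class TestResolutionOverLines:
    def test_duplicated_profiles_have_zero_sd(self):
        x = np.linspace(-5, 5, 41)
        y = logistic(x, 3, 0, 1.2, 0.0)
        mean, sd, fits = resolution_over_lines([(x, y)] * 4)
        assert sd == pytest.approx(0.0, abs=1e-9)
        assert all(f.success for f in fits)

    def test_mean_and_sd_of_known_widths(self):
        x = np.linspace(-20, 20, 161)
        profiles = [(x, logistic(x, 1, 0, LOGISTIC_FWHM_CONST / w, 0.0))
                    for w in (3.0, 4.0, 5.0)]
        mean, sd, _ = resolution_over_lines(profiles)
        assert mean == pytest.approx(4.0, rel=1e-3)
        assert sd == pytest.approx(1.0, rel=1e-2)

    def test_noisy_lines_mean_close_to_truth(self):
        x = np.linspace(-8, 8, 65)
        truth = LOGISTIC_FWHM_CONST
        profiles = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            profiles.append((x, logistic(x, 3, 1, 1.0, 0.0)
                             + rng.normal(0, 0.05 * 2, size=x.size)))
        mean, _, _ = resolution_over_lines(profiles)
        assert abs(mean - truth) / truth < 0.10


class TestDecaySlope:
    def test_constant_profile_has_zero_slope(self):
        fit = decay_slope(np.full(10, 7.0))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_exact_line_recovered(self):
        x = np.arange(20, dtype=float)
        fit = decay_slope(3.0 - 0.5 * x, x)
        assert fit.slope == pytest.approx(-0.5, abs=1e-12)
        assert fit.intercept == pytest.approx(3.0, abs=1e-12)

    def test_offset_changes_intercept_only(self, rng):
        y = rng.normal(size=15)
        f0, f1 = decay_slope(y), decay_slope(y + 10.0)
        assert f1.slope == pytest.approx(f0.slope, abs=1e-12)
        assert f1.intercept == pytest.approx(f0.intercept + 10.0, abs=1e-10)

    def test_degenerate_positions_rejected(self):
        with pytest.raises(ParameterError):
            decay_slope(np.arange(3.0), np.zeros(3))


def test_evaluate_spectra_report(rng):
    ref = rng.normal(size=(6, 40)) + 5
    test = ref + rng.normal(0, 0.1, size=(6, 40))
    rep = evaluate_spectra(ref, test)
    assert rep.mse_values.shape == (6,)
    assert rep.mean_mse == pytest.approx(np.mean(rep.mse_values))
    assert rep.mean_snr_db == pytest.approx(
        np.mean([snr_db(r, t) for r, t in zip(ref, test)]), abs=1e-9)


def test_snr_linear_consistency(rng):
    x = rng.normal(size=30)
    y = x + rng.normal(size=30)
    assert 10 * np.log10(snr_linear(x, y)) == pytest.approx(snr_db(x, y), abs=1e-12)
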
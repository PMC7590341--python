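import numpy as np
import pytest

from serscreen.baseline import (
    AirplsConfig,
    DegenerateSystemError,
    airpls_baseline,
    whittaker_smooth,
)
from serscreen.spectra_io import DEFAULT_GRID
from serscreen.synthetic import SyntheticConfig, baseline_function, simulate_spectrum


def dense_whittaker_oracle(y, w, lam, diff_order):
    """Explicit dense solve of (W + lam D'D) z = W y."""
    n = len(y)
    d = np.eye(n)
    for _ in range(diff_order):
        d = np.diff(d, axis=0)
    a = np.diag(w) + lam * d.T @ d
    return np.linalg.solve(a, w * y)


class TestWhittaker:
    def test_constant_signal_is_fixed_point(self):
        y = np.full(50, 3.7)
        z = whittaker_smooth(y, np.ones(50), lam=1e4, diff_order=2)
        assert np.allclose(z, 3.7, atol=1e-9)

    def test_line_in_penalty_null_space(self):
        y = 2.0 + 0.5 * np.arange(40)
        z = whittaker_smooth(y, np.ones(40), lam=1e6, diff_order=2)
        assert np.allclose(z, y, atol=1e-6)

    @pytest.mark.parametrize("diff_order", [1, 2])
    @pytest.mark.parametrize("n", [8, 32, 64])
    def test_matches_dense_oracle(self, rng, n, diff_order):
        y = rng.normal(size=n)
        w = rng.uniform(0.1, 2.0, size=n)
        z = whittaker_smooth(y, w, lam=10.0, diff_order=diff_order)
        z_oracle = dense_whittaker_oracle(y, w, 10.0, diff_order)
        assert np.allclose(z, z_oracle, atol=1e-8)

    def test_lambda_to_inf_is_weighted_ls_line(self, rng):
        y = rng.normal(size=64)
        z = whittaker_smooth(y, np.ones(64), lam=1e12, diff_order=2)
        coef = np.polyfit(np.arange(64), y, 1)
        assert np.allclose(z, np.polyval(coef, np.arange(64)), atol=1e-4)

    def test_all_zero_weights_degenerate(self):
        with pytest.raises(DegenerateSystemError):
            whittaker_smooth(np.ones(10), np.zeros(10), lam=1.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            whittaker_smooth(np.array([1.0, np.inf, 2.0]), np.ones(3), lam=1.0)


class TestAirpls:
    def test_smooth_drift_fully_removed(self, grid):
        v = grid.points
        drift = 0.2 + 2e-4 * v + 2.0 * np.exp(-v / 300.0)
        fit = airpls_baseline(drift, AirplsConfig(lam=100.0))
        amplitude = drift.max() - drift.min()
        assert np.abs(fit.corrected).max() < 0.01 * amplitude
        assert fit.converged

    def test_drift_plus_peaks_recovered(self, grid):
        # linear drift + 3 Lorentzians; stiffness matched to ~6 cm-1 peaks
        v = grid.points
        drift = 0.1 + 3e-4 * (v - 204.0)
        centers, heights, gamma = [600.0, 975.0, 1470.0], [0.5, 0.3, 0.4], 6.0
        y = drift.copy()
        for c, h in zip(centers, heights):
            y += h * gamma**2 / ((v - c) ** 2 + gamma**2)
        fit = airpls_baseline(y, AirplsConfig(lam=1e5))
        for c, h in zip(centers, heights):
            i = np.argmin(np.abs(v - c))
            apex = fit.corrected[i - 2 : i + 3].max()
            assert apex == pytest.approx(h, rel=0.05)
        off_peak = np.ones(len(v), bool)
        for c in centers:
            off_peak &= np.abs(v - c) > 40.0
        rms = np.sqrt(np.mean((fit.baseline[off_peak] - drift[off_peak]) ** 2))
        assert rms < 0.02 * (drift.max() - drift.min())

    def test_negative_peaks_baseline_hugs_upper_envelope(self, grid):
        v = grid.points
        drift = 1.0 + 1e-4 * v
        y = drift.copy()
        for c in [700.0, 1200.0]:
            y -= 0.8 * 36.0 / ((v - c) ** 2 + 36.0)
        fit = airpls_baseline(y, AirplsConfig(lam=100.0))
        # downward peaks sit below the fitted baseline: corrected <= 0 nearly
        # everywhere (within 1% of peak depth; the flexible baseline dips
        # slightly into the peak cores, leaving small positives on the flanks)
        depth = 0.8
        assert np.mean(fit.corrected <= 0.01 * depth) > 0.9
        assert np.median(fit.corrected) <= 0.0
        # flat regions never rise above the baseline
        flat = np.ones(len(v), bool)
        for c in [700.0, 1200.0]:
            flat &= np.abs(v - c) > 60.0
        assert np.all(fit.corrected[flat] <= 0.01 * depth)

    def test_weights_zero_above_baseline_positive_below(self, grid):
        v = grid.points
        rng = np.random.default_rng(3)
        y = 0.5 + 1e-4 * v + rng.normal(0, 0.01, len(v))
        y += 0.7 * 36.0 / ((v - 900.0) ** 2 + 36.0)
        fit = airpls_baseline(y, AirplsConfig(max_iter=8))
        assert len(fit.weights_history) == fit.n_iter
        assert np.all(fit.weights_history[0] == 1.0)
        for w in fit.weights_history[1:]:
            interior = w[1:-1]
            assert np.all(interior >= 0)
            # signal points (weight 0) and anchor points (>= 1) only
            assert np.all((interior == 0) | (interior >= 1.0))

    def test_scale_equivariance(self, grid, rng):
        v = grid.points
        y = 0.3 + 1e-4 * v + rng.normal(0, 0.01, len(v))
        y += 0.5 * 36.0 / ((v - 1000.0) ** 2 + 36.0)
        alpha = 7.3
        f1 = airpls_baseline(y)
        f2 = airpls_baseline(alpha * y)
        assert np.allclose(alpha * f1.baseline, f2.baseline, atol=1e-8 * alpha)

    def test_max_iter_reached_is_not_error(self):
        rng = np.random.default_rng(0)
        y = np.abs(rng.normal(size=200)) + np.linspace(0, 1, 200)
        fit = airpls_baseline(y, AirplsConfig(max_iter=2, tol_ratio=1e-9))
        assert not fit.converged
        assert fit.n_iter == 2

    def test_corrected_is_input_minus_baseline(self, rng):
        y = rng.normal(size=128) + 5
        fit = airpls_baseline(y)
        assert np.allclose(fit.corrected, y - fit.baseline, atol=1e-12)

    def test_recovers_generator_baseline_off_peak(self):
        # ties the baseline module to the synthetic ground truth
        cfg = SyntheticConfig(noise_sd=0.0)
        for seed in [1, 2, 3]:
            s, truth = simulate_spectrum(600.0, cfg, seed=seed)
            fit = airpls_baseline(s.intensities)
            v = s.wavenumbers
            off = np.ones(len(v), bool)
            for p in truth.peaks:
                off &= np.abs(v - p.center) > 5 * p.width
            rms = np.sqrt(np.mean((fit.baseline[off] - truth.baseline[off]) ** 2))
            amplitude = truth.baseline.max() - truth.baseline.min()
            assert rms < 0.02 * amplitude

    def test_invalid_configs_rejected(self):
        for kwargs in [
            {"lam": 0.0},
            {"max_iter": 0},
            {"tol_ratio": 0.0},
            {"tol_ratio": 1.0},
            {"diff_order": 3},
        ]:
            with pytest.raises(ValueError):
                AirplsConfig(**kwargs)
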
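"""Dipolar kernel, trace simulation, background correction, Tikhonov inversion."""

import numpy as np
import pytest

from peldock.deer import (BackgroundModel, DeerInversion, DipolarTrace,
                          InversionSettings, background_correct,
                          dipolar_kernel, select_alpha_lcurve, simulate_trace,
                          tikhonov_invert)
from peldock.labelling import (DistanceDistribution, default_r_grid,
                               modal_distance)

T_GRID = np.arange(0.0, 3.0 + 0.008, 0.016)
FAST_ALPHAS = np.logspace(-3, 3, 25)


def gaussian_distribution(mean, sd, provenance="ground-truth"):
    grid = default_r_grid()
    dens = np.exp(-0.5 * ((grid - mean) / sd) ** 2)
    return DistanceDistribution.from_unnormalized(grid, dens, provenance)


def fast_settings(**kw):
    kw.setdefault("alpha_candidates", FAST_ALPHAS)
    return InversionSettings(**kw)


class TestDipolarKernel:
    def test_first_row_is_unity(self):
        K = dipolar_kernel(T_GRID, default_r_grid())
        assert np.allclose(K[0], 1.0)

    def test_matches_brute_force_quadrature(self):
        """K(1 us, 30 A) against direct powder-average quadrature."""
        K = dipolar_kernel(np.array([0.0, 1.0]), np.array([30.0]))
        x = (np.arange(100_000) + 0.5) / 100_000
        omega = 2 * np.pi * 52.04 / 3.0 ** 3
        brute = np.mean(np.cos((1 - 3 * x ** 2) * omega * 1.0))
        assert K[1, 0] == pytest.approx(brute, abs=1e-4)

    def test_large_r_limit_is_unity(self):
        K = dipolar_kernel(T_GRID, np.array([5000.0]))
        assert np.allclose(K, 1.0, atol=1e-4)

    def test_entries_within_powder_average_bounds(self):
        K = dipolar_kernel(np.arange(0, 10, 0.01), np.arange(15.0, 81.0, 5.0))
        assert K.max() <= 1.0 + 1e-12
        assert K.min() >= -0.5

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            dipolar_kernel(T_GRID, np.array([0.0]))


class TestSimulateTrace:
    def test_zero_mod_depth_gives_pure_background(self):
        p = gaussian_distribution(35, 2)
        bg = BackgroundModel(k=0.1, mod_depth=0.0)
        tr = simulate_trace(p, T_GRID, bg)
        assert np.allclose(tr.signal, np.exp(-0.1 * T_GRID))

    def test_delta_distribution_reproduces_kernel_column(self):
        grid = default_r_grid()
        dens = np.zeros_like(grid)
        dens[40] = 1.0
        p = DistanceDistribution.from_unnormalized(grid, dens)
        bg = BackgroundModel(k=0.0, mod_depth=1.0)
        tr = simulate_trace(p, T_GRID, bg)
        K = dipolar_kernel(T_GRID, grid[[40]])
        assert np.allclose(tr.signal, K[:, 0], atol=1e-12)

    def test_same_seed_identical_noise(self):
        p = gaussian_distribution(35, 2)
        bg = BackgroundModel(k=0.08, mod_depth=0.35)
        a = simulate_trace(p, T_GRID, bg, noise_sigma=0.01, seed=9)
        b = simulate_trace(p, T_GRID, bg, noise_sigma=0.01, seed=9)
        assert np.array_equal(a.signal, b.signal)

    def test_negative_noise_rejected(self):
        p = gaussian_distribution(35, 2)
        with pytest.raises(ValueError):
            simulate_trace(p, T_GRID, BackgroundModel(0.1, 0.3), noise_sigma=-1)

    def test_stretched_background_dimension(self):
        """Fractal spin-bath dimension d gives B(t) = exp(-k t^(d/3))."""
        bg = BackgroundModel(k=0.1, mod_depth=0.0, dimension=2.0)
        p = gaussian_distribution(35, 2)
        tr = simulate_trace(p, T_GRID, bg)
        assert np.allclose(tr.signal, np.exp(-0.1 * T_GRID ** (2 / 3)))
        with pytest.raises(ValueError, match="dimension"):
            BackgroundModel(0.1, 0.3, dimension=9.0)


class TestBackgroundCorrect:
    def test_known_background_recovered(self):
        p = gaussian_distribution(35, 2)
        bg = BackgroundModel(k=0.08, mod_depth=0.35)
        tr = simulate_trace(p, T_GRID, bg)
        _, fit = background_correct(tr)
        assert fit.k == pytest.approx(0.08, rel=0.01)
        assert fit.mod_depth == pytest.approx(0.35, abs=0.01)

    def test_no_modulation_raises(self):
        tr = DipolarTrace(T_GRID, np.exp(-0.05 * T_GRID))
        with pytest.raises(ValueError, match="modulation depth"):
            background_correct(tr)

    def test_flat_background_full_depth_returns_form_factor(self):
        p = gaussian_distribution(30, 2)
        tr = simulate_trace(p, T_GRID, BackgroundModel(k=0.0, mod_depth=1.0))
        form, fit = background_correct(tr)
        assert fit.k == pytest.approx(0.0, abs=1e-3)
        assert np.abs(form.signal - tr.signal).max() < 0.02

    def test_bad_fraction_rejected(self):
        p = gaussian_distribution(30, 2)
        tr = simulate_trace(p, T_GRID, BackgroundModel(0.05, 0.3))
        with pytest.raises(ValueError):
            background_correct(tr, fit_start_fraction=1.5)


class TestTikhonov:
    def test_round_trip_modal_within_one_angstrom(self):
        p = gaussian_distribution(35, 2)
        tr = simulate_trace(p, T_GRID, BackgroundModel(0.0, 1.0))
        rec = tikhonov_invert(tr, fast_settings())
        assert modal_distance(rec) == pytest.approx(35.0, abs=1.0)

    def test_output_nonnegative_and_normalized(self):
        p = gaussian_distribution(42, 3)
        tr = simulate_trace(p, T_GRID, BackgroundModel(0.0, 1.0))
        rec = tikhonov_invert(tr, fast_settings(alpha_mode="fixed", alpha=1.0))
        assert np.all(rec.density >= 0)
        assert np.trapezoid(rec.density, rec.r_grid) == pytest.approx(1.0, abs=1e-6)
        assert rec.provenance == "inverted"

    def test_roughness_nonincreasing_in_alpha(self):
        p = gaussian_distribution(38, 2)
        tr = simulate_trace(p, T_GRID, BackgroundModel(0.0, 1.0))
        seminorms = []
        for alpha in (0.01, 0.1, 1.0, 10.0, 100.0):
            _, info = tikhonov_invert(
                tr, fast_settings(alpha_mode="fixed", alpha=alpha),
                full_output=True)
            seminorms.append(info["seminorm"])
        assert all(a >= b - 1e-9 for a, b in zip(seminorms, seminorms[1:]))

    def test_unnormalized_form_factor_rejected(self):
        bad = DipolarTrace(T_GRID, 0.5 * np.ones_like(T_GRID), normalized=False)
        with pytest.raises(ValueError, match="F\\(0\\)"):
            tikhonov_invert(bad, fast_settings())


class TestLCurve:
    def test_corner_found_on_synthetic_problem(self):
        p = gaussian_distribution(35, 2)
        tr = simulate_trace(p, T_GRID, BackgroundModel(0.0, 1.0),
                            noise_sigma=0.005, seed=3)
        tr = DipolarTrace(tr.t, tr.signal / tr.signal[0], normalized=True)
        alpha = select_alpha_lcurve(tr, fast_settings())
        assert alpha in FAST_ALPHAS
        # the corner for a modestly noisy trace is neither extreme
        assert FAST_ALPHAS[1] <= alpha <= FAST_ALPHAS[-2]
        rec = tikhonov_invert(tr, fast_settings(alpha_mode="fixed", alpha=alpha))
        assert modal_distance(rec) == pytest.approx(35.0, abs=2.0)

    def test_too_few_candidates_rejected(self):
        p = gaussian_distribution(35, 2)
        tr = simulate_trace(p, T_GRID, BackgroundModel(0.0, 1.0))
        with pytest.raises(ValueError, match="insufficient candidates"):
            select_alpha_lcurve(tr, InversionSettings(
                alpha_candidates=np.array([0.1, 10.0])))


class TestForwardInverseConsistency:
    @pytest.mark.parametrize("r_mean,lam,k", [
        (25.0, 0.2, 0.0), (35.0, 0.35, 0.08), (45.0, 0.6, 0.2),
        (55.0, 0.4, 0.1),
    ])
    def test_noise_free_modal_recovery(self, r_mean, lam, k):
        """Full simulate -> background-correct -> invert round trip, <= 1 A."""
        p = gaussian_distribution(r_mean, 2.5)
        tr = simulate_trace(p, T_GRID, BackgroundModel(k=k, mod_depth=lam))
        form, _ = background_correct(tr)
        rec = tikhonov_invert(form, fast_settings())
        assert modal_distance(rec) == pytest.approx(r_mean, abs=1.0)

    def test_model_results_surface(self):
        p = gaussian_distribution(40, 2)
        tr = simulate_trace(p, T_GRID, BackgroundModel(0.08, 0.35),
                            noise_sigma=0.01, seed=4)
        res = DeerInversion(tr, fast_settings()).fit()
        assert res.modal_r == pytest.approx(40.0, abs=2.0)
        assert 0 < res.background.mod_depth < 1
        text = res.summary()
        assert "modal distance" in text and "alpha" in text
        report = res.report()
        assert set(report) >= {"alpha", "residual_norm", "modal_r"}


class TestTraceIO:
    def test_ascii_round_trip(self, tmp_path):
        p = gaussian_distribution(35, 2)
        tr = simulate_trace(p, T_GRID, BackgroundModel(0.08, 0.35),
                            noise_sigma=0.01, seed=1)
        path = tmp_path / "trace.dat"
        tr.to_file(path)
        back = DipolarTrace.from_file(path)
        assert np.allclose(back.t, tr.t, atol=1e-6)
        assert np.allclose(back.signal, tr.signal, atol=1e-6)

    def test_nonuniform_grid_rejected(self):
        t = np.array([0.0, 0.1, 0.3])
        with pytest.raises(ValueError, match="uniform"):
            DipolarTrace(t, np.ones(3))
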
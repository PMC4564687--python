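"""Fixed-array projection: grid construction, simplex fit, Monte Carlo errors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from impactnmr.impact import (
    brute_force_simplex,
    build_grid,
    design_matrix,
    effective_tm,
    fit_impact,
    impact_spectral_density,
    monte_carlo_errors,
)
from impactnmr.relaxation import lorentzian_j
from impactnmr.synthetic import NoiseSpec, engrailed_like_profile, simulate_dataset


class TestBuildGrid:
    def test_standard_array_three_sig_figs(self, standard_grid):
        ns = standard_grid.taus_ns
        assert ns[0] == pytest.approx(21.0, abs=1e-12)
        assert ns[1] == pytest.approx(5.27, abs=0.005)
        assert ns[2] == pytest.approx(1.33, abs=0.005)
        assert ns[3] * 1e3 == pytest.approx(333.0, abs=0.5)
        assert ns[4] * 1e3 == pytest.approx(83.6, abs=0.05)
        assert ns[5] == pytest.approx(0.021, abs=1e-12)

    def test_two_point_grid_is_endpoints(self):
        g = build_grid(1e-12, 1e-9, 2)
        assert g.taus == pytest.approx([1e-9, 1e-12])

    @pytest.mark.parametrize("n", [2, 4, 6, 9])
    def test_constant_geometric_ratio(self, n):
        g = build_grid(3e-12, 17e-9, n)
        ratios = g.taus[1:] / g.taus[:-1]
        assert np.all(np.abs(ratios - g.alpha) < 1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            build_grid(1e-9, 1e-12, 6)
        with pytest.raises(ValueError):
            build_grid(1e-12, 1e-9, 1)


class TestSpectralDensity:
    def test_zero_frequency(self, standard_grid):
        A = np.array([0.1, 0.2, 0.3, 0.2, 0.1, 0.1])
        expect = 0.4 * float(np.sum(A * standard_grid.taus))
        assert impact_spectral_density(standard_grid, A, 0.0) == pytest.approx(expect, rel=1e-14)

    def test_half_height_at_omega_tau_one(self, standard_grid):
        A = np.zeros(6)
        A[2] = 1.0
        tau3 = standard_grid.taus[2]
        assert impact_spectral_density(standard_grid, A, 1.0 / tau3) == pytest.approx(
            tau3 / 5.0, rel=1e-14
        )

    def test_matches_term_by_term_loop(self, standard_grid):
        rng = np.random.default_rng(3)
        A = rng.dirichlet(np.ones(6))
        for om in np.geomspace(1e5, 1e10, 20):
            manual = sum(
                0.4 * a * t / (1.0 + (om * t) ** 2) for a, t in zip(A, standard_grid.taus)
            )
            assert impact_spectral_density(standard_grid, A, om) == pytest.approx(manual, rel=1e-13)


class TestFitImpact:
    def test_exact_recovery_of_on_grid_truth(self, standard_grid, exact_map):
        rng = np.random.default_rng(11)
        for k in range(10):
            A_true = rng.dirichlet(np.ones(6))
            res = fit_impact(exact_map(lorentzian_j(standard_grid.taus, A_true), rid=k), standard_grid)
            assert np.abs(res.A - A_true).max() < 1e-6
            assert res.chi2 >= 0.0

    def test_off_grid_lorentzian_brackets(self, standard_grid, exact_map):
        res = fit_impact(exact_map(lorentzian_j([2e-9], [1.0])), standard_grid)
        # 2 ns sits between tau2 = 5.27 ns and tau3 = 1.33 ns
        assert res.A[1] + res.A[2] > 0.95
        assert res.A.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_optimality_vs_brute_force_enumeration(self, seed, map_frequencies):
        omega, _ = map_frequencies
        g4 = build_grid(21e-12, 21e-9, 4)
        rng = np.random.default_rng(seed)
        A_true = rng.dirichlet(np.ones(4))
        y = lorentzian_j(g4.taus, A_true)(omega) * (1 + 0.02 * rng.standard_normal(len(omega)))
        from impactnmr.sdm import SpectralDensityMap

        smap = SpectralDensityMap(
            residue_id=0,
            omega=omega,
            J=y,
            sigma=np.zeros_like(y),
            labels=np.array(["x"] * len(y)),
            j0_field_mhz=1000.0,
            fields_mhz=(),
        )
        res = fit_impact(smap, g4)
        w = np.full(len(y), 1.0 / np.max(np.abs(y)) ** 2)
        _, chi2_brute = brute_force_simplex(design_matrix(g4, omega), y, w, step=0.02)
        assert res.chi2 <= chi2_brute + 1e-12

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_simplex_feasibility_for_noisy_maps(self, seed):
        from impactnmr.relaxation import make_field_context
        from impactnmr.sdm import SpectralDensityMap

        grid = build_grid(21e-12, 21e-9, 6)
        fields = [make_field_context(m) for m in (400.0, 500.0, 600.0, 800.0, 1000.0)]
        omega = np.array([f.omega_eff for f in fields] + [f.omega_N for f in fields] + [0.0])
        rng = np.random.default_rng(seed)
        A_true = rng.dirichlet(np.ones(6))
        y0 = lorentzian_j(grid.taus, A_true)(omega)
        sig = 0.05 * np.abs(y0)
        smap = SpectralDensityMap(
            residue_id=0,
            omega=omega,
            J=y0 + sig * rng.standard_normal(len(y0)),
            sigma=sig,
            labels=np.array(["x"] * len(y0)),
            j0_field_mhz=1000.0,
            fields_mhz=(),
        )
        res = fit_impact(smap, grid)
        assert np.all(res.A >= 0.0)
        assert abs(res.A.sum() - 1.0) <= 1e-9
        assert np.isfinite(res.chi2)

    def test_degenerate_zero_map_flagged(self, standard_grid, exact_map):
        smap = exact_map(lambda om: np.zeros(np.shape(om)))
        res = fit_impact(smap, standard_grid)
        assert "degenerate-nonpositive-map" in res.flags
        assert np.all(np.isfinite(res.A))
        assert res.A.sum() == pytest.approx(1.0, abs=1e-9)

    def test_fast_motion_plateau(self, standard_grid):
        # the 21 ps basis term is effectively constant over the sampled band:
        # at 870 MHz it retains ~98.7% of its zero-frequency value
        A = np.zeros(6)
        A[5] = 1.0
        om = 2 * np.pi * 870e6
        ratio = impact_spectral_density(standard_grid, A, om) / impact_spectral_density(
            standard_grid, A, 0.0
        )
        assert ratio == pytest.approx(0.987, abs=0.002)


class TestEffectiveTm:
    def test_vertex_and_mean_cases(self, standard_grid):
        t = standard_grid.taus
        A = np.zeros(6)
        A[1] = 1.0
        assert effective_tm(A, t) == pytest.approx(t[1], rel=1e-14)
        A = np.array([0.5, 0.5, 0, 0, 0, 0])
        assert effective_tm(A, t) * 1e9 == pytest.approx((21.0 + 5.275) / 2, abs=0.01)

    def test_matches_direct_formula(self, standard_grid):
        rng = np.random.default_rng(5)
        for _ in range(5):
            A = rng.dirichlet(np.ones(6))
            expect = (A[0] * standard_grid.taus[0] + A[1] * standard_grid.taus[1]) / (A[0] + A[1])
            assert effective_tm(A, standard_grid.taus) == pytest.approx(expect, rel=1e-13)

    def test_undefined_when_slow_weights_vanish(self, standard_grid):
        with pytest.raises(ValueError):
            effective_tm([0, 0, 0.5, 0.5, 0, 0], standard_grid.taus)


@pytest.fixture(scope="module")
def one_residue_records():
    truth = engrailed_like_profile(1, seed=3)
    return simulate_dataset(truth).records


class TestMonteCarloErrors:
    def test_zero_noise_gives_zero_sigma(self, standard_grid):
        truth = engrailed_like_profile(1, seed=3, noise=NoiseSpec(scale=0.0))
        recs = simulate_dataset(truth).records
        res = monte_carlo_errors(recs, standard_grid, n_steps=16, seed=1)
        assert np.all(res.sigma_A == 0.0)

    def test_same_seed_reproducible(self, standard_grid, one_residue_records):
        r1 = monte_carlo_errors(one_residue_records, standard_grid, n_steps=64, seed=42)
        r2 = monte_carlo_errors(one_residue_records, standard_grid, n_steps=64, seed=42)
        assert np.array_equal(r1.sigma_A, r2.sigma_A)
        assert np.array_equal(r1.draws, r2.draws)

    def test_draw_matrix_shape_and_feasibility(self, standard_grid, one_residue_records):
        res = monte_carlo_errors(one_residue_records, standard_grid, n_steps=64, seed=42)
        assert res.draws.shape == (64, 6)
        assert np.all(res.draws >= 0.0)
        assert np.allclose(res.draws.sum(axis=1), 1.0, atol=1e-9)

    def test_rejects_too_few_steps(self, standard_grid, one_residue_records):
        with pytest.raises(ValueError):
            monte_carlo_errors(one_residue_records, standard_grid, n_steps=1)
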
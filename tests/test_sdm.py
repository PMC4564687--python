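"""Reduced spectral density mapping: per-frequency operations and round trips."""

import math

import numpy as np
import pytest

from impactnmr.relaxation import (
    DEFAULT_CONSTANTS,
    forward_rates,
    interaction_constants,
    lorentzian_j,
    make_field_context,
)
from impactnmr.sdm import (
    HighFreqModel,
    fit_high_freq,
    j_at_wn,
    j_high,
    j_zero,
    map_dataset,
    map_residue,
)

FIVE = (400.0, 500.0, 600.0, 800.0, 1000.0)


def _forward_records(jfun, fields_mhz=FIVE, rid=1, rex=0.0):
    return [
        forward_rates(jfun, make_field_context(m), rex=rex, residue_id=rid)
        for m in fields_mhz
    ]


class TestJHigh:
    def test_zero_cross_relaxation(self):
        fc = make_field_context(600.0)
        assert j_high(1.5, 1.0, fc) == 0.0

    def test_linear_in_noe_minus_one(self):
        fc = make_field_context(600.0)
        j1 = j_high(1.5, 0.8, fc)
        j2 = j_high(1.5, 0.6, fc)
        assert j2 == pytest.approx(2.0 * j1, rel=1e-12)
        assert j1 > 0.0  # NOE < 1 with negative gammaN gives positive J

    def test_exact_for_lam_mu_truth(self):
        # rates forward-generated from J = mu/omega^2 at high frequency:
        # the recovered point equals the model value at the effective frequency
        mu = 3e8
        lam = 2e-11
        wcut = 1.5e9

        def jtruth(om):
            om = abs(float(om)) if np.isscalar(om) else np.abs(om)
            return lam + mu / np.square(np.maximum(om, wcut))

        for mhz in FIVE:
            fc = make_field_context(mhz)
            rec = forward_rates(jtruth, fc)
            got = j_high(rec.R1, rec.NOE, fc)
            assert got == pytest.approx(lam + mu / fc.omega_eff**2, rel=1e-12)

    def test_rejects_nonpositive_r1(self):
        with pytest.raises(ValueError):
            j_high(0.0, 0.8, make_field_context(600.0))


class TestFitHighFreq:
    def test_constant_j_gives_flat_model(self):
        om = np.array([m * 1e6 * 2 * math.pi * 0.87 for m in FIVE])
        hf = fit_high_freq(om, np.full(5, 3e-11))
        assert hf.lam == pytest.approx(3e-11, rel=1e-12)
        # the 1/omega^2 term contributes nothing beyond numerical rounding
        assert hf.mu / om.min() ** 2 <= 1e-12 * hf.lam

    def test_two_exact_points_interpolated(self):
        lam, mu = 5e-11, 2e8
        om = np.array([2.5e9, 5.0e9])
        hf = fit_high_freq(om, lam + mu / om**2)
        assert hf.lam == pytest.approx(lam, rel=1e-9)
        assert hf.mu == pytest.approx(mu, rel=1e-9)

    def test_matches_brute_force_constrained_ls(self):
        # oracle: coarse-to-fine grid search over (lam, mu) >= 0
        rng = np.random.default_rng(7)
        om = np.array([m * 1e6 * 2 * math.pi * 0.87 for m in FIVE])
        truth = 1e-11 + 4e8 / om**2
        sig = 0.05 * truth
        y = truth + sig * rng.standard_normal(5)
        w = 1.0 / sig**2
        hf = fit_high_freq(om, y, sig)

        def ssr(lam, mu):
            return np.sum(w * (y - lam - mu / om**2) ** 2)

        lam_grid = np.linspace(0, 5e-11, 201)
        mu_grid = np.linspace(0, 2e9, 201)
        for _ in range(4):
            vals = np.array([[ssr(l, m) for m in mu_grid] for l in lam_grid])
            i, j = np.unravel_index(np.argmin(vals), vals.shape)
            lam0, mu0 = lam_grid[i], mu_grid[j]
            dl = (lam_grid[1] - lam_grid[0]) * 2
            dm = (mu_grid[1] - mu_grid[0]) * 2
            lam_grid = np.linspace(max(lam0 - dl, 0.0), lam0 + dl, 41)
            mu_grid = np.linspace(max(mu0 - dm, 0.0), mu0 + dm, 41)
        assert ssr(hf.lam, hf.mu) <= ssr(lam0, mu0) * (1 + 1e-9)

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            fit_high_freq([2e9, 2e9], [1e-11, 2e-11])
        with pytest.raises(ValueError):
            fit_high_freq([2e9], [1e-11])


class TestJAtWn:
    def test_no_correction_limit(self):
        fc = make_field_context(800.0)
        d, c = interaction_constants(fc)
        hf0 = HighFreqModel(0.0, 0.0)
        assert j_at_wn(2.0, fc, hf0) == pytest.approx(2.0 / (0.75 * d * d + c * c), rel=1e-12)

    def test_monotone_decreasing_in_mu(self):
        fc = make_field_context(800.0)
        vals = [j_at_wn(2.0, fc, HighFreqModel(0.0, mu)) for mu in (0.0, 1e8, 2e8)]
        assert vals[0] > vals[1] > vals[2]

    def test_single_lorentzian_recovery_within_2pct(self):
        jf = lorentzian_j([7e-9], [1.0])
        recs = _forward_records(jf)
        om_eff = np.array([r.field.omega_eff for r in recs])
        jh = np.array([j_high(r.R1, r.NOE, r.field) for r in recs])
        hf = fit_high_freq(om_eff, jh)
        for r in recs:
            got = j_at_wn(r.R1, r.field, hf)
            assert got == pytest.approx(jf(r.field.omega_N), rel=0.02)


class TestJZero:
    def test_equal_etas(self):
        assert j_zero(2e-9, 1.0, 1.0) == pytest.approx(1.5e-9, rel=1e-14)

    def test_single_lorentzian_exact(self):
        # with the exact J(wN), the eta ratio returns J(0) = (2/5) tau exactly
        tau = 7e-9
        jf = lorentzian_j([tau], [1.0])
        fc = make_field_context(1000.0)
        rec = forward_rates(jf, fc)
        got = j_zero(jf(fc.omega_N), rec.eta_xy, rec.eta_z)
        assert got == pytest.approx(0.4 * tau, rel=1e-13)

    def test_guards(self):
        with pytest.raises(ValueError):
            j_zero(1e-9, 1.0, 0.0)
        with pytest.raises(ValueError, match="2 sigma"):
            j_zero(1e-9, 1.0, 0.5, sigma_eta_z=0.3)
        with pytest.raises(ValueError, match="opposite"):
            j_zero(1e-9, 1.0, -1.0)


class TestMapResidue:
    @pytest.mark.parametrize(
        "fields_mhz, expected_points",
        [(FIVE, 11), ((500.0, 600.0, 800.0), 7)],
    )
    def test_point_cardinality(self, fields_mhz, expected_points):
        recs = _forward_records(lorentzian_j([5e-9, 0.5e-9], [0.7, 0.3]), fields_mhz)
        m = map_residue(recs, n_mc=0)
        assert m.n_points == expected_points
        assert int(np.sum(m.labels == "zero")) == 1
        assert m.j0_field_mhz == max(fields_mhz)

    def test_single_field_rejected(self):
        recs = _forward_records(lorentzian_j([5e-9], [1.0]), (600.0,))
        with pytest.raises(ValueError, match=">= 2 fields"):
            map_residue(recs)

    def test_point_frequencies_span_constrained_windows(self):
        recs = _forward_records(lorentzian_j([5e-9], [1.0]))
        m = map_residue(recs, n_mc=0)
        nmhz = m.freq_mhz[m.labels == "nitrogen"]
        hmhz = m.freq_mhz[m.labels == "high"]
        assert nmhz.min() == pytest.approx(40.54, rel=1e-3)
        assert nmhz.max() == pytest.approx(101.36, rel=1e-3)
        assert hmhz.min() == pytest.approx(348.0, rel=2e-3)
        assert hmhz.max() == pytest.approx(870.0, rel=2e-3)

    @pytest.mark.parametrize(
        "taus, weights, tol",
        [
            ([8e-9, 50e-12], [0.85, 0.15], 0.02),
            ([5e-9, 0.8e-9, 30e-12], [0.6, 0.3, 0.1], 0.02),
        ],
    )
    def test_noiseless_round_trip_smooth_truths(self, taus, weights, tol):
        jf = lorentzian_j(taus, weights)
        m = map_residue(_forward_records(jf), n_mc=0)
        assert np.abs(m.J / jf(m.omega) - 1.0).max() < tol

    def test_noiseless_round_trip_exact_tail(self):
        # truth whose high-frequency tail is exactly lam + mu/omega^2:
        # the whole map is recovered to machine precision
        lam, mu, wcut = 2e-11, 3e8, 1.5e9

        def jtruth(om):
            om = np.abs(np.asarray(om, dtype=float))
            out = lam + mu / np.square(np.maximum(om, wcut))
            return float(out) if out.ndim == 0 else out

        m = map_residue(_forward_records(jtruth), n_mc=0)
        assert np.abs(m.J / jtruth(m.omega) - 1.0).max() < 1e-10

    def test_mc_sigmas_scale_linearly_with_rate_noise(self):
        from impactnmr.synthetic import NoiseSpec, engrailed_like_profile, simulate_dataset

        t1 = engrailed_like_profile(1, seed=9)
        t2 = engrailed_like_profile(1, seed=9, noise=NoiseSpec(scale=2.0))
        r1 = simulate_dataset(t1).records
        r2 = simulate_dataset(t2).records
        m1 = map_residue(r1, n_mc=510, seed=4)
        m2 = map_residue(r2, n_mc=510, seed=4)
        ratio = np.mean(m2.sigma / m1.sigma)
        assert ratio == pytest.approx(2.0, abs=0.2)

    def test_j0_field_fallback_when_eta_missing(self):
        recs = _forward_records(lorentzian_j([5e-9], [1.0]))
        recs[-1].eta_z = None  # strip eta pair at 1000 MHz
        recs[-1].eta_xy = None
        m = map_residue(recs, n_mc=0)
        assert m.j0_field_mhz == 800.0

    def test_map_dataset_excludes_unusable_residues(self):
        good = _forward_records(lorentzian_j([5e-9], [1.0]), rid=1)
        bad = _forward_records(lorentzian_j([5e-9], [1.0]), (600.0,), rid=2)
        maps, excluded = map_dataset(good + bad, n_mc=0)
        assert set(maps) == {1}
        assert 2 in excluded
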
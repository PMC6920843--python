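import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrdfit.fitting import (
    FitConfig,
    PeakDetectionError,
    PeakReport,
    RelaxationProfile,
    _model_rates,
    _seed_starts,
    analyze_profile,
    decompose,
    detect_peaks,
    fit_profile,
    quad_params_from_peaks,
    tauq_from_width,
)
from nmrdfit.models import (
    HNModelParams,
    QuadrupoleCoupling,
    angular_frequency,
    hh_total_rate,
    transition_frequencies,
)
from nmrdfit.synthetic import (
    GeneratorConfig,
    ProteinParams,
    simulate_profile,
    table1_fixtures,
    table1_uncertainties,
)


class TestRelaxationProfile:
    def test_validation(self):
        with pytest.raises(ValueError):
            RelaxationProfile(np.array([1.0, 0.5]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            RelaxationProfile(np.array([0.5, 1.0]), np.array([1.0, -1.0]))
        with pytest.raises(ValueError):
            RelaxationProfile(np.array([0.5, 1.0]), np.array([1.0]))

    def test_from_points_sorts(self):
        p = RelaxationProfile.from_points([2.0, 1.0, 3.0], [4.0, 5.0, 6.0])
        np.testing.assert_allclose(p.frequencies, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(p.rates, [5.0, 4.0, 6.0])


class TestDetectPeaks:
    def test_lysozyme_peaks_within_one_percent(self, dense_lysozyme_profile, lysozyme):
        report = detect_peaks(dense_lysozyme_profile)
        spec = transition_frequencies(lysozyme.quad)
        assert report.nu_minus_obs == pytest.approx(spec.nu_minus, rel=0.01)
        assert report.nu_plus_obs == pytest.approx(spec.nu_plus, rel=0.01)

    def test_no_peaks_without_hn_coupling(self, elastin):
        silent = ProteinParams(
            name="silent",
            hh=elastin.hh,
            hn=HNModelParams(C_HN=0.0, tau_Q=elastin.hn.tau_Q,
                             theta=elastin.hn.theta, phi=elastin.hn.phi,
                             quad=elastin.hn.quad),
        )
        profile = simulate_profile(silent, GeneratorConfig())
        with pytest.raises(PeakDetectionError, match="window"):
            detect_peaks(profile)

    def test_elastin_nu_zero_detected(self, elastin):
        config = GeneratorConfig(n_points=60, densify_factor=8, densify_window=(0.4, 3.5))
        profile = simulate_profile(elastin, config)
        report = detect_peaks(profile, window=(0.4, 3.5))
        assert report.nu_zero_obs is not None
        assert report.nu_zero_obs == pytest.approx(0.6591, rel=0.05)

    def test_sparse_window_rejected(self, elastin):
        profile = simulate_profile(
            elastin, GeneratorConfig(n_points=12, densify_factor=1)
        )
        with pytest.raises(PeakDetectionError):
            detect_peaks(profile)


class TestQuadFromPeaks:
    def test_lysozyme_inversion(self):
        report = PeakReport(nu_minus_obs=2.1672, nu_plus_obs=2.8728,
                            fwhm_minus=0.3, fwhm_plus=0.3)
        quad = quad_params_from_peaks(report)
        assert quad.a_Q == pytest.approx(3.36, rel=1e-10)
        assert quad.eta == pytest.approx(0.42, rel=1e-10)

    def test_elastin_inversion(self):
        report = PeakReport(nu_minus_obs=2.2055, nu_plus_obs=2.8645,
                            fwhm_minus=0.3, fwhm_plus=0.3)
        quad = quad_params_from_peaks(report)
        assert quad.a_Q == pytest.approx(3.38, abs=5e-3)
        assert quad.eta == pytest.approx(0.39, abs=5e-3)

    def test_symmetric_case(self):
        # degenerate peaks: tiny split to satisfy nu_+ > nu_-
        report = PeakReport(nu_minus_obs=2.55, nu_plus_obs=2.55 + 1e-9,
                            fwhm_minus=0.3, fwhm_plus=0.3)
        quad = quad_params_from_peaks(report)
        assert quad.a_Q == pytest.approx(3.4, rel=1e-6)
        assert quad.eta == pytest.approx(0.0, abs=1e-6)

    @given(a=st.floats(1.0, 6.0), eta=st.floats(0.01, 1.0))
    def test_round_trip_with_transition_frequencies(self, a, eta):
        spec = transition_frequencies(QuadrupoleCoupling(a_Q=a, eta=eta))
        report = PeakReport(nu_minus_obs=spec.nu_minus, nu_plus_obs=spec.nu_plus,
                            fwhm_minus=0.1, fwhm_plus=0.1)
        quad = quad_params_from_peaks(report)
        assert quad.a_Q == pytest.approx(a, rel=1e-9)
        assert quad.eta == pytest.approx(eta, rel=1e-6)

    def test_unphysical_eta_rejected(self):
        report = PeakReport(nu_minus_obs=0.5, nu_plus_obs=2.9,
                            fwhm_minus=0.3, fwhm_plus=0.3)
        with pytest.raises(ValueError, match="eta"):
            quad_params_from_peaks(report)


class TestTauqFromWidth:
    def test_width_lifetime_relation(self):
        report = PeakReport(nu_minus_obs=2.2, nu_plus_obs=2.9,
                            fwhm_minus=0.2675, fwhm_plus=0.2675)
        assert tauq_from_width(report) == pytest.approx(1.19e-6, rel=2e-3)

    def test_doubling_width_halves_tau(self):
        r1 = PeakReport(2.2, 2.9, 0.2, 0.2)
        r2 = PeakReport(2.2, 2.9, 0.4, 0.4)
        assert tauq_from_width(r1) == pytest.approx(2.0 * tauq_from_width(r2))

    def test_measured_width_close_to_truth(self, dense_lysozyme_profile, lysozyme):
        report = detect_peaks(dense_lysozyme_profile)
        est = tauq_from_width(report)
        assert est == pytest.approx(lysozyme.hn.tau_Q, rel=0.15)

    def test_nonpositive_width_rejected(self):
        report = PeakReport(2.2, 2.9, -0.1, 0.3)
        with pytest.raises(ValueError):
            tauq_from_width(report)


class TestFitProfile:
    def test_elastin_noiseless_recovery(self, elastin_profile):
        result = analyze_profile(elastin_profile)
        assert result.success
        assert result.hh.slow.tau == pytest.approx(2.55e-6, rel=0.02)
        assert result.hh.A == pytest.approx(6.47, rel=0.02)
        assert abs(result.hn.tau_Q / result.tau_q_init - 1.0) <= 0.10 + 1e-9

    def test_four_protein_recovery_within_printed_uncertainty(self, fixtures):
        unc = table1_uncertainties()
        for name, params in fixtures.items():
            profile = simulate_profile(params, GeneratorConfig())
            result = analyze_profile(profile)
            truth = {
                "C_s": params.hh.slow.C, "tau_s": params.hh.slow.tau,
                "C_i": params.hh.intermediate.C, "tau_i": params.hh.intermediate.tau,
                "C_f": params.hh.fast.C, "tau_f": params.hh.fast.tau,
                "A": params.hh.A, "C_HN": params.hn.C_HN,
                "tau_Q": params.hn.tau_Q, "theta": params.hn.theta,
                "phi": params.hn.phi,
            }
            got = {
                "C_s": result.hh.slow.C, "tau_s": result.hh.slow.tau,
                "C_i": result.hh.intermediate.C, "tau_i": result.hh.intermediate.tau,
                "C_f": result.hh.fast.C, "tau_f": result.hh.fast.tau,
                "A": result.hh.A, "C_HN": result.hn.C_HN,
                "tau_Q": result.hn.tau_Q, "theta": result.hn.theta,
                "phi": result.hn.phi,
            }
            for key, true_val in truth.items():
                tol = max(unc[name].get(key, 0.0), 0.05)
                assert got[key] == pytest.approx(true_val, rel=tol), (name, key)

    def test_noisy_recovery_median_within_3x_printed(self, fixtures):
        unc = table1_uncertainties()
        rel_tol = {k: 3.0 * max(v, 0.05) for name in unc for k, v in unc[name].items()}
        for name, params in fixtures.items():
            truth = {
                "tau_s": params.hh.slow.tau, "tau_i": params.hh.intermediate.tau,
                "tau_f": params.hh.fast.tau, "tau_Q": params.hn.tau_Q,
                "C_s": params.hh.slow.C, "C_i": params.hh.intermediate.C,
                "C_f": params.hh.fast.C, "C_HN": params.hn.C_HN,
            }
            errs = {k: [] for k in truth}
            for seed in range(20):
                profile = simulate_profile(
                    params, GeneratorConfig(noise_cv=0.02, seed=seed)
                )
                result = analyze_profile(profile)
                got = {
                    "tau_s": result.hh.slow.tau, "tau_i": result.hh.intermediate.tau,
                    "tau_f": result.hh.fast.tau, "tau_Q": result.hn.tau_Q,
                    "C_s": result.hh.slow.C, "C_i": result.hh.intermediate.C,
                    "C_f": result.hh.fast.C, "C_HN": result.hn.C_HN,
                }
                for k in truth:
                    errs[k].append(abs(got[k] / truth[k] - 1.0))
            for k in truth:
                tol = 3.0 * max(table1_uncertainties()[name].get(k, 0.0), 0.05)
                assert np.median(errs[k]) <= tol, (name, k, np.median(errs[k]))

    def test_pure_constant_profile(self):
        nu = np.logspace(-2, np.log10(40.0), 40)
        profile = RelaxationProfile(nu, np.full_like(nu, 2.36))
        config = FitConfig(
            quad=QuadrupoleCoupling(a_Q=3.4, eta=0.4), tau_q_init=1e-6
        )
        result = fit_profile(profile, config)
        model = (
            hh_total_rate(result.hh, angular_frequency(nu))
            - result.hh.A
        )
        assert result.hh.A == pytest.approx(2.36, rel=1e-3)
        assert np.max(model) < 1e-2  # all dispersion terms negligible
        assert result.hn.C_HN * result.hn.tau_Q * 4 < 1e-2

    def test_objective_not_worse_than_seeds(self, elastin_profile):
        report = detect_peaks(elastin_profile)
        config = FitConfig(
            quad=quad_params_from_peaks(report),
            tau_q_init=tauq_from_width(report),
            peak_report=report,
        )
        result = fit_profile(elastin_profile, config)
        omega = angular_frequency(elastin_profile.frequencies)
        spec = transition_frequencies(config.quad)
        trans = angular_frequency(np.array([spec.nu_minus, spec.nu_plus, spec.nu_zero]))
        for x0 in _seed_starts(elastin_profile, config):
            r0 = (_model_rates(x0, omega, trans) - elastin_profile.rates) / elastin_profile.rates
            assert result.cost <= 0.5 * float(r0 @ r0) + 1e-12

    def test_permutation_invariance(self, elastin_profile):
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(elastin_profile))
        shuffled = RelaxationProfile.from_points(
            elastin_profile.frequencies[perm], elastin_profile.rates[perm]
        )
        r1 = analyze_profile(elastin_profile)
        r2 = analyze_profile(shuffled)
        assert r1.hh.slow.tau == pytest.approx(r2.hh.slow.tau, rel=1e-9)
        assert r1.hn.C_HN == pytest.approx(r2.hn.C_HN, rel=1e-9)
        assert r1.cost == pytest.approx(r2.cost, rel=1e-9)

    def test_relative_error_reported(self, elastin_profile):
        result = analyze_profile(elastin_profile)
        assert 0.0 <= result.relative_error < 5.0
        assert result.relative_error == pytest.approx(
            100.0 * np.sqrt(np.mean(result.residuals**2))
        )


class TestDecompose:
    def test_components_sum_to_total(self, elastin_profile):
        result = analyze_profile(elastin_profile)
        nu = np.logspace(-2, np.log10(40), 50)
        table = decompose(result, nu)
        total = (
            table["R1_s_per_s"] + table["R1_i_per_s"] + table["R1_f_per_s"]
            + table["A_per_s"] + table["R1_HN_per_s"]
        )
        np.testing.assert_allclose(total, table["total_per_s"], rtol=1e-14)

    def test_fast_exceeds_slow_at_40MHz(self, fixtures):
        from nmrdfit.models import hh_component_rate

        omega = angular_frequency(40.0)
        for params in fixtures.values():
            fast = hh_component_rate(params.hh.fast, omega)
            slow = hh_component_rate(params.hh.slow, omega)
            assert fast > slow

    def test_hn_component_peaks_only_in_window(self, elastin_profile):
        result = analyze_profile(elastin_profile)
        nu = np.logspace(-2, np.log10(40), 600)
        table = decompose(result, nu)
        r = table["R1_HN_per_s"].to_numpy()
        interior = np.flatnonzero((r[1:-1] > r[:-2]) & (r[1:-1] > r[2:])) + 1
        assert interior.size >= 2
        assert np.all((nu[interior] > 0.5) & (nu[interior] < 3.5))
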
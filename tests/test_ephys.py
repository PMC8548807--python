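"""Sigmoid fitting, reverse transformation, opponent decomposition, PS."""

import numpy as np
import pandas as pd
import pytest

from rhabdomsim import ephys as E
from rhabdomsim import synth as S


def make_iv_run(V0, logR, n, log_levels, noise_sd=0.0, seed=0, wavelength=525.0):
    """Intensity-response run generated directly from the sigmoid formula."""
    rng = np.random.default_rng(seed)
    I = 10.0 ** np.asarray(log_levels, float)
    R = 10.0**logR
    V = V0 * I**n / (I**n + R**n) + rng.normal(0, noise_sd, len(I))
    table = pd.DataFrame(
        {
            "stimulus_wavelength_nm": wavelength,
            "polarizer_angle_deg": 0.0,
            "log10_intensity": log_levels,
            "adaptation_label": "dark",
            "injected_current_nA": 0.0,
            "response_mV": V,
        }
    )
    return E.EphysRun(table=table)


class TestIntensityResponseFit:
    def test_noiseless_recovery(self):
        run = make_iv_run(20.0, -2.5, 1.0, np.linspace(-4.5, -0.5, 8))
        fit = E.fit_intensity_response(run)
        assert fit.V0 == pytest.approx(20.0, abs=1e-6)
        assert fit.logR == pytest.approx(-2.5, abs=1e-6)
        assert fit.n == pytest.approx(1.0, abs=1e-6)
        assert fit.branch == "depolarizing"

    def test_noisy_recovery_of_measured_green_unit_parameters(self):
        # generative truth: the depolarizing unit's printed fit parameters
        run = make_iv_run(25.0, -2.51, 0.86, np.linspace(-4.5, 0, 30),
                          noise_sd=0.5, seed=42)
        fit = E.fit_intensity_response(run)
        assert fit.logR == pytest.approx(-2.51, abs=0.15)
        assert fit.n == pytest.approx(0.86, abs=0.12)
        assert fit.V0 == pytest.approx(25.0, abs=1.5)

    def test_hyperpolarizing_branch_detected(self):
        run = make_iv_run(-10.0, -1.21, 1.05, np.linspace(-3.5, 0, 10))
        fit = E.fit_intensity_response(run)
        assert fit.branch == "hyperpolarizing"
        assert fit.V0 == pytest.approx(-10.0, abs=1e-6)

    def test_exclusion_window(self):
        levels = np.linspace(-4.5, 0, 12)
        run = make_iv_run(20.0, -2.5, 1.0, levels)
        fit = E.fit_intensity_response(run, exclude_above_log=-1.0)
        assert fit.logR == pytest.approx(-2.5, abs=1e-6)

    def test_constant_responses_raise_fit_error(self):
        run = make_iv_run(20.0, -2.5, 1.0, np.linspace(-4, 0, 8))
        run.table["response_mV"] = 5.0
        with pytest.raises(E.FitError, match="constant"):
            E.fit_intensity_response(run)

    def test_too_few_levels_raise(self):
        run = make_iv_run(20.0, -2.5, 1.0, [-3, -2, -1])
        with pytest.raises(ValueError, match="4 intensity levels"):
            E.fit_intensity_response(run)


class TestReverseTransform:
    @pytest.fixture()
    def fit(self):
        return E.SigmoidFit(V0=20.0, logR=-2.5, n=0.9, rmse=0.0, branch="depolarizing")

    def test_half_max_maps_to_R(self, fit):
        I_eq = E.equivalent_intensity([10.0], fit)
        assert I_eq[0] == pytest.approx(10.0**-2.5, rel=1e-12)

    def test_small_response_maps_to_small_sensitivity(self, fit):
        est = E.response_to_sensitivity([1e-9, 10.0], fit, stimulus=[500.0, 520.0])
        assert est.sensitivity[0] == pytest.approx(0.0, abs=1e-9)

    def test_matches_bisection_oracle(self, fit):
        rng = np.random.default_rng(3)
        V = rng.uniform(0.5, 18.0, 25)

        def invert_by_bisection(v):
            lo, hi = 1e-12, 1e3
            for _ in range(200):
                mid = np.sqrt(lo * hi)
                if fit.response(mid) < v:
                    lo = mid
                else:
                    hi = mid
            return np.sqrt(lo * hi)

        oracle = np.array([invert_by_bisection(v) for v in V])
        I_eq = E.equivalent_intensity(V, fit)
        assert np.allclose(I_eq, oracle, rtol=1e-9)

    def test_round_trip_recovers_relative_intensity(self, fit):
        I = 10.0 ** np.linspace(-4, -1, 12)
        V = fit.response(I)
        est = E.response_to_sensitivity(V, fit, stimulus=I, normalize=True)
        assert np.allclose(est.sensitivity, I / I.max(), rtol=1e-9)

    def test_saturation_error(self, fit):
        with pytest.raises(E.SaturationError, match="520"):
            E.response_to_sensitivity([5.0, 21.0], fit, stimulus=[500.0, 520.0])

    def test_near_saturation_excluded_with_warning(self, fit):
        with pytest.warns(UserWarning, match="near-saturated"):
            est = E.response_to_sensitivity(
                [5.0, 19.8], fit, stimulus=[500.0, 520.0]
            )
        assert np.isnan(est.sensitivity[1])
        assert est.n_excluded_saturated == 1


class TestDecomposition:
    def test_no_hyperpolarizing_responses_give_zero_r_minus(self, argynnis_runs):
        _, runs = argynnis_runs
        fit_g = E.fit_intensity_response(runs["intensity_green"])
        green = runs["spectral_green_adapted"]
        positive = green.table.copy()
        positive["response_mV"] = np.abs(positive["response_mV"])
        dec = E.decompose_opponent(
            runs["spectral_red_adapted"],
            E.EphysRun(table=positive),
            fit_g,
            None,
        )
        assert np.all(dec.r_minus == 0)
        assert dec.g_plus.max() == pytest.approx(1.0)

    def test_component_recovery_from_synthetic_cell(self):
        cell = S.make_cell(g_peaks=(520.0,), r_peak=620.0, r_fwhm=45.0)
        protos = S.standard_protocols()
        runs = {k: S.generate_run(cell, p, seed=11 + i)
                for i, (k, p) in enumerate(protos.items())}
        fit_g = E.fit_intensity_response(runs["intensity_green"])
        fit_r = E.fit_intensity_response(runs["intensity_red"])
        dec = E.decompose_opponent(
            runs["spectral_red_adapted"], runs["spectral_green_adapted"], fit_g, fit_r
        )
        g_peak = E.fit_template_lambda_max(dec.wavelengths, dec.g_plus)
        r_peak, _ = E.fit_gaussian_peak(dec.wavelengths, dec.r_minus)
        assert g_peak == pytest.approx(520.0, abs=5.0)
        assert r_peak == pytest.approx(620.0, abs=5.0)
        assert dec.r_minus.min() < 0  # opponent component is negative-going
        assert np.abs(dec.combined).max() == pytest.approx(1.0)

    def test_gain_invariance(self, argynnis_runs):
        _, runs = argynnis_runs

        def decompose(scale):
            scaled = {}
            for key in ("intensity_green", "intensity_red",
                        "spectral_red_adapted", "spectral_green_adapted"):
                t = runs[key].table.copy()
                t["response_mV"] = t["response_mV"] * scale
                scaled[key] = E.EphysRun(table=t)
            fg = E.fit_intensity_response(scaled["intensity_green"])
            fr = E.fit_intensity_response(scaled["intensity_red"])
            return E.decompose_opponent(
                scaled["spectral_red_adapted"], scaled["spectral_green_adapted"], fg, fr
            )

        d1, d2 = decompose(1.0), decompose(3.0)
        assert np.allclose(d1.g_plus, d2.g_plus, atol=1e-6)
        assert np.allclose(d1.r_minus, d2.r_minus, atol=1e-6)


class TestPolarizationFit:
    def _ps_run(self, phi, psi, noise_sd=0.0, seed=0, reverse=False, offset=0.0):
        cell = S.make_cell(
            g_peaks=(525.0,), r_peak=None, noise_sd_mV=noise_sd
        )
        from dataclasses import replace

        cell = replace(cell, green=replace(cell.green, phi_deg=phi, psi=psi))
        proto = S.StimulusProtocol(
            "polarizer_rotation", wavelengths=(525,), log_intensity=-2.5
        )
        run = S.generate_run(cell, proto, seed=seed)
        if reverse or offset:
            t = run.table.copy()
            if reverse:
                t["polarizer_angle_deg"] = (-t["polarizer_angle_deg"]) % 360.0
            t["polarizer_angle_deg"] = t["polarizer_angle_deg"] + offset
            run = E.EphysRun(table=t)
        fit = E.fit_intensity_response(
            S.generate_run(
                cell,
                S.StimulusProtocol("intensity_series", wavelengths=(525,), n_repeats=3),
                seed=seed + 1,
            )
        )
        return run, fit

    def test_flat_run_flagged_degenerate(self):
        run, fit = self._ps_run(phi=96.0, psi=1.0)
        ps = E.fit_polarization(run, fit)
        assert ps.degenerate and ps.psi == 1.0 and ps.phi_deg is None

    def test_recovery_of_measured_red_unit_ps(self):
        run, fit = self._ps_run(phi=96.0, psi=2.0, noise_sd=0.5, seed=5)
        ps = E.fit_polarization(run, fit)
        assert ps.phi_deg == pytest.approx(96.0, abs=3.0)
        assert ps.psi == pytest.approx(2.0, abs=0.1)

    def test_phi_reported_mod_180(self):
        run, fit = self._ps_run(phi=10.0, psi=2.0)
        ps = E.fit_polarization(run, fit)
        assert 0 <= ps.phi_deg < 180
        assert ps.phi_deg == pytest.approx(10.0, abs=0.5)

    def test_invariance_to_angle_offset_and_direction(self):
        base, fit = self._ps_run(phi=40.0, psi=1.8)
        shifted, _ = self._ps_run(phi=40.0, psi=1.8, offset=360.0)
        reversed_, _ = self._ps_run(phi=40.0, psi=1.8, reverse=True)
        p0 = E.fit_polarization(base, fit)
        p1 = E.fit_polarization(shifted, fit)
        p2 = E.fit_polarization(reversed_, fit)
        assert p1.phi_deg == pytest.approx(p0.phi_deg, abs=1e-6)
        assert p1.psi == pytest.approx(p0.psi, rel=1e-9)
        assert p2.phi_deg == pytest.approx((-p0.phi_deg) % 180.0, abs=1e-6)
        assert p2.psi == pytest.approx(p0.psi, rel=1e-9)

    def test_partial_rotation_rejected(self):
        run, fit = self._ps_run(phi=96.0, psi=2.0)
        partial = E.EphysRun(table=run.table.iloc[:10].copy())
        with pytest.raises(ValueError, match="full rotation"):
            E.fit_polarization(partial, fit)


class TestSpectrumSummary:
    def test_gaussian_fwhm(self):
        wl = np.arange(400.0, 701.0)
        sigma = 21.23
        v = np.exp(-0.5 * ((wl - 620.0) / sigma) ** 2)
        summ = E.spectrum_summary(wl, v)
        assert summ.fwhm == pytest.approx(50.0, abs=0.5)
        assert summ.lambda_max == pytest.approx(620.0, abs=0.1)

    def test_dual_peaks_reported(self):
        wl = np.arange(380.0, 701.0)
        v = np.exp(-0.5 * ((wl - 465) / 25) ** 2) + 0.9 * np.exp(
            -0.5 * ((wl - 545) / 25) ** 2
        )
        summ = E.spectrum_summary(wl, v)
        assert summ.lambda_max == pytest.approx(465.0, abs=2.0)
        assert summ.secondary_peak == pytest.approx(545.0, abs=3.0)

    def test_monotone_spectrum_flags_edge(self):
        wl = np.arange(400.0, 501.0)
        summ = E.spectrum_summary(wl, np.linspace(0, 1, len(wl)))
        assert summ.edge_peak

    def test_negative_component_summarized_on_magnitude(self):
        wl = np.arange(500.0, 701.0)
        v = -np.exp(-0.5 * ((wl - 620.0) / 19.0) ** 2)
        summ = E.spectrum_summary(wl, v)
        assert summ.lambda_max == pytest.approx(620.0, abs=0.5)
        assert summ.fwhm == pytest.approx(19.0 * 2.3548, abs=0.5)
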
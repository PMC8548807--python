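"""Slab light-transport model: propagation, rates, solvers, sensitivities."""

import numpy as np
import pytest

from rhabdomsim import model as M
from rhabdomsim.spectra import find_peak
from rhabdomsim.templates import PigmentSpec, ScreeningPigmentSpec, WavelengthGrid


def _uniform_config(
    rho_receptor: float = 1.0,
    receptor: int = 2,
    depth: M.DepthGrid | None = None,
    grid: WavelengthGrid | None = None,
    source: np.ndarray | None = None,
    screening: ScreeningPigmentSpec | None = None,
) -> M.RhabdomConfig:
    """A single-absorber configuration: one receptor fills the rhabdom."""
    depth = depth or M.DepthGrid()
    grid = grid or WavelengthGrid()
    rho = np.zeros((depth.n_slabs, M.N_RECEPTORS))
    rho[:, receptor] = rho_receptor
    geometry = M.ReceptorGeometry(depth=depth, rho=rho)
    green = PigmentSpec(515.0, 495.0)
    lw = PigmentSpec(545.0, 505.0)
    return M.RhabdomConfig(
        wavelength_grid=grid,
        depth=depth,
        pigments=(green, green) + (lw,) * 7,
        screening=screening,
        geometry=geometry,
        source=source,
    )


def _monochromatic(grid: WavelengthGrid, wavelength: float) -> np.ndarray:
    src = np.zeros(len(grid))
    src[np.where(grid.wavelengths == wavelength)[0][0]] = 1.0
    return src


class TestAbsorptionCoefficients:
    def test_dark_state_full_cross_section(self):
        cfg = _uniform_config()
        kR, kM = M.absorption_coefficients(M.dark_state(cfg), cfg)
        assert np.allclose(kR[:, 2], 6.0)
        assert np.allclose(kM, 0.0)

    def test_zero_cross_section_gives_zero(self):
        cfg = _uniform_config(rho_receptor=0.0)
        kR, kM = M.absorption_coefficients(M.dark_state(cfg), cfg)
        assert np.all(kR == 0) and np.all(kM == 0)

    def test_isoform_fractions_partition_rho(self):
        cfg = M.default_config()
        rng = np.random.default_rng(0)
        f = rng.uniform(0, 1, size=(cfg.depth.n_slabs, M.N_RECEPTORS))
        kR, kM = M.absorption_coefficients(f, cfg)
        rho = cfg.resolved_geometry().rho
        assert np.allclose(kR / 6.0 + kM / 7.5, rho, atol=1e-12)

    def test_grid_mismatch_raises(self):
        cfg = M.default_config()
        with pytest.raises(ValueError, match="do not match"):
            M.absorption_coefficients(np.ones((3, 9)), cfg)


class TestPropagateFlux:
    def test_lossless_cavity(self):
        cfg = _uniform_config(rho_receptor=0.0)
        flux = M.propagate_flux(cfg)
        assert np.allclose(flux.down_in, 1.0)
        assert np.allclose(flux.up_in, 1.0)
        assert np.allclose(flux.exiting, 1.0)
        assert np.allclose(flux.actinic, 2.0)

    def test_beer_lambert_closed_form(self):
        cfg = _uniform_config(rho_receptor=1.0, receptor=2)
        flux = M.propagate_flux(cfg)
        from rhabdomsim.templates import rhodopsin_template

        gamma = rhodopsin_template(545.0, cfg.wavelength_grid).values
        expected = np.exp(-0.450 * 6.0 * gamma)  # 450 um = 0.45 mm
        assert np.allclose(flux.at_tapetum, expected, rtol=1e-10)

    def test_downwelling_never_increases_with_depth(self, default_run):
        _, _, flux, _ = default_run
        assert np.all(np.diff(flux.down_in, axis=0) <= 1e-12)

    def test_photon_bookkeeping(self, default_run):
        cfg, f_R, flux, _ = default_run
        balance = flux.absorbed + flux.exiting
        assert np.allclose(balance, flux.source, rtol=1e-6)

    def test_negative_source_rejected(self):
        grid = WavelengthGrid()
        src = -np.ones(len(grid))
        with pytest.raises(ValueError, match="non-negative"):
            _uniform_config(source=src)


class TestPhotochemicalRates:
    def test_no_light_no_conversion(self):
        grid = WavelengthGrid()
        cfg = _uniform_config(source=np.zeros(len(grid)))
        flux = M.propagate_flux(cfg)
        kR, kM = M.photochemical_rates(cfg, M.dark_state(cfg), flux)
        assert np.all(kR == 0) and np.all(kM == 0)

    def test_monochromatic_rate_ratio(self):
        grid = WavelengthGrid()
        cfg = _uniform_config(source=_monochromatic(grid, 550.0))
        f = 0.5 * np.ones((cfg.depth.n_slabs, M.N_RECEPTORS))
        flux = M.propagate_flux(cfg, f)
        kR, kM = M.photochemical_rates(cfg, f, flux)
        from rhabdomsim.templates import rhodopsin_template

        gR = rhodopsin_template(545.0, grid)(550.0)
        gM = rhodopsin_template(505.0, grid)(550.0)
        ratio = kR[:, 2] / kM[:, 2]
        assert np.allclose(ratio, (6.0 * gR) / (7.5 * gM), rtol=1e-9)

    def test_against_fine_wavelength_quadrature(self):
        coarse = _uniform_config(grid=WavelengthGrid(300, 700, 1))
        fine = _uniform_config(grid=WavelengthGrid(300, 700, 0.1))
        k = []
        for cfg in (coarse, fine):
            flux = M.propagate_flux(cfg)
            kR, _ = M.photochemical_rates(cfg, M.dark_state(cfg), flux)
            k.append(kR[:, 2])
        assert np.allclose(k[0], k[1], rtol=1e-3)


class TestEquilibrium:
    def test_single_slab_closed_form_and_intensity_invariance(self):
        grid = WavelengthGrid()
        depth = M.DepthGrid(length=5.0, dz=5.0)
        src = _monochromatic(grid, 550.0)
        cfg = _uniform_config(depth=depth, grid=grid, source=src)
        f, _, _ = M.solve_equilibrium_fixed_point(cfg, tolerance=1e-12)
        from rhabdomsim.templates import rhodopsin_template

        gR = rhodopsin_template(545.0, grid)(550.0)
        gM = rhodopsin_template(505.0, grid)(550.0)
        expected = (7.5 * gM) / (6.0 * gR + 7.5 * gM)
        assert f[0, 2] == pytest.approx(expected, abs=1e-9)

        cfg_scaled = _uniform_config(depth=depth, grid=grid, source=37.0 * src)
        f_scaled, _, _ = M.solve_equilibrium_fixed_point(cfg_scaled, tolerance=1e-12)
        assert np.allclose(f_scaled, f, atol=1e-12)

    def test_state_stays_physical(self, default_run):
        _, f_R, _, _ = default_run
        assert np.all(f_R >= 0) and np.all(f_R <= 1)

    def test_convergence_error_reports_delta(self):
        cfg = M.default_config()
        with pytest.raises(M.ConvergenceError, match="delta"):
            M.solve_equilibrium_fixed_point(cfg, tolerance=1e-9, max_iter=2)

    def test_ode_matches_fixed_point_on_reduced_model(self):
        cfg = M.default_config(depth=M.DepthGrid(length=450, dz=25))
        f_fp, _, _ = M.solve_equilibrium_fixed_point(cfg, tolerance=1e-6)
        _, traj, f_ode = M.solve_equilibrium_ode(cfg, duration=400.0)
        assert np.abs(f_ode - f_fp).max() < 0.01
        assert np.allclose(traj[0], 1.0)  # dark-adapted start

    def test_ode_constant_without_light(self):
        grid = WavelengthGrid()
        cfg = _uniform_config(
            depth=M.DepthGrid(length=50, dz=25), source=np.zeros(len(grid))
        )
        _, traj, f_end = M.solve_equilibrium_ode(cfg, duration=10.0)
        assert np.allclose(f_end, 1.0)
        assert np.allclose(traj, 1.0)


class TestSensitivity:
    def test_absent_receptor_has_zero_catch(self, default_run):
        cfg, f_R, flux, _ = default_run
        sens = M.effective_sensitivity(cfg, f_R, flux, z_range=(300.0, 350.0))
        # R1/2 vacate the rhabdom below 250 um
        assert np.all(sens.receptor("R1") == 0)
        assert sens.receptor("R3").max() > 0

    def test_r9_red_shift_requires_screening_pigment(self, default_run, nored_run):
        for run, expect_red in [(default_run, True), (nored_run, False)]:
            cfg, f_R, flux, _ = run
            sens = M.effective_sensitivity(cfg, f_R, flux)
            peak, _ = find_peak(cfg.wavelength_grid.wavelengths, sens.receptor("R9"))
            if expect_red:
                peak_red = peak
            else:
                peak_nored = peak
        assert peak_red > peak_nored

    def test_log_ratio_identity_and_pigment_dependence(self, default_run, nored_run):
        cfg, f_R, flux, _ = default_run
        sens = M.effective_sensitivity(cfg, f_R, flux)
        assert M.sensitivity_log_ratio(sens, "R1", "R1") == 0.0
        lr_red = M.sensitivity_log_ratio(sens, "R1", "R9")
        cfg0, f0, flux0, _ = nored_run
        sens0 = M.effective_sensitivity(cfg0, f0, flux0)
        lr_nored = M.sensitivity_log_ratio(sens0, "R1", "R9")
        assert abs(lr_nored) < abs(lr_red)

    def test_slab_refinement_stability(self):
        spectra = {}
        for dz in (5.0, 2.5):
            cfg = M.default_config(depth=M.DepthGrid(dz=dz))
            f, flux, _ = M.solve_equilibrium_fixed_point(cfg, tolerance=1e-5)
            spectra[dz] = M.effective_sensitivity(cfg, f, flux).normalized
        assert np.abs(spectra[5.0] - spectra[2.5]).max() < 0.01

    def test_receptor_permutation_invariance(self):
        cfg = M.default_config()
        perm = [4, 1, 2, 3, 0, 5, 6, 7, 8]  # swap R1 and R5
        geom = cfg.resolved_geometry()
        cfg_p = M.RhabdomConfig(
            wavelength_grid=cfg.wavelength_grid,
            depth=cfg.depth,
            pigments=tuple(cfg.pigments[i] for i in perm),
            screening=cfg.screening,
            geometry=M.ReceptorGeometry(depth=cfg.depth, rho=geom.rho[:, perm]),
        )
        out, out_p = [], []
        for c in (cfg, cfg_p):
            f, flux, _ = M.solve_equilibrium_fixed_point(c)
            out.append(M.effective_sensitivity(c, f, flux).quantum_catch)
        assert np.allclose(out[0][perm], out[1], atol=1e-12)


class TestEyeshine:
    def test_flat_for_lossless_cavity(self):
        cfg = _uniform_config(rho_receptor=0.0)
        _, refl = M.eyeshine_spectrum(M.propagate_flux(cfg))
        assert np.allclose(refl, 1.0)

    def test_red_dominates_default_model(self, default_run):
        cfg, _, flux, _ = default_run
        wl, refl = M.eyeshine_spectrum(flux)
        assert refl[wl == 650][0] > refl[wl == 500][0]

    def test_monotone_in_screening_density(self):
        values = []
        for alpha_S in (0.0, 10.0, 20.0):
            cfg = M.default_config(alpha_S=alpha_S)
            f, flux, _ = M.solve_equilibrium_fixed_point(cfg)
            wl, refl = M.eyeshine_spectrum(flux)
            values.append(refl[wl == 500][0])
        assert values[0] >= values[1] >= values[2]


def test_perturbed_geometry_stays_valid():
    rng = np.random.default_rng(7)
    geom = M.default_geometry()
    pert = M.perturb_geometry(geom, 0.10, rng)
    assert np.all(pert.rho >= 0)
    assert np.all(pert.rho.sum(axis=1) <= 1 + 1e-9)
    assert not np.allclose(pert.rho, geom.rho)
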
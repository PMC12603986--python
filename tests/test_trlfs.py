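"""Luminescence forward model, deconvolution pipeline and binding-constant fit."""

from __future__ import annotations

import math

import numpy as np
import pytest

import lanthafit as lf
from lanthafit.errors import CalibrationError, InputError
from lanthafit.synthetic import (PRESETS, default_delays, default_photophysics,
                                 default_wavelengths)
from lanthafit.trlfs import _fit_monoexp, project_onto_basis

UM = 1e-6


class TestNormalizeSpectrum:
    def test_idempotent_and_scale_invariant(self):
        wl = default_wavelengths()
        spec = np.exp(-0.5 * ((wl - 592) / 3.0) ** 2)
        once = lf.normalize_spectrum(spec, wl)
        assert np.allclose(lf.normalize_spectrum(once, wl), once)
        assert np.allclose(lf.normalize_spectrum(7.0 * spec, wl), once)

    def test_boxcar_analytic_integral(self):
        wl = np.arange(570.0, 640.5, 0.5)
        spec = np.where((wl >= 588) & (wl <= 598), 2.0, 0.0)
        out = lf.normalize_spectrum(spec, wl, band=(588.0, 598.0))
        # integral = height x width = 2 x 10 = 20 -> scaled by 1/20
        assert out.max() == pytest.approx(2.0 / 20.0)

    def test_errors(self):
        wl = np.arange(570.0, 640.5, 0.5)
        with pytest.raises(InputError):
            lf.normalize_spectrum(np.zeros_like(wl), wl)
        with pytest.raises(InputError):
            lf.normalize_spectrum(np.ones(10), np.linspace(600, 640, 10))


class TestSimulateTRLFS:
    def test_single_species_single_step_is_rank_one(self):
        wl, delays = default_wavelengths(), default_delays()
        photo = default_photophysics(PRESETS["EF1-R"], wl)[:1]
        state = lf.solve_speciation(
            lf.MixtureComposition(l_tot=0.0, m_tot=10 * UM),
            lf.BindingModel(0.5 * UM, 1.1 * UM))
        data = lf.simulate_trlfs([state], photo, wl, delays)
        x = data.intensity[0]
        s = np.linalg.svd(x, compute_uv=False)
        assert s[1] <= 1e-10 * s[0]

    def test_noiseless_reconstruction_identity(self):
        wl, delays = default_wavelengths(), default_delays()
        photo = default_photophysics(PRESETS["EF1-R"], wl)
        model = lf.BindingModel(0.5 * UM, 1.1 * UM)
        comps = [lf.MixtureComposition(l_tot=l * UM, m_tot=10 * UM)
                 for l in (0, 5, 20)]
        states = [lf.solve_speciation(c, model) for c in comps]
        data = lf.simulate_trlfs(states, photo, wl, delays)
        conc = np.array([s.eu_species() for s in states])
        amps = conc * [p.brightness for p in photo]
        spectra = np.stack([p.spectrum for p in photo], axis=1)
        decays = np.stack([np.exp(-delays / p.lifetime_us) for p in photo], axis=1)
        recon = np.einsum("ir,jr,kr->ijk", amps, spectra, decays)
        assert np.allclose(data.intensity, recon, rtol=0, atol=1e-12)

    def test_decay_reaches_inverse_e_at_one_lifetime(self):
        """Intensity at t = tau is e^-1 of the t = 0 value, per species."""
        wl = default_wavelengths()
        delays = np.array([0.0, 204.0, 408.0])
        photo = default_photophysics(PRESETS["EF1-R"], wl)[1:2]  # 204 µs species
        state = lf.solve_speciation(
            lf.MixtureComposition(l_tot=50 * UM, m_tot=10 * UM),
            lf.BindingModel(0.5 * UM, 1.1 * UM))
        data = lf.simulate_trlfs([state], photo, wl, delays)
        peak = np.argmax(data.intensity[0, :, 0])
        ratio = data.intensity[0, peak, 1] / data.intensity[0, peak, 0]
        assert ratio == pytest.approx(math.exp(-1), rel=1e-12)

    def test_seeded_noise_is_reproducible(self):
        wl, delays = default_wavelengths(), default_delays()
        photo = default_photophysics(PRESETS["EF1-R"], wl)
        state = lf.solve_speciation(
            lf.MixtureComposition(l_tot=10 * UM, m_tot=10 * UM),
            lf.BindingModel(0.5 * UM, 1.1 * UM))
        d1 = lf.simulate_trlfs([state], photo, wl, delays, noise=0.01, seed=3)
        d2 = lf.simulate_trlfs([state], photo, wl, delays, noise=0.01, seed=3)
        assert np.array_equal(d1.intensity, d2.intensity)


class TestExtractLifetimes:
    @pytest.mark.parametrize("tau", [204.0, 134.0])
    def test_exact_exponential_recovered(self, tau):
        t = default_delays()
        res = _fit_monoexp(t, np.exp(-t / tau))
        assert res.tau_us == pytest.approx(tau, rel=1e-8)
        assert not res.unphysical

    def test_noisy_lifetime_within_five_percent(self, rng):
        t = np.linspace(0, 1000, 30)
        y = np.exp(-t / 150.0) * (1 + rng.normal(0, 0.02, t.size))
        res = _fit_monoexp(t, np.clip(y, 0, None))
        assert res.tau_us == pytest.approx(150.0, rel=0.05)

    def test_non_decaying_mode_flagged(self):
        t = np.linspace(0, 100, 20)
        res = _fit_monoexp(t, np.linspace(1.0, 2.0, 20))
        assert res.unphysical
        assert math.isinf(res.tau_us)

    def test_pipeline_lifetime_ordering(self, ef1r_fit):
        """Canonical order: 1:1 (slowest) > 1:2 > aquo (most quenched)."""
        taus = ef1r_fit.lifetimes_us
        assert taus[0] > taus[1] > taus[2]
        results = lf.extract_lifetimes(ef1r_fit)
        assert [r.tau_us for r in results] == pytest.approx(list(taus), rel=1e-6)


class TestCalibration:
    def test_aquo_only_steps_carry_total_metal(self):
        wl, delays = default_wavelengths(), default_delays()
        photo = default_photophysics(PRESETS["EF1-R"], wl)[:1]
        model = lf.BindingModel(0.5 * UM, 1.1 * UM)
        comps = [lf.MixtureComposition(l_tot=0.0, m_tot=m * UM)
                 for m in (5, 10, 20, 40, 60, 80)]
        states = [lf.solve_speciation(c, model) for c in comps]
        data = lf.simulate_trlfs(states, photo, wl, delays)
        fit = lf.fit_parafac(data, 1, n_restarts=2)
        calib = lf.calibrate_concentrations(fit, comps)
        assert calib.concentrations[:, 0] == pytest.approx(
            [c.m_tot for c in comps], rel=1e-6)

    def test_brightness_rescaling_leaves_concentrations_unchanged(self):
        from dataclasses import replace
        wl, delays = default_wavelengths(), default_delays()
        model = lf.BindingModel(0.5 * UM, 1.1 * UM)
        comps = [lf.MixtureComposition(l_tot=l * UM, m_tot=10 * UM)
                 for l in (0, 2, 5, 10, 20, 40)]
        states = [lf.solve_speciation(c, model) for c in comps]
        out = []
        for factor in (1.0, 2.0):
            photo = [replace(p, brightness=p.brightness * factor)
                     for p in default_photophysics(PRESETS["EF1-R"], wl)]
            data = lf.simulate_trlfs(states, photo, wl, delays)
            fit = lf.fit_parafac(data, 3, n_restarts=4)
            out.append(lf.calibrate_concentrations(fit, comps).concentrations)
        a, b = out
        perm = [int(np.argmin([np.abs(a[:, i] - b[:, j]).sum() for j in range(3)]))
                for i in range(3)]
        assert np.allclose(a, b[:, perm], rtol=1e-4, atol=1e-12)

    def test_three_species_recovery_within_3_percent_rms(self):
        """Calibrated profiles track the generating speciation at modest noise."""
        data, truth = lf.generate_trlfs_scenario("EF1-R", seed=8, noise=0.002)
        fit = lf.fit_parafac(data, 3, init_seed=8, n_restarts=6)
        calib = lf.calibrate_concentrations(fit, data.compositions)
        # canonical order is descending lifetime = (1:1, 1:2, aquo)
        est = calib.concentrations[:, [2, 0, 1]]
        rms = np.sqrt(np.mean((est - truth["concentrations"]) ** 2))
        assert rms <= 0.03 * np.mean(data.m_tot())

    def test_noiseless_closure_below_one_percent(self, ef1r_noiseless):
        data, _ = ef1r_noiseless
        fit = lf.fit_parafac(data, 3, n_restarts=4)
        calib = lf.calibrate_concentrations(fit, data.compositions)
        assert calib.closure_residuals.max() <= 0.01

    def test_gross_mismatch_raises_calibration_error(self, ef1r_fit):
        wrong = [lf.MixtureComposition(l_tot=0.0, m_tot=(1 + 5 * (i % 2)) * UM)
                 for i in range(ef1r_fit.concentration_loadings.shape[0])]
        with pytest.raises(CalibrationError):
            lf.calibrate_concentrations(ef1r_fit, wrong)


class TestFitBindingConstants:
    def test_noiseless_profiles_recover_exactly(self, ef1r_noiseless):
        data, truth = ef1r_noiseless
        res = lf.fit_binding_constants(truth["concentrations"], data.compositions)
        assert res.model.kd_11 == pytest.approx(truth["kd_11"], rel=1e-3)
        assert res.model.kd_12 == pytest.approx(truth["kd_12"], rel=1e-3)
        assert not res.warning_large_residual

    def test_one_to_one_truth_gives_negligible_second_complex(self):
        model = lf.BindingModel(8.6 * UM)  # 1:1-only binder
        comps = [lf.MixtureComposition(l_tot=l * UM, m_tot=10 * UM)
                 for l in (0, 2, 5, 10, 20, 40, 60)]
        comps += [lf.MixtureComposition(l_tot=10 * UM, m_tot=m * UM)
                  for m in (20, 40, 80)]
        prof = np.array([lf.solve_speciation(c, model).eu_species() for c in comps])
        res = lf.fit_binding_constants(prof, comps, two_step=True)
        pred_lm = res.predicted[:, 1]
        pred_lm2 = res.predicted[:, 2] / 2.0   # metal-ion basis -> complex
        mask = pred_lm > 1e-9
        assert np.all(pred_lm2[mask] < 0.01 * pred_lm[mask])

    def test_optimizer_agrees_with_grid_oracle(self, ef1r_noiseless, rng):
        data, truth = ef1r_noiseless
        prof = truth["concentrations"] + rng.normal(0, 0.2 * UM,
                                                    truth["concentrations"].shape)
        res = lf.fit_binding_constants(prof, data.compositions,
                                       assignment=(0, 1, 2))
        # coarse 50x50 log-spaced grid oracle
        m_tot = data.m_tot()
        def rss(k1, k2):
            mo = lf.BindingModel(k1, k2)
            pred = np.array([lf.solve_speciation(c, mo).eu_species()
                             for c in data.compositions])
            return float(np.sum(((pred - prof) / np.mean(m_tot)) ** 2))
        grid = np.logspace(-8, -4, 50)
        best = min(((rss(k1, k2), k1, k2) for k1 in grid for k2 in grid))
        assert rss(res.model.kd_11, res.model.kd_12) <= best[0] * (1 + 1e-6)
        # optimizer lands within one grid cell of the oracle minimum
        assert abs(math.log10(res.model.kd_11 / best[1])) <= 4 / 49
        assert abs(math.log10(res.model.kd_12 / best[2])) <= 4 / 49

    def test_refinement_recovers_generating_constants(self, ef1r_scenario,
                                                      ef1r_binding):
        _, truth = ef1r_scenario
        assert ef1r_binding.refined
        assert ef1r_binding.model.kd_11 == pytest.approx(truth["kd_11"], rel=0.10)
        assert ef1r_binding.model.kd_12 == pytest.approx(truth["kd_12"], rel=0.10)
        # refined speciation satisfies metal closure exactly
        m_tot = np.array([c.m_tot for c in ef1r_scenario[0].compositions])
        closure = ef1r_binding.predicted.sum(axis=1) - m_tot
        assert np.all(np.abs(closure) <= 1e-8 * m_tot)


class TestEndToEnd:
    def test_als_trace_monotone_on_study_tensor(self, ef1r_fit):
        trace = ef1r_fit.residual_trace
        assert np.all(np.diff(trace) <= 1e-9 * trace[:-1] + 1e-15)

    def test_noiseless_full_pipeline_recovers_truth(self, ef1r_noiseless):
        data, truth = ef1r_noiseless
        fit = lf.fit_parafac(data, 3, n_restarts=4)
        calib = lf.calibrate_concentrations(fit, data.compositions)
        res = lf.fit_binding_constants(calib, data.compositions, refine_with=data)
        assert res.model.kd_11 == pytest.approx(truth["kd_11"], rel=1e-3)
        assert res.model.kd_12 == pytest.approx(truth["kd_12"], rel=1e-3)
        assert res.lifetimes_us == pytest.approx(truth["lifetimes_us"], rel=1e-4)

    def test_projection_of_noiseless_sample_returns_exact_speciation(
            self, ef1r_noiseless):
        data, truth = ef1r_noiseless
        fit = lf.fit_parafac(data, 3, n_restarts=4)
        calib = lf.calibrate_concentrations(fit, data.compositions)
        binding = lf.fit_binding_constants(calib, data.compositions,
                                           refine_with=data)
        basis = lf.competition_basis(data, binding)
        amps, rel = project_onto_basis(data.intensity[5], basis.fit)
        with np.errstate(divide="ignore"):
            conc = amps / basis.brightness
        want = truth["concentrations"][5]
        assert conc == pytest.approx(want, rel=1e-6, abs=1e-12)
        assert rel < 1e-6
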
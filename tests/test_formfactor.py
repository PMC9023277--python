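"""Debye-equation scattering, model Rg and the (r0, delta_rho) grid search."""

import numpy as np
import pytest

import quadstack as qs
from quadstack.errors import InputError, ParameterError, RangeError


def point_model(coords, z=1.0):
    coords = np.asarray(coords, float)
    n = len(coords)
    return qs.AtomicModel(("X",) * n, coords, np.full(n, z), np.zeros(n))


class TestDebyeIntensity:
    def test_two_point_closed_form(self):
        d = 10.0
        m = point_model([[0, 0, 0], [0, 0, d]])
        q = np.linspace(0.01, 1.0, 80)
        prof = qs.debye_intensity(m, q, delta_rho=0.0, solvent_density=0.0)
        expect = 2.0 * (1.0 + np.sin(q * d) / (q * d))
        assert np.allclose(prof.intensity, expect, atol=1e-12)

    def test_single_atom_monotone(self):
        """In-vacuo single-atom intensity f(q)^2 decays monotonically."""
        m = qs.AtomicModel(("C",), np.zeros((1, 3)), np.array([6.0]), np.array([16.44]))
        q = np.linspace(0.01, 1.0, 100)
        prof = qs.debye_intensity(
            m, q, delta_rho=0.0, solvent_density=0.0, form_factors="cromer-mann"
        )
        assert np.all(np.diff(prof.intensity) <= 1e-12)

    def test_sphere_cloud_first_minimum(self):
        """500-point sphere reproduces the 4.493/R form-factor minimum."""
        from scipy.signal import argrelmin

        R = 30.0
        m = qs.make_sphere_model(R, 500, seed=2)
        q = np.linspace(0.02, 0.25, 300)
        prof = qs.debye_intensity(m, q, delta_rho=0.0, solvent_density=0.0)
        mins = argrelmin(prof.intensity)[0]
        assert len(mins) >= 1
        assert q[mins[0]] * R == pytest.approx(4.493, rel=0.02)

    def test_rotation_translation_invariance(self):
        rng = np.random.default_rng(9)
        m = qs.make_tetrad_stack_model(3)
        # random rotation via QR
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        m2 = m.transformed(rotation=Q, translation=[5.0, -3.0, 12.0])
        q = np.linspace(0.01, 0.4, 60)
        i1 = qs.debye_intensity(m, q, delta_rho=0.0).intensity
        i2 = qs.debye_intensity(m2, q, delta_rho=0.0).intensity
        assert np.allclose(i1, i2, rtol=1e-9)

    def test_i0_is_squared_amplitude_sum(self):
        m = qs.make_tetrad_stack_model(2)
        q = np.array([1e-6, 0.01])
        prof = qs.debye_intensity(m, q, r0=0.162, delta_rho=0.0)
        # at q -> 0 every f_i -> Z_i - rho_s V_i
        f0 = m.electrons - 0.3368 * m.volumes
        assert prof.intensity[0] == pytest.approx(float(np.sum(f0) ** 2), rel=1e-8)

    def test_unknown_element_rejected(self):
        with pytest.raises(InputError):
            qs.AtomicModel.from_elements(["Zz"], [[0, 0, 0]])

    def test_empty_q_grid(self):
        m = qs.make_tetrad_stack_model(1)
        with pytest.raises(ParameterError):
            qs.debye_intensity(m, np.array([]))


class TestModelRg:
    def test_matches_direct_second_moment(self):
        m = qs.make_sphere_model(30.0, 400, seed=5)
        com = m.coords.mean(axis=0)
        rg_direct = np.sqrt(np.mean(np.sum((m.coords - com) ** 2, axis=1)))
        rg = qs.model_rg(m, delta_rho=0.0)
        assert rg == pytest.approx(rg_direct, rel=0.005)

    def test_sphere_cloud_rg(self):
        """Cloud Rg agrees with its own second moment (tight) and with the
        continuum sqrt(3/5) R (up to finite-sample fluctuation)."""
        m = qs.make_sphere_model(30.0, 2000, seed=6)
        com = m.coords.mean(axis=0)
        rg_direct = np.sqrt(np.mean(np.sum((m.coords - com) ** 2, axis=1)))
        rg = qs.model_rg(m, delta_rho=0.0)
        assert rg == pytest.approx(rg_direct, rel=0.005)
        assert rg == pytest.approx(np.sqrt(3 / 5) * 30.0, rel=0.02)

    def test_hydration_shell_increases_rg(self, tetrad_model):
        assert qs.model_rg(tetrad_model, delta_rho=30.0) > qs.model_rg(tetrad_model, delta_rho=0.0)


class TestChi2:
    def _prof(self, q, i, s):
        return qs.ScatteringProfile(q, i, s)

    def test_perfect_scaled_fit(self):
        q = np.linspace(0.01, 0.3, 50)
        calc = self._prof(q, np.exp(-q * 3), np.ones(50))
        exp = self._prof(q, 2.5 * np.exp(-q * 3), np.ones(50))
        chi2, c = qs.chi2_reduced(calc, exp)
        assert chi2 == pytest.approx(0.0, abs=1e-20)
        assert c == pytest.approx(2.5)

    def test_unit_residual_definition(self):
        q = np.linspace(0.01, 0.3, 50)
        base = np.exp(-q * 3)
        calc = self._prof(q, base, np.ones(50))
        exp = self._prof(q, base + 0.05, np.full(50, 0.05))
        chi2, c = qs.chi2_reduced(calc, exp, scale_mode="fixed")
        assert chi2 == pytest.approx(1.0)

    def test_gaussian_residual_statistics(self):
        rng = np.random.default_rng(12)
        q = np.linspace(0.01, 0.3, 1000)
        base = 10 * np.exp(-q * 5)
        sigma = 0.02 * base
        vals = []
        for seed in range(8):
            noisy = base + np.random.default_rng(seed).normal(0, 1, 1000) * sigma
            chi2, _ = qs.chi2_reduced(self._prof(q, base, np.ones(1000)), self._prof(q, noisy, sigma))
            vals.append(chi2)
        assert np.mean(vals) == pytest.approx(1.0, abs=0.05)

    def test_grid_span_enforced(self):
        calc = self._prof(np.linspace(0.05, 0.2, 30), np.ones(30), np.ones(30))
        exp = self._prof(np.linspace(0.01, 0.3, 30), np.ones(30), np.ones(30))
        with pytest.raises(RangeError):
            qs.chi2_reduced(calc, exp)


class TestGridSearchFit:
    def test_self_recovery_noise_free_chi2_zero(self, tetrad_model):
        q = np.linspace(0.01, 0.3, 60)
        clean = qs.debye_intensity(tetrad_model, q, r0=0.162, delta_rho=30.0)
        exp = qs.ScatteringProfile(q, clean.intensity, 0.02 * np.abs(clean.intensity))
        fit = qs.fit_model_to_scattering(tetrad_model, exp)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-16)
        assert fit.r0 == pytest.approx(0.162)
        assert fit.delta_rho == pytest.approx(30.0)
        assert fit.scale_c == pytest.approx(1.0)

    def test_zero_hydration_boundary(self, tetrad_model):
        q = np.linspace(0.01, 0.3, 60)
        clean = qs.debye_intensity(tetrad_model, q, r0=0.162, delta_rho=0.0)
        exp = qs.ScatteringProfile(q, clean.intensity, 0.02 * np.abs(clean.intensity))
        fit = qs.fit_model_to_scattering(tetrad_model, exp)
        assert fit.delta_rho == 0.0

    def test_grid_minimum_beats_default(self, tetrad_model):
        """The searched minimum is never worse than the default-parameter fit."""
        q = np.linspace(0.01, 0.3, 80)
        clean = qs.debye_intensity(tetrad_model, q, r0=0.156, delta_rho=55.0)
        exp = qs.apply_noise(q, clean.intensity, 0.02, seed=3)
        fit = qs.fit_model_to_scattering(tetrad_model, exp)
        from quadstack.formfactor import DebyeEvaluator

        ev = DebyeEvaluator(tetrad_model, exp.q)
        default_prof = qs.ScatteringProfile(exp.q, ev.intensity(0.162, 30.0), exp.sigma)
        chi_default, _ = qs.chi2_reduced(default_prof, exp)
        assert fit.chi2 <= chi_default + 1e-12

    def test_model_discrimination(self, tetrad_model):
        q = np.linspace(0.01, 0.3, 80)
        clean = qs.debye_intensity(tetrad_model, q, r0=0.162, delta_rho=30.0)
        exp = qs.apply_noise(q, clean.intensity, 0.02, seed=21)
        decoy = qs.AtomicModel(
            tetrad_model.elements,
            tetrad_model.coords * 1.2,
            tetrad_model.electrons,
            tetrad_model.volumes,
        )
        fit_true = qs.fit_model_to_scattering(tetrad_model, exp)
        fit_decoy = qs.fit_model_to_scattering(decoy, exp)
        assert fit_true.chi2 < fit_decoy.chi2

    def test_refinement_never_hurts(self, tetrad_model):
        q = np.linspace(0.01, 0.3, 80)
        clean = qs.debye_intensity(tetrad_model, q, r0=0.162, delta_rho=30.0)
        exp = qs.apply_noise(q, clean.intensity, 0.02, seed=8)
        coarse = qs.fit_model_to_scattering(tetrad_model, exp, refine=False)
        fine = qs.fit_model_to_scattering(tetrad_model, exp, refine=True)
        assert fine.chi2 <= coarse.chi2 + 1e-12


class TestBestFrame:
    def test_identical_frames_tie_break(self, tetrad_model):
        q = np.linspace(0.01, 0.3, 40)
        clean = qs.debye_intensity(tetrad_model, q, r0=0.162, delta_rho=30.0)
        exp = qs.ScatteringProfile(q, clean.intensity, 0.02 * np.abs(clean.intensity))
        idx, fit = qs.best_frame_over_trajectory([tetrad_model, tetrad_model], exp)
        assert idx == 0

    def test_generating_frame_wins(self, tetrad_model):
        q = np.linspace(0.01, 0.3, 60)
        clean = qs.debye_intensity(tetrad_model, q, r0=0.162, delta_rho=30.0)
        exp = qs.apply_noise(q, clean.intensity, 0.02, seed=5)
        frames = [
            qs.AtomicModel(
                tetrad_model.elements, tetrad_model.coords * s, tetrad_model.electrons, tetrad_model.volumes
            )
            for s in (1.3, 1.0, 0.8)
        ]
        idx, fit = qs.best_frame_over_trajectory(frames, exp)
        assert idx == 1

    def test_empty_list_errors(self):
        q = np.linspace(0.01, 0.3, 20)
        exp = qs.ScatteringProfile(q, np.ones(20), np.ones(20))
        with pytest.raises(ParameterError):
            qs.best_frame_over_trajectory([], exp)
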
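"""Prony kernel, trapezoidal loading, hereditary-integral stress."""

import math

import numpy as np
import pytest

from axonve.presets import AXON_CORE_PRONY_MEANS, default_core_matrix
from axonve.viscoelastic import (
    LOAD_CASES,
    OrthotropicRelaxationMatrix,
    PronyRelaxation,
    TimeSeries,
    TrapezoidalLoading,
    orthotropic_response,
    prony_eval,
    ramp_stress,
    stress_closed_form,
    stress_convolution,
    trapezoid_strain,
)

from conftest import random_admissible_prony, trapezoid_convolution_oracle

C33 = PronyRelaxation(1601.38e3, ((0.19, 19.27e-3), (0.75, 23.84e-3)))
LOADING = TrapezoidalLoading(eps_star=0.003)


class TestPronyKernel:
    def test_short_and_long_term_limits(self):
        p = C33
        assert prony_eval(p, 0.0) == pytest.approx(p.C0)
        assert prony_eval(p, 1e3) == pytest.approx(p.C0 * (1 - 0.19 - 0.75))

    def test_axial_modulus_at_20ms_matches_spreadsheet_arithmetic(self):
        # independent re-computation with scalar math
        t = 20e-3
        expected = 1601.38e3 * (
            1.0
            - 0.19 * (1.0 - math.exp(-t / 19.27e-3))
            - 0.75 * (1.0 - math.exp(-t / 23.84e-3))
        )
        assert prony_eval(C33, t) == pytest.approx(expected, rel=1e-14)

    def test_monotone_nonincreasing_and_convex(self, rng):
        t = np.linspace(0.0, 0.1, 400)
        for _ in range(20):
            p = random_admissible_prony(rng)
            c = prony_eval(p, t)
            assert np.all(np.diff(c) <= 1e-12 * p.C0)
            assert np.all(np.diff(c, 2) >= -1e-9 * p.C0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            prony_eval(C33, -1e-6)

    @pytest.mark.parametrize(
        "c0, terms",
        [
            (-1.0, ()),
            (1.0, ((-0.1, 1e-3),)),
            (1.0, ((0.6, 1e-3), (0.5, 2e-3))),
            (1.0, ((0.5, 0.0),)),
        ],
    )
    def test_thermodynamic_admissibility_enforced(self, c0, terms):
        with pytest.raises(ValueError):
            PronyRelaxation(c0, terms)


class TestTrapezoidalLoading:
    def test_ramp_midpoint_and_plateau(self):
        eps, rate = trapezoid_strain(LOADING, 1.5e-3)
        assert eps == pytest.approx(LOADING.eps_star / 2)
        assert rate == pytest.approx(LOADING.eps_star / 3e-3)
        eps, rate = trapezoid_strain(LOADING, 8e-3)
        assert (eps, rate) == (LOADING.eps_star, 0.0)

    def test_recovery_phase_is_zero(self):
        eps, rate = trapezoid_strain(LOADING, 30e-3)
        assert (eps, rate) == (0.0, 0.0)

    def test_strain_continuous_at_phase_boundaries(self):
        for tk in (3e-3, 12e-3, 15e-3):
            lo = trapezoid_strain(LOADING, tk - 1e-12)[0]
            hi = trapezoid_strain(LOADING, tk + 1e-12)[0]
            assert lo == pytest.approx(hi, abs=1e-11)

    def test_outside_window_rejected(self):
        with pytest.raises(ValueError):
            trapezoid_strain(LOADING, 41e-3)

    def test_plateau_strain_from_geometry(self):
        # 3 nm displacement on the axial box dimension 2L = 1000 nm
        from axonve.synthetic import SyntheticConfig

        cfg = SyntheticConfig()
        assert cfg.loading(3).eps_star == pytest.approx(0.003)
        assert cfg.loading(1).eps_star == pytest.approx(3.0 / 45.0)

    def test_misordered_times_rejected(self):
        with pytest.raises(ValueError):
            TrapezoidalLoading(0.01, t1=5e-3, t2=4e-3)


class TestStressClosedForm:
    def test_elastic_limit_tracks_strain(self):
        p = PronyRelaxation(2.0e5, ())
        t = np.linspace(0.0, 40e-3, 200)
        eps, _ = trapezoid_strain(LOADING, t)
        np.testing.assert_allclose(stress_closed_form(p, LOADING, t),
                                   p.C0 * eps, rtol=1e-12, atol=1e-9)

    def test_extended_hold_relaxes_to_long_term(self):
        slow = TrapezoidalLoading(0.003, t2=5.0, t3=5.003, t4=6.0)
        sigma = stress_closed_form(C33, slow, 5.0)
        assert sigma == pytest.approx(C33.long_term * 0.003, rel=1e-4)

    def test_continuous_across_phase_boundaries(self):
        for tk in (3e-3, 12e-3, 15e-3):
            lo = stress_closed_form(C33, LOADING, tk - 1e-12)
            hi = stress_closed_form(C33, LOADING, tk + 1e-12)
            assert lo == pytest.approx(hi, rel=1e-9)

    def test_residual_stress_decays_after_unload(self):
        long_rec = TrapezoidalLoading(0.003, t4=1.0)
        t = np.linspace(16e-3, 1.0, 100)
        sigma = stress_closed_form(C33, long_rec, t)
        assert abs(sigma[-1]) < 1e-6 * abs(sigma[0])

    def test_axial_response_matches_convolution_oracle(self):
        oracle = trapezoid_convolution_oracle(
            C33, lambda u: trapezoid_strain(LOADING, u)[0], [12e-3])
        assert stress_closed_form(C33, LOADING, 12e-3) == pytest.approx(
            oracle[0], rel=1e-3)

    def test_random_models_match_convolution_oracle(self, rng):
        t_eval = np.array([1e-3, 3e-3, 7e-3, 12e-3, 13.5e-3, 20e-3, 39e-3])
        for _ in range(10):
            p = random_admissible_prony(rng)
            closed = stress_closed_form(p, LOADING, t_eval)
            oracle = trapezoid_convolution_oracle(
                p, lambda u: trapezoid_strain(LOADING, u)[0], t_eval)
            scale = np.max(np.abs(closed))
            np.testing.assert_allclose(closed, oracle, atol=1e-3 * scale)


class TestStressConvolution:
    def test_zero_strain_gives_zero_stress(self):
        eh = TimeSeries(np.linspace(0, 0.04, 50), np.zeros(50))
        assert np.all(stress_convolution(C33, eh).values == 0.0)

    def test_linearity_in_strain_amplitude(self, rng):
        t = np.linspace(0, 0.04, 80)
        eps = np.concatenate([[0.0], np.cumsum(rng.normal(0, 1e-4, 79))])
        p = random_admissible_prony(rng)
        one = stress_convolution(p, TimeSeries(t, eps)).values
        three = stress_convolution(p, TimeSeries(t, 3.0 * eps)).values
        np.testing.assert_allclose(three, 3.0 * one, rtol=1e-12)

    def test_boltzmann_superposition_of_delayed_ramps(self, rng):
        t = np.linspace(0, 0.05, 501)
        ramp_a = np.clip(t / 0.01, 0.0, 1.0) * 0.002
        ramp_b = np.clip((t - 0.02) / 0.01, 0.0, 1.0) * 0.001
        for _ in range(5):
            p = random_admissible_prony(rng)
            sum_resp = stress_convolution(p, TimeSeries(t, ramp_a + ramp_b)).values
            parts = (stress_convolution(p, TimeSeries(t, ramp_a)).values
                     + stress_convolution(p, TimeSeries(t, ramp_b)).values)
            np.testing.assert_allclose(sum_resp, parts, rtol=1e-10,
                                       atol=1e-12 * p.C0)

    def test_matches_closed_form_on_trapezoid_samples(self):
        t = np.linspace(0.0, 0.04, 2001)
        eps, _ = trapezoid_strain(LOADING, t)
        conv = stress_convolution(C33, TimeSeries(t, eps)).values
        closed = stress_closed_form(C33, LOADING, t)
        np.testing.assert_allclose(conv, closed, rtol=1e-10, atol=1e-9)

    def test_nonzero_initial_strain_rejected(self):
        with pytest.raises(ValueError):
            stress_convolution(C33, TimeSeries([0.0, 1.0], [0.1, 0.2]))

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError):
            TimeSeries([0.0, 2.0, 1.0], [0.0, 0.1, 0.2])


class TestOrthotropicResponse:
    def test_axial_loading_excites_normal_stresses_only(self):
        M = default_core_matrix()
        t = np.linspace(0, 0.04, 401)
        eps, _ = trapezoid_strain(LOADING, t)
        out = orthotropic_response(M, {3: TimeSeries(t, eps, component=3)})
        for i in (1, 2, 3):
            assert np.max(np.abs(out[i].values)) > 0
        for i in (4, 5, 6):
            assert np.all(out[i].values == 0.0)

    def test_long_time_plateau_recovers_long_term_modulus(self):
        M = default_core_matrix()
        t = np.linspace(0, 5.0, 2001)
        eps = np.clip(t / 0.003, 0, 1) * 0.003
        out = orthotropic_response(M, {1: TimeSeries(t, eps, component=1)})
        assert out[1].values[-1] / 0.003 == pytest.approx(
            M["C11"].long_term, rel=1e-6)

    def test_matches_dense_matrix_oracle(self, rng):
        comps = {}
        for key in AXON_CORE_PRONY_MEANS:
            comps[key] = random_admissible_prony(rng)
        M = OrthotropicRelaxationMatrix(comps)
        t = np.linspace(0, 0.04, 201)
        strains = {}
        for j in range(1, 7):
            eps = np.concatenate([[0.0], np.cumsum(rng.normal(0, 1e-4, 200))])
            strains[j] = TimeSeries(t, eps, component=j)
        out = orthotropic_response(M, strains)
        # brute force: fill the dense 6x6 Voigt matrix, convolve everything
        dense = [[None] * 6 for _ in range(6)]
        for i in range(1, 7):
            for j in range(1, 7):
                dense[i - 1][j - 1] = M.entry(i, j)
        for i in range(1, 7):
            total = np.zeros_like(t)
            for j in range(1, 7):
                if dense[i - 1][j - 1] is not None:
                    total += stress_convolution(dense[i - 1][j - 1],
                                                strains[j]).values
            np.testing.assert_allclose(out[i].values, total, rtol=1e-12)

    def test_missing_component_rejected(self):
        comps = {k: C33 for k in AXON_CORE_PRONY_MEANS}
        comps.pop("C23")
        with pytest.raises(ValueError):
            OrthotropicRelaxationMatrix(comps)


class TestRampStress:
    def test_elastic_and_short_time_limits(self):
        p_el = PronyRelaxation(1e5, ())
        t = np.linspace(0, 0.01, 50)
        np.testing.assert_allclose(ramp_stress(p_el, 10.0, t), 1e5 * 10.0 * t)
        t_small = 1e-7
        assert ramp_stress(C33, 50.0, t_small) == pytest.approx(
            C33.C0 * 50.0 * t_small, rel=1e-3)

    def test_matches_convolution_oracle(self, rng):
        rate = 50.0
        t_eval = np.array([2e-4, 7e-4, 1.4e-3])  # up to 7% strain
        for _ in range(5):
            p = random_admissible_prony(rng)
            oracle = trapezoid_convolution_oracle(p, lambda u: rate * u, t_eval,
                                                  dt=1e-7)
            np.testing.assert_allclose(ramp_stress(p, rate, t_eval), oracle,
                                       rtol=2e-3)

    def test_load_case_metadata_covers_all_components(self):
        fitted = {}
        for case in LOAD_CASES.values():
            fitted.update(case.fitted)
        assert sorted(fitted) == sorted(AXON_CORE_PRONY_MEANS)
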
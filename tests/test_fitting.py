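"""Volume averaging, constrained Prony regression, summary statistics."""

import numpy as np
import pytest

from axonve.fitting import (
    ElementField,
    PronyRelaxationModel,
    summarize_fits,
    volume_average,
)
from axonve.viscoelastic import (
    PronyRelaxation,
    TimeSeries,
    TrapezoidalLoading,
    stress_closed_form,
)

from conftest import random_admissible_prony

LOADING = TrapezoidalLoading(eps_star=0.003)


def _field(times, volumes, values):
    """Element field with a single stress component from raw arrays."""
    return ElementField(
        times=np.asarray(times, dtype=float),
        volumes=np.asarray(volumes, dtype=float),
        stress={3: np.asarray(values, dtype=float)},
        strain={},
        V_RVE=float(np.sum(volumes)),
    )


def _series(p: PronyRelaxation, n_pts: int = 161) -> TimeSeries:
    t = np.linspace(0.0, 0.04, n_pts)
    return TimeSeries(t, stress_closed_form(p, LOADING, t), kind="stress")


def _match_branches(fit: PronyRelaxation, truth: PronyRelaxation):
    """Max relative coefficient error, pairing branches across label exchange."""
    import itertools

    best = np.inf
    for perm in itertools.permutations(fit.terms):
        err = max(
            max(abs(f[0] - t[0]) / t[0], abs(f[1] - t[1]) / t[1])
            for f, t in zip(perm, truth.terms)
        )
        best = min(best, err)
    return best


class TestVolumeAverage:
    def test_uniform_field_is_identity(self):
        f = _field([0, 1, 2], [1.0, 2.0], np.full((2, 3), 7.5))
        assert np.all(volume_average(f, "stress", 3).values == 7.5)

    def test_weighted_mean(self):
        f = _field([0.0], [1.0, 3.0], [[0.0], [4.0]])
        assert volume_average(f, "stress", 3).values[0] == pytest.approx(3.0)

    def test_random_field_matches_direct_sum_oracle(self, rng):
        t = np.linspace(0, 1, 7)
        vols = rng.uniform(0.5, 2.0, 100)
        vals = rng.normal(0.0, 1.0, (100, 7))
        f = _field(t, vols, vals)
        oracle = (vols[:, None] * vals).sum(axis=0) / vols.sum()
        np.testing.assert_allclose(volume_average(f, "stress", 3).values,
                                   oracle, rtol=1e-12)

    def test_volume_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ElementField(times=np.array([0.0]), volumes=np.array([1.0, 1.0]),
                         stress={}, strain={}, V_RVE=3.0)


class TestPronyFit:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_noiseless_parameter_recovery(self, seed):
        rng = np.random.default_rng(seed)
        truth = random_admissible_prony(rng)
        res = PronyRelaxationModel(_series(truth), LOADING).fit(seed=seed)
        assert res.converged
        assert res.prony.C0 == pytest.approx(truth.C0, rel=0.01)
        tau = truth.tau
        degenerate = max(tau) / min(tau) < 2.0
        tol = 0.05 if degenerate else 0.01
        assert _match_branches(res.prony, truth) < tol

    def test_stress_scaling_scales_c0_only(self):
        truth = PronyRelaxation(2.5e5, ((0.3, 4e-3), (0.5, 9e-3)))
        base = PronyRelaxationModel(_series(truth), LOADING).fit(seed=0)
        ts = _series(truth)
        scaled = PronyRelaxationModel(
            TimeSeries(ts.times, 3.0 * ts.values, kind="stress"), LOADING
        ).fit(seed=0)
        assert scaled.prony.C0 == pytest.approx(3.0 * base.prony.C0, rel=1e-6)
        np.testing.assert_allclose(scaled.prony.h, base.prony.h, rtol=1e-5)
        np.testing.assert_allclose(scaled.prony.tau, base.prony.tau, rtol=1e-5)

    def test_noisy_recovery_of_short_term_modulus(self, rng):
        truth = PronyRelaxation(4.0e5, ((0.25, 3e-3), (0.6, 10e-3)))
        clean = _series(truth)
        c0s = []
        for rep in range(20):
            noisy = TimeSeries(
                clean.times,
                clean.values + 0.01 * np.max(np.abs(clean.values))
                * rng.normal(size=clean.values.shape),
                kind="stress",
            )
            res = PronyRelaxationModel(noisy, LOADING).fit(seed=rep, n_starts=3)
            c0s.append(res.prony.C0)
        assert np.mean(c0s) == pytest.approx(truth.C0, rel=0.05)

    def test_fitted_curve_reproduces_input(self):
        truth = PronyRelaxation(8.0e5, ((0.4, 5e-3), (0.45, 15e-3)))
        res = PronyRelaxationModel(_series(truth), LOADING).fit(seed=0)
        assert res.nrmse < 1e-3

    def test_outputs_satisfy_thermodynamic_constraints(self, rng):
        clean = _series(PronyRelaxation(4.0e5, ((0.45, 3e-3), (0.5, 8e-3))))
        for rep in range(3):
            noisy = TimeSeries(
                clean.times,
                clean.values * (1 + 0.05 * rng.normal(size=clean.values.shape)),
                kind="stress")
            p = PronyRelaxationModel(noisy, LOADING).fit(seed=rep).prony
            assert p.C0 > 0
            assert np.all(p.h >= 0)
            assert float(np.sum(p.h)) <= 1.0 + 1e-12
            assert np.all(p.tau > 0)

    def test_branches_sorted_by_relaxation_time(self):
        truth = PronyRelaxation(1e5, ((0.7, 20e-3), (0.2, 2e-3)))
        res = PronyRelaxationModel(_series(truth), LOADING).fit(seed=0)
        assert res.prony.tau[0] < res.prony.tau[1]

    def test_single_branch_model(self):
        truth = PronyRelaxation(3e5, ((0.6, 8e-3),))
        res = PronyRelaxationModel(_series(truth), LOADING, n_terms=1).fit(seed=0)
        assert len(res.params) == 3
        assert res.prony.C0 == pytest.approx(truth.C0, rel=1e-4)

    def test_infeasible_init_projected_with_warning(self):
        truth = PronyRelaxation(3e5, ((0.3, 4e-3), (0.5, 9e-3)))
        model = PronyRelaxationModel(_series(truth), LOADING)
        bad = {"C0": 3e5, "h1": 0.8, "h2": 0.7, "tau1": 4e-3, "tau2": 9e-3}
        with pytest.warns(UserWarning, match="thermodynamic"):
            res = model.fit(seed=0, n_starts=1, init=bad)
        assert float(np.sum(res.prony.h)) <= 1.0 + 1e-12

    def test_incomplete_history_rejected(self):
        t = np.linspace(0, 0.01, 50)  # stops before the unload phase
        with pytest.raises(ValueError):
            PronyRelaxationModel(TimeSeries(t, np.zeros(50)), LOADING)

    def test_summary_mentions_coefficients(self):
        truth = PronyRelaxation(3e5, ((0.3, 4e-3), (0.5, 9e-3)))
        res = PronyRelaxationModel(_series(truth), LOADING).fit(seed=0)
        text = res.summary()
        assert "C0" in text and "chi2" in text and "tau1" in text


class TestSummarize:
    def _results(self, params_list):
        out = []
        truth = PronyRelaxation(3e5, ((0.3, 4e-3), (0.5, 9e-3)))
        base = PronyRelaxationModel(_series(truth), LOADING).fit(seed=0)
        from dataclasses import replace

        for p in params_list:
            out.append(replace(base, prony=PronyRelaxation(
                p["C0"], ((p["h1"], p["tau1"]), (p["h2"], p["tau2"])))))
        return out

    def test_identical_observations_have_zero_se(self):
        p = {"C0": 1e5, "h1": 0.3, "h2": 0.5, "tau1": 4e-3, "tau2": 9e-3}
        table = summarize_fits({"C33": self._results([p, p, p])})
        assert table.loc["C33", "C0_se"] == 0.0
        assert table.loc["C33", "C0_mean"] == pytest.approx(1e5)

    def test_two_observations_hand_computation(self):
        # sample sd of (a, b) is |a-b|/sqrt(2); SE = sd/sqrt(2) = |a-b|/2
        pa = {"C0": 1.0e5, "h1": 0.3, "h2": 0.5, "tau1": 4e-3, "tau2": 9e-3}
        pb = {"C0": 1.4e5, "h1": 0.3, "h2": 0.5, "tau1": 4e-3, "tau2": 9e-3}
        table = summarize_fits({"C33": self._results([pa, pb])})
        assert table.loc["C33", "C0_mean"] == pytest.approx(1.2e5)
        assert table.loc["C33", "C0_se"] == pytest.approx(0.2e5)

    def test_five_observations_match_direct_formula(self, rng):
        c0s = rng.uniform(1e5, 5e5, 5)
        plist = [{"C0": c, "h1": 0.3, "h2": 0.5, "tau1": 4e-3, "tau2": 9e-3}
                 for c in c0s]
        table = summarize_fits({"C11": self._results(plist)})
        assert table.loc["C11", "C0_mean"] == pytest.approx(np.mean(c0s))
        assert table.loc["C11", "C0_se"] == pytest.approx(
            np.std(c0s, ddof=1) / np.sqrt(5))

    def test_single_observation_reports_absent_se(self):
        p = {"C0": 1e5, "h1": 0.3, "h2": 0.5, "tau1": 4e-3, "tau2": 9e-3}
        table = summarize_fits({"C44": self._results([p])})
        assert np.isnan(table.loc["C44", "C0_se"])
        assert table.loc["C44", "n_obs"] == 1
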
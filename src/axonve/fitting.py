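"""Homogenization and constrained Prony-series regression.

Element-wise stress/strain fields are volume-averaged into one stress
history per Voigt component; a :class:`PronyRelaxationModel` then fits the
closed-form hereditary-integral response of the trapezoidal relaxation test
to that history by weighted nonlinear least squares,

    chi^2(C) = sum_i [ (y_i - y(x_i; C)) / sigma_SD,i ]^2,

over the 2n+1 coefficients C = {C0, h_1..h_n, tau_1..tau_n}, subject to the
thermodynamic constraints C0 > 0, h_k >= 0, sum h_k <= 1, tau_k > 0.

Positivity is enforced through log-parameterization of C0 and tau_k, the
branch fractions through [0, 1] box bounds, and the simplex constraint
sum h_k <= 1 through a smooth quadratic penalty; the damped least-squares
step is the trust-region-reflective refinement of the Levenberg-Marquardt
iteration so the bounds stay applicable.  Because the chi^2 surface is
nearly flat when two relaxation times approach each other, the fit
multi-starts from seeded jitters of the initial guess and keeps the best
minimum.  Branches are reported sorted by ascending relaxation time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .viscoelastic import (
    PronyRelaxation,
    TimeSeries,
    TrapezoidalLoading,
    stress_closed_form,
    trapezoid_basis,
)

__all__ = [
    "ElementField",
    "volume_average",
    "PronyRelaxationModel",
    "PronyFitResults",
    "summarize_fits",
]


@dataclass(frozen=True)
class ElementField:
    """Per-element stress/strain histories on a shared time grid.

    ``stress`` and ``strain`` map Voigt component -> array of shape
    (n_elements, n_times); ``volumes`` are the element volumes (nm^3) whose
    sum must equal ``V_RVE``.
    """

    times: np.ndarray
    volumes: np.ndarray
    stress: dict[int, np.ndarray]
    strain: dict[int, np.ndarray]
    V_RVE: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        volumes = np.asarray(self.volumes, dtype=float)
        if np.any(volumes <= 0):
            raise ValueError("element volumes must be positive")
        total = float(volumes.sum())
        if not np.isclose(total, self.V_RVE, rtol=1e-9, atol=0.0):
            raise ValueError(
                f"element volumes sum to {total}, expected V_RVE={self.V_RVE}"
            )
        for name, table in (("stress", self.stress), ("strain", self.strain)):
            for comp, arr in table.items():
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (len(volumes), len(times)):
                    raise ValueError(
                        f"{name}[{comp}] has shape {arr.shape}, expected "
                        f"{(len(volumes), len(times))}"
                    )
                table[comp] = arr
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "volumes", volumes)

    @property
    def n_elements(self) -> int:
        return len(self.volumes)


def volume_average(field: ElementField, quantity: str, component: int) -> TimeSeries:
    """Volume-weighted mean history of one stress or strain component."""
    if quantity not in ("stress", "strain"):
        raise ValueError("quantity must be 'stress' or 'strain'")
    table = field.stress if quantity == "stress" else field.strain
    if component not in table:
        raise KeyError(f"component {component} not present in {quantity} field")
    mean = field.volumes @ table[component] / field.V_RVE
    return TimeSeries(field.times, mean, component=component, kind=quantity)


class PronyRelaxationModel:
    """Prony-series relaxation model for one volume-averaged stress history.

    Parameters
    ----------
    stress : TimeSeries
        Volume-averaged stress response (Pa) covering all four loading
        phases of the relaxation test.
    loading : TrapezoidalLoading
        The applied strain history.
    n_terms : int
        Number of Maxwell branches (default 2).
    weights : array-like, optional
        Per-point standard deviations sigma_SD of the observations; unit
        weights by default.
    """

    def __init__(self, stress: TimeSeries, loading: TrapezoidalLoading,
                 n_terms: int = 2, weights=None):
        if stress.times[-1] < loading.t3:
            raise ValueError("stress history must cover all four loading phases")
        if n_terms < 1:
            raise ValueError("at least one Maxwell branch is required")
        self.stress = stress
        self.loading = loading
        self.n_terms = int(n_terms)
        if weights is None:
            self.weights = np.ones_like(stress.values)
        else:
            self.weights = np.asarray(weights, dtype=float)
            if self.weights.shape != stress.values.shape or np.any(self.weights <= 0):
                raise ValueError("weights must be positive, one per data point")

    @classmethod
    def from_element_field(cls, field: ElementField, component: int,
                           loading: TrapezoidalLoading, **kwargs):
        """Build the model from an element field by volume averaging."""
        return cls(volume_average(field, "stress", component), loading, **kwargs)

    # -- parameter transform: theta = [log C0, h_1..h_n, log tau_1..log tau_n]

    def _unpack(self, theta: np.ndarray) -> PronyRelaxation:
        n = self.n_terms
        c0 = float(np.exp(theta[0]))
        h = np.clip(theta[1 : 1 + n], 0.0, 1.0)
        tau = np.exp(theta[1 + n :])
        s = h.sum()
        if s > 1.0:  # project onto the simplex for evaluation
            h = h / s
        return PronyRelaxation(c0, tuple(zip(h, tau)))

    @property
    def _penalty_scale(self) -> float:
        return 1e3 * np.sqrt(len(self.stress.values)) * max(
            1.0, float(np.max(np.abs(self.stress.values / self.weights))))

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        n = self.n_terms
        c0 = np.exp(theta[0])
        h = np.asarray(theta[1 : 1 + n], dtype=float)
        tau = np.exp(theta[1 + n :])
        A, B, _ = trapezoid_basis(self.loading, tau, self.stress.times)
        model = c0 * ((1.0 - h.sum()) * A + B @ h)
        res = (model - self.stress.values) / self.weights
        # smooth quadratic penalty keeping sum h_k <= 1
        penalty = self._penalty_scale * max(0.0, float(h.sum()) - 1.0)
        return np.append(res, penalty)

    def _jacobian(self, theta: np.ndarray) -> np.ndarray:
        n = self.n_terms
        c0 = np.exp(theta[0])
        h = np.asarray(theta[1 : 1 + n], dtype=float)
        tau = np.exp(theta[1 + n :])
        A, B, dB = trapezoid_basis(self.loading, tau, self.stress.times,
                                   with_grad=True)
        model = c0 * ((1.0 - h.sum()) * A + B @ h)
        w = self.weights
        J = np.zeros((len(model) + 1, 2 * n + 1))
        J[:-1, 0] = model / w  # d/d(log C0)
        for k in range(n):
            J[:-1, 1 + k] = c0 * (B[:, k] - A) / w
            J[:-1, 1 + n + k] = c0 * h[k] * tau[k] * dB[:, k] / w
        if float(h.sum()) > 1.0:
            J[-1, 1 : 1 + n] = self._penalty_scale
        return J

    def _initial_guess(self) -> np.ndarray:
        l, ts = self.loading, self.stress
        i1 = int(np.argmin(np.abs(ts.times - l.t1)))
        c0 = abs(ts.values[i1]) / abs(l.eps_star) if ts.values[i1] != 0 else np.nan
        if not np.isfinite(c0) or c0 <= 0:
            c0 = float(np.max(np.abs(ts.values))) / abs(l.eps_star)
        n = self.n_terms
        if n == 2:
            h = np.array([0.3, 0.6])
            tau = np.array([l.t1, l.t2 - l.t1])
        else:
            h = np.full(n, 0.9 / n)
            tau = np.geomspace(l.t1 / 2.0, l.t2, n)
        return np.concatenate([[np.log(c0)], h, np.log(tau)])

    def fit(self, seed: int = 0, n_starts: int = 5, max_nfev: int = 20000,
            init: dict | None = None) -> "PronyFitResults":
        """Fit the Prony coefficients; multi-start keeps the lowest chi^2.

        ``init`` may override the automatic starting point with coefficients
        {"C0", "h1".., "tau1"..}; a guess violating the thermodynamic
        constraints is projected into the feasible set with a warning.  A
        non-convergent search is returned flagged, not raised.
        """
        rng = np.random.default_rng(seed)
        n = self.n_terms
        if init is not None:
            h0 = np.array([float(init[f"h{k}"]) for k in range(1, n + 1)])
            tau0 = np.array([float(init[f"tau{k}"]) for k in range(1, n + 1)])
            if (init["C0"] <= 0 or np.any(h0 < 0) or h0.sum() > 1.0
                    or np.any(tau0 <= 0)):
                warnings.warn("initial guess violates the thermodynamic "
                              "constraints; projecting into the feasible set")
            c0 = max(float(init["C0"]), 1e-300)
            h0 = np.clip(h0, 0.0, 1.0)
            tau0 = np.maximum(tau0, 1e-12)
            theta0 = np.concatenate([[np.log(c0)], h0, np.log(tau0)])
        else:
            theta0 = self._initial_guess()
        if np.sum(theta0[1 : 1 + n]) > 1.0:  # infeasible guess: project
            theta0[1 : 1 + n] /= np.sum(theta0[1 : 1 + n])
        lo = np.concatenate([[-np.inf], np.zeros(n), np.full(n, -np.inf)])
        hi = np.concatenate([[np.inf], np.ones(n), np.full(n, np.inf)])

        starts = [theta0]
        for _ in range(max(0, n_starts - 1)):
            jitter = theta0.copy()
            jitter[0] += rng.normal(0.0, 0.2)
            jitter[1 : 1 + n] = np.clip(
                jitter[1 : 1 + n] + rng.uniform(-0.15, 0.15, n), 0.01, 0.95)
            jitter[1 + n :] += rng.normal(0.0, 0.5, n)
            starts.append(jitter)

        best = None
        total_nfev = 0
        for s in starts:
            sol = least_squares(
                self._residuals, s, jac=self._jacobian, bounds=(lo, hi),
                method="trf", xtol=3e-16, ftol=3e-16, gtol=3e-16,
                max_nfev=max_nfev,
            )
            total_nfev += sol.nfev
            if best is None or sol.cost < best.cost:
                best = sol

        # Optima on the sum(h) = 1 boundary sit at the kink of the penalty,
        # where the bounded solver stalls; a plain damped (Levenberg-
        # Marquardt) polish without the penalty row is kept when it stays
        # feasible and improves the fit.
        x = best.x
        try:
            plain = lambda th: self._residuals(th)[:-1]
            plain_jac = lambda th: self._jacobian(th)[:-1]
            pol = least_squares(plain, x, jac=plain_jac, method="lm",
                                xtol=3e-16, ftol=3e-16, gtol=3e-16,
                                max_nfev=max_nfev)
            total_nfev += pol.nfev
            h_pol = pol.x[1 : 1 + n]
            if (pol.cost < best.cost and np.all(h_pol > -1e-9)
                    and h_pol.sum() < 1.0 + 1e-9):
                x = pol.x.copy()
                x[1 : 1 + n] = np.clip(h_pol, 0.0, None)
                s = x[1 : 1 + n].sum()
                if s > 1.0:
                    x[1 : 1 + n] /= s
        except Exception:  # polish is best-effort only
            pass

        p = self._unpack(x)
        # report branches sorted by ascending relaxation time
        order = np.argsort(p.tau)
        p = PronyRelaxation(p.C0, tuple((p.h[i], p.tau[i]) for i in order))
        fitted = stress_closed_form(p, self.loading, self.stress.times)
        chi2 = float(np.sum(((fitted - self.stress.values) / self.weights) ** 2))
        h_sum = float(np.sum(p.h))
        return PronyFitResults(
            model=self,
            prony=p,
            chi2=chi2,
            converged=bool(best.status > 0),
            iterations=total_nfev,
            constraint_active={
                "h_sum_at_one": bool(h_sum > 1.0 - 1e-6),
                "h_at_zero": bool(np.any(p.h < 1e-9)),
            },
            fittedvalues=fitted,
        )


@dataclass(frozen=True)
class PronyFitResults:
    """Fitted Prony coefficients with goodness-of-fit diagnostics."""

    model: PronyRelaxationModel
    prony: PronyRelaxation
    chi2: float
    converged: bool
    iterations: int
    constraint_active: dict[str, bool]
    fittedvalues: np.ndarray

    @property
    def params(self) -> dict[str, float]:
        out = {"C0": self.prony.C0}
        for k, (h, tau) in enumerate(self.prony.terms, start=1):
            out[f"h{k}"] = h
            out[f"tau{k}"] = tau
        return out

    @property
    def resid(self) -> np.ndarray:
        return self.model.stress.values - self.fittedvalues

    @property
    def nrmse(self) -> float:
        """RMS residual normalized by the peak stress magnitude."""
        scale = float(np.max(np.abs(self.model.stress.values)))
        return float(np.sqrt(np.mean(self.resid**2))) / scale if scale else np.nan

    def summary(self) -> str:
        lines = [
            "Prony relaxation fit",
            f"  branches:   {self.prony.n}",
            f"  chi2:       {self.chi2:.6g}",
            f"  nrmse:      {self.nrmse:.3e}",
            f"  converged:  {self.converged}   (nfev {self.iterations})",
            f"  active:     {self.constraint_active}",
            f"  C0:         {self.prony.C0:.6g} Pa",
        ]
        for k, (h, tau) in enumerate(self.prony.terms, start=1):
            lines.append(f"  h{k}, tau{k}:  {h:.4f}, {tau * 1e3:.4g} ms")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Data vs fitted stress history (diagnostic)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.model.stress.times * 1e3
        ax.plot(t, self.model.stress.values / 1e3, ".", ms=3, label="data")
        ax.plot(t, self.fittedvalues / 1e3, "-", label="fit")
        ax.set_xlabel("time [ms]")
        ax.set_ylabel("volume-averaged stress [kPa]")
        ax.legend()
        return ax


def summarize_fits(results: dict[str, list[PronyFitResults]]) -> pd.DataFrame:
    """Mean and standard error of fitted coefficients across observations.

    ``results`` maps a relaxation-function label (e.g. "C33") to its fits
    over repeated observations.  The standard error is the sample standard
    deviation over sqrt(N); with a single observation it is reported absent
    (NaN).
    """
    rows = []
    for label, fits in results.items():
        if not fits:
            continue
        table = pd.DataFrame([f.params for f in fits])
        n = len(table)
        means = table.mean()
        se = table.std(ddof=1) / np.sqrt(n) if n >= 2 else means * np.nan
        row = {"component": label, "n_obs": n}
        for name in table.columns:
            row[f"{name}_mean"] = means[name]
            row[f"{name}_se"] = se[name]
        rows.append(row)
    return pd.DataFrame(rows).set_index("component")
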
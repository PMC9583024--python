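"""Shared fixtures and independent numerical oracles.

The oracles here deliberately avoid the library's own closed-form code
paths: stress responses are re-computed by brute-force trapezoidal
quadrature of the hereditary integral, creep responses by stiff ODE
integration, and volume fractions by quasi-random voxel sampling of the
explicit geometry.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from axonve.viscoelastic import PronyRelaxation

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def trapezoid_convolution_oracle(p: PronyRelaxation, strain_fn, t_eval,
                                 dt: float = 1.0e-6) -> np.ndarray:
    """Brute-force hereditary integral: sigma(t) = int_0^t C(t-u) deps/du du.

    ``strain_fn(t)`` returns the strain; the rate is obtained by central
    differencing on a fine grid, and the integral by trapezoidal quadrature
    with step ``dt``.  Independent of the package's exact per-segment
    integration.
    """
    out = np.empty(len(t_eval))
    for i, t in enumerate(np.asarray(t_eval, dtype=float)):
        n = max(int(round(t / dt)), 2)
        u = np.linspace(0.0, t, n + 1)
        eps = strain_fn(u)
        rate = np.gradient(eps, u)
        kernel = p.C0 * (1.0 - np.sum(
            p.h * (1.0 - np.exp(-(t - u)[:, None] / p.tau)), axis=1))
        out[i] = np.trapezoid(kernel * rate, u)
    return out


def random_admissible_prony(rng: np.random.Generator,
                            n_terms: int = 2) -> PronyRelaxation:
    """A random thermodynamically admissible 2-term Prony model."""
    c0 = 10 ** rng.uniform(4.0, 6.5)
    h = rng.dirichlet(np.ones(n_terms + 1))[:n_terms]  # sum < 1 strictly
    h = np.maximum(h, 0.02)
    h *= rng.uniform(0.5, 0.98) / h.sum()
    tau = 10 ** rng.uniform(-3.0, -1.5, size=n_terms)
    return PronyRelaxation(float(c0), tuple(zip(h, tau)))


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
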
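"""Synthetic relaxation-test and damage-ramp data generator.

Stands in for the finite-element solver: given a ground-truth orthotropic
Prony model it produces the element-wise and volume-averaged stress/strain
histories of the six characterization load cases, and the Tau/microtubule
micro-strain histories of the constant-rate damage stage.

The generator's defaults are the study conditions: ground truth equal to the
characterized core coefficients, the 3/12/15/40 ms trapezoidal protocol with
a 3 nm face displacement on the base RVE box, and a Tau strain-concentration
factor of 5.48 for the damage stage.

Element-level noise is applied in a volume-weighted mean-preserving way, so
the averaged series equal the exact forward-model response regardless of the
noise level; this separates tests of the averaging stage from tests of the
regression stage.  What the generator deliberately does not emulate:
spatially correlated stress fields, mesh geometry, or the stiffening of a
genuinely nonlinear large-strain solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import presets, rve
from .fitting import ElementField
from .viscoelastic import (
    LOAD_CASES,
    OrthotropicRelaxationMatrix,
    TimeSeries,
    TrapezoidalLoading,
    stress_closed_form,
    trapezoid_strain,
)

__all__ = ["SyntheticConfig", "generate_case", "generate_damage_microfield"]


def _default_box() -> dict[str, float]:
    s = rve.summarize(rve.RVE_PRESETS["RVE-1"])
    return {"a1": s.a1, "a2": s.a2, "a3": s.a3}


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions under which synthetic relaxation data are generated."""

    truth: OrthotropicRelaxationMatrix = field(
        default_factory=presets.default_core_matrix)
    times: tuple[float, ...] = presets.LOAD_TIMES
    delta_nm: float = presets.DELTA_NM
    box: dict[str, float] = field(default_factory=_default_box)
    noise_sd: float = 0.0
    n_elements: int = 1
    concentration_factor: float = presets.TAU_CONCENTRATION_FACTOR
    dt: float = 5.0e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_elements < 1:
            raise ValueError("at least one element is required")
        if self.concentration_factor <= 0:
            raise ValueError("concentration factor must be positive")

    def loading(self, case: int) -> TrapezoidalLoading:
        spec = LOAD_CASES[case]
        return TrapezoidalLoading(spec.eps_star(self.delta_nm, self.box),
                                  *self.times)

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


def _time_grid(cfg: SyntheticConfig) -> np.ndarray:
    n = int(round(cfg.times[-1] / cfg.dt))
    return np.linspace(cfg.times[0], cfg.times[-1], n + 1)


def generate_case(cfg: SyntheticConfig, case: int) -> ElementField:
    """Element field of one characterization load case.

    The driven Voigt component follows the trapezoidal history; responding
    stresses come from the ground-truth hereditary-integral solution.  With
    ``noise_sd = 0`` every element carries the exact mean; otherwise
    elements are perturbed by seeded relative Gaussian noise whose
    volume-weighted sum is projected to zero, so the volume average is
    preserved exactly.
    """
    if case not in LOAD_CASES:
        raise ValueError(f"load case must be 1..6, got {case}")
    spec = LOAD_CASES[case]
    loading = cfg.loading(case)
    t = _time_grid(cfg)
    strain, _ = trapezoid_strain(loading, t)

    rng = np.random.default_rng([cfg.seed, case])
    v_rve = cfg.box["a1"] * cfg.box["a2"] * cfg.box["a3"]
    if cfg.n_elements == 1:
        volumes = np.array([v_rve])
    else:
        volumes = rng.dirichlet(np.full(cfg.n_elements, 5.0)) * v_rve

    stress: dict[int, np.ndarray] = {}
    for label, i in spec.fitted.items():
        mean = stress_closed_form(cfg.truth[label], loading, t)
        elem = np.tile(mean, (cfg.n_elements, 1))
        if cfg.noise_sd > 0 and cfg.n_elements > 1:
            g = rng.normal(0.0, 1.0, size=elem.shape)
            g -= (volumes @ g) / v_rve  # zero volume-weighted sum
            elem = elem * (1.0 + cfg.noise_sd * g)
        stress[i] = elem

    strain_field = {spec.driven_component: np.tile(strain, (cfg.n_elements, 1))}
    return ElementField(times=t, volumes=volumes, stress=stress,
                        strain=strain_field, V_RVE=v_rve)


def generate_damage_microfield(
    cfg: SyntheticConfig, rate: float, t_end: float, dt: float = 1.0e-5
) -> dict[str, TimeSeries]:
    """Micro-strain histories under a constant axial strain-rate ramp.

    The volume-averaged RVE axial strain grows as ``rate * t``; the
    microtubule axial strain follows it one-to-one, while the Tau
    population-mean maximum principal strain is amplified by the
    concentration factor (plus optional seeded relative noise).
    """
    if rate <= 0:
        raise ValueError("strain rate must be positive")
    t = np.linspace(0.0, t_end, int(round(t_end / dt)) + 1)
    rve_strain = rate * t
    tau_strain = cfg.concentration_factor * rve_strain
    if cfg.noise_sd > 0:
        rng = np.random.default_rng([cfg.seed, 97, int(rate * 1e6)])
        tau_strain = tau_strain * (1.0 + cfg.noise_sd
                                   * rng.normal(0.0, 1.0, size=t.shape))
    return {
        "RVE": TimeSeries(t, rve_strain, component=3, kind="strain"),
        "MT": TimeSeries(t, rve_strain, component=3, kind="strain"),
        "TAU": TimeSeries(t, tau_strain, component=3, kind="strain"),
    }
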
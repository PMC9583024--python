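"""Constituent material models of the axonal cytoskeleton.

Tau protein is characterized in the literature as a Kelvin-Voigt (KV) solid
(spring and dashpot in parallel: creep retardation, no full stress
relaxation).  Relaxation-type finite-element inputs instead require a General
Maxwell (GM) representation, so the KV parameters are converted in two steps:

1. a 3-parameter GM model (standard linear solid) is matched to the KV creep
   response, with the equilibrium spring and the branch dashpot pinned to the
   KV constants and the branch stiffness chosen as a multiple of the KV
   modulus;
2. the Young's-modulus relaxation function is converted to a shear relaxation
   function through the elastic-viscoelastic correspondence principle at
   constant Poisson's ratio, which reduces to term-wise scaling by 1/(2(1+nu)).

The axoplasmic matrix (combined neurofilament/microfilament effect) is a
compressible neo-Hookean solid; only its parameter conversions (G, K, d=2/K)
live here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KelvinVoigtTau",
    "MaxwellBranch",
    "GeneralMaxwellModel",
    "IsotropicElastic",
    "NeoHookeanMatrix",
    "kv_creep_strain",
    "gm_creep_strain",
    "fit_gm_to_kv",
    "young_to_shear_relaxation",
    "elastic_conversions",
]


@dataclass(frozen=True)
class KelvinVoigtTau:
    """Kelvin-Voigt model of Tau: spring ``E_tau`` and dashpot ``mu_tau`` in parallel.

    Parameters
    ----------
    E_tau : float
        Spring modulus in Pa.
    mu_tau : float
        Dashpot viscosity in Pa*s.

    The retardation time ``tau_ret = mu_tau / E_tau`` is derived.
    """

    E_tau: float
    mu_tau: float

    def __post_init__(self) -> None:
        if self.E_tau <= 0 or self.mu_tau <= 0:
            raise ValueError("Kelvin-Voigt parameters must be positive")

    @property
    def tau_ret(self) -> float:
        """Retardation time mu/E in seconds."""
        return self.mu_tau / self.E_tau


@dataclass(frozen=True)
class MaxwellBranch:
    """One Maxwell element: spring ``stiffness`` in series with dashpot ``viscosity``."""

    stiffness: float
    viscosity: float

    def __post_init__(self) -> None:
        if self.stiffness <= 0 or self.viscosity <= 0:
            raise ValueError("Maxwell branch parameters must be positive")

    @property
    def relax_time(self) -> float:
        return self.viscosity / self.stiffness


@dataclass(frozen=True)
class GeneralMaxwellModel:
    """Equilibrium spring in parallel with Maxwell branches.

    ``domain_tag`` records whether the moduli are Young's-type ("young") or
    shear-type ("shear"); conversions between the two preserve relaxation
    times and scale stiffnesses.
    """

    long_term: float
    branches: tuple[MaxwellBranch, ...]
    domain_tag: str = "young"

    def __post_init__(self) -> None:
        if self.long_term <= 0:
            raise ValueError("long-term modulus must be positive")
        if self.domain_tag not in ("young", "shear"):
            raise ValueError(f"unknown domain tag {self.domain_tag!r}")
        object.__setattr__(self, "branches", tuple(self.branches))

    @property
    def short_term(self) -> float:
        """Instantaneous modulus: long-term plus all branch stiffnesses."""
        return self.long_term + sum(b.stiffness for b in self.branches)

    def relaxation_modulus(self, t):
        """Relaxation modulus E(t) = E_inf + sum_k E_k exp(-t/tau_k), t >= 0."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        out = np.full_like(t, self.long_term, dtype=float)
        for b in self.branches:
            out = out + b.stiffness * np.exp(-t / b.relax_time)
        return out


@dataclass(frozen=True)
class IsotropicElastic:
    """Isotropic linear-elastic constants (E, nu) with derived (G, K)."""

    E: float
    nu: float
    G: float = field(init=False)
    K: float = field(init=False)

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("Young's modulus must be positive")
        if not -1.0 < self.nu < 0.5:
            raise ValueError("Poisson's ratio must lie in (-1, 0.5)")
        object.__setattr__(self, "G", self.E / (2.0 * (1.0 + self.nu)))
        object.__setattr__(self, "K", self.E / (3.0 * (1.0 - 2.0 * self.nu)))


@dataclass(frozen=True)
class NeoHookeanMatrix:
    """Compressible neo-Hookean matrix parameters: G0, K and d = 2/K."""

    G0: float
    K: float

    def __post_init__(self) -> None:
        if self.G0 <= 0 or self.K <= 0:
            raise ValueError("matrix moduli must be positive")

    @property
    def d(self) -> float:
        """Incompressibility parameter 2/K (1/Pa)."""
        return 2.0 / self.K


def kv_creep_strain(kv: KelvinVoigtTau, sigma0: float, t):
    """Creep strain of the Kelvin-Voigt solid under constant stress.

    eps(t) = (sigma0/E) * (1 - exp(-t/tau_ret)).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if not math.isfinite(sigma0):
        raise ValueError("stress must be finite")
    return (sigma0 / kv.E_tau) * (1.0 - np.exp(-t / kv.tau_ret))


def gm_creep_strain(gm: GeneralMaxwellModel, sigma0: float, t):
    """Creep strain of the 3-parameter General Maxwell (standard linear) solid.

    For a single Maxwell branch (E1, mu1) in parallel with the equilibrium
    spring E_inf, constant stress sigma0 gives a first-order ODE whose
    solution interpolates the instantaneous compliance 1/(E_inf + E1) and the
    equilibrium compliance 1/E_inf with retardation time
    ``tau_c = mu1 (E_inf + E1) / (E1 E_inf)``.
    """
    if len(gm.branches) != 1:
        raise ValueError(
            "closed-form creep implemented for the single-branch model only"
        )
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    (b,) = gm.branches
    e_inf, e1, mu1 = gm.long_term, b.stiffness, b.viscosity
    e0 = e_inf + e1
    tau_c = mu1 * e0 / (e1 * e_inf)
    return sigma0 / e_inf + (sigma0 / e0 - sigma0 / e_inf) * np.exp(-t / tau_c)


def fit_gm_to_kv(
    kv: KelvinVoigtTau,
    multiplier_grid=(1.0, 10.0, 100.0, 1000.0),
    *,
    selected_multiplier: float | None = 100.0,
    n_times: int = 500,
):
    """Match a General Maxwell branch to the Kelvin-Voigt creep response.

    The equilibrium spring is pinned to ``E_tau`` and the branch viscosity to
    ``mu_tau``; the branch stiffness is ``m * E_tau`` for each multiplier
    ``m`` in the grid.  The discrepancy metric is the maximum absolute creep
    difference over ``t in [0, 5 tau_ret]`` at ``n_times`` log-spaced points
    (normalized by the asymptotic strain sigma0/E_tau), and decreases
    monotonically with ``m``: the GM solid approaches the KV solid as the
    branch spring stiffens.

    ``selected_multiplier`` pins the returned model to a conventional choice
    (default 100, giving a branch relaxation time mu/(100 E)); pass ``None``
    to select the grid minimizer instead.

    Returns
    -------
    (GeneralMaxwellModel, dict[multiplier, discrepancy])
    """
    grid = sorted(float(m) for m in multiplier_grid)
    if not grid:
        raise ValueError("multiplier grid must be non-empty")
    if any(m < 1.0 for m in grid):
        raise ValueError("multipliers must be >= 1")

    # log-spaced window catches the fast transient and the asymptote
    t = np.concatenate(
        [[0.0], np.geomspace(5e-4 * kv.tau_ret, 5.0 * kv.tau_ret, n_times - 1)]
    )
    sigma0 = kv.E_tau  # unit asymptotic strain; discrepancy is scale-free
    eps_kv = kv_creep_strain(kv, sigma0, t)

    table: dict[float, float] = {}
    for m in grid:
        gm = _gm_from_multiplier(kv, m)
        table[m] = float(np.max(np.abs(gm_creep_strain(gm, sigma0, t) - eps_kv)))

    if selected_multiplier is None:
        m_star = min(table, key=table.get)
    else:
        m_star = float(selected_multiplier)
    return _gm_from_multiplier(kv, m_star), table


def _gm_from_multiplier(kv: KelvinVoigtTau, m: float) -> GeneralMaxwellModel:
    return GeneralMaxwellModel(
        long_term=kv.E_tau,
        branches=(MaxwellBranch(stiffness=m * kv.E_tau, viscosity=kv.mu_tau),),
        domain_tag="young",
    )


def young_to_shear_relaxation(
    gm_young: GeneralMaxwellModel, nu: float
) -> GeneralMaxwellModel:
    """Convert a Young's-modulus relaxation function to shear.

    Under the correspondence principle the elastic relation G = E/(2(1+nu))
    holds between Carson transforms.  For a time-constant Poisson's ratio the
    transform relation collapses to term-wise scaling: every modulus is
    divided by 2(1+nu) and every relaxation time is preserved.
    """
    if gm_young.domain_tag != "young":
        raise ValueError("input model must be tagged as Young's-domain")
    if not -1.0 < nu < 0.5:
        raise ValueError("Poisson's ratio must lie in (-1, 0.5)")
    s = 2.0 * (1.0 + nu)
    return GeneralMaxwellModel(
        long_term=gm_young.long_term / s,
        branches=tuple(
            MaxwellBranch(stiffness=b.stiffness / s, viscosity=b.viscosity / s)
            for b in gm_young.branches
        ),
        domain_tag="shear",
    )


def elastic_conversions(E: float, nu: float) -> IsotropicElastic:
    """Shear and bulk moduli from (E, nu): G = E/(2(1+nu)), K = E/(3(1-2nu))."""
    if nu >= 0.5:
        raise ValueError("incompressible limit: bulk modulus undefined at nu >= 0.5")
    return IsotropicElastic(E=E, nu=nu)


def gm_to_dict(gm: GeneralMaxwellModel) -> dict:
    """JSON-ready representation of a General Maxwell model."""
    return {
        "model": "general_maxwell",
        "domain": gm.domain_tag,
        "long_term_Pa": gm.long_term,
        "branches": [
            {"stiffness_Pa": b.stiffness, "relax_time_s": b.relax_time}
            for b in gm.branches
        ],
    }


def gm_from_dict(d: dict) -> GeneralMaxwellModel:
    if d.get("model") != "general_maxwell":
        raise ValueError(f"not a general_maxwell record: {d.get('model')!r}")
    return GeneralMaxwellModel(
        long_term=float(d["long_term_Pa"]),
        branches=tuple(
            MaxwellBranch(
                stiffness=float(b["stiffness_Pa"]),
                viscosity=float(b["stiffness_Pa"]) * float(b["relax_time_s"]),
            )
            for b in d["branches"]
        ),
        domain_tag=d.get("domain", "young"),
    )


def derive_tau_and_matrix(
    *,
    E_tau: float = 5.0e6,
    tau_ret: float = 0.35,
    nu_tau: float = 0.33,
    multiplier: float = 100.0,
    E_matrix: float = 1.47e3,
    nu_matrix: float = 0.33,
) -> dict:
    """Full constituent-parameter derivation with literature defaults.

    Returns a JSON-ready dict with the Tau shear-domain General Maxwell model
    and the neo-Hookean matrix parameters (G0, K, d).
    """
    kv = KelvinVoigtTau(E_tau=E_tau, mu_tau=E_tau * tau_ret)
    gm_young, table = fit_gm_to_kv(kv, selected_multiplier=multiplier)
    gm_shear = young_to_shear_relaxation(gm_young, nu_tau)
    matrix_el = elastic_conversions(E_matrix, nu_matrix)
    matrix = NeoHookeanMatrix(G0=matrix_el.G, K=matrix_el.K)
    return {
        "tau_kelvin_voigt": {"E_Pa": kv.E_tau, "mu_Pa_s": kv.mu_tau,
                             "tau_ret_s": kv.tau_ret},
        "tau_young": gm_to_dict(gm_young),
        "tau_shear": gm_to_dict(gm_shear),
        "creep_fit_discrepancy": {str(k): v for k, v in table.items()},
        "matrix": {"G0_Pa": matrix.G0, "K_Pa": matrix.K, "d_per_Pa": matrix.d},
    }


def write_materials_json(path, result: dict) -> None:
    with open(path, "w") as fh:
        json.dump(result, fh, indent=2)
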
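"""Effective transverse elastic modulus of the layered axon cross-section.

In the transverse plane the axon is a concentric composite: an optional
myelin sheath, a thin actin-spectrin membrane skeleton, a soft inner region
(cytoplasm with microfilaments/neurofilaments) and the stiff MT-Tau
cytoskeletal core.  Under transverse loading the layers act approximately in
series, so the effective modulus is the inverse rule of mixture (Reuss
model): ``E1 = [ sum_p alpha_p / E_p ]^{-1}`` over the area fractions
``alpha_p`` and phase moduli ``E_p``.  The core phase uses the short-term
transverse relaxation modulus ``C11(0)`` of the cytoskeletal
characterization.

For a myelinated axon the sheath fraction follows from the g-ratio
``g = R_a / R_ms``: the inner fractions are renormalized to the sheath disc
by ``g^2`` and ``alpha_ms = 1 - g^2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import presets

__all__ = [
    "AxonCrossSection",
    "fractions_from_geometry",
    "myelin_modulus",
    "reuss_transverse_modulus",
    "voigt_transverse_modulus",
    "sweep_alpha_i",
]


def fractions_from_geometry(
    R_a: float, t_m: float, t_inner: float, g_ratio: float | None = None
) -> dict[str, float]:
    """Annulus area fractions of the axon cross-section.

    The inner-region thickness is counted from the axon surface
    (R_c = R_a - t_inner); the membrane annulus [R_a - t_m, R_a] lies within
    it, the inner region proper occupies [R_c, R_a - t_m] and the core fills
    [0, R_c].  Fractions are normalized to the axon disc; with a g-ratio
    they are rescaled to the sheath disc and the myelin fraction 1 - g^2 is
    added.
    """
    if R_a <= 0 or t_m < 0 or t_inner <= 0:
        raise ValueError("radii and thicknesses must be positive")
    if t_m + (R_a - t_inner) > R_a or t_inner >= R_a:
        raise ValueError("membrane and inner region must fit inside the axon")
    r_c = R_a - t_inner
    alpha_m = (R_a**2 - (R_a - t_m) ** 2) / R_a**2
    alpha_i = ((R_a - t_m) ** 2 - r_c**2) / R_a**2
    alpha_c = (r_c / R_a) ** 2
    out = {"alpha_ms": 0.0, "alpha_m": alpha_m, "alpha_i": alpha_i,
           "alpha_c": alpha_c}
    if g_ratio is not None:
        if not 0.0 < g_ratio <= 1.0:
            raise ValueError("g-ratio must lie in (0, 1]")
        g2 = g_ratio**2
        out = {"alpha_ms": 1.0 - g2, "alpha_m": alpha_m * g2,
               "alpha_i": alpha_i * g2, "alpha_c": alpha_c * g2}
    return out


def myelin_modulus(K_ms: float, nu_ms: float) -> float:
    """Myelin Young's modulus from bulk modulus and Poisson's ratio.

    E_ms = 3 K_ms (1 - 2 nu_ms); degenerates to zero at the incompressible
    limit (flagged by a ValueError rather than returning a non-positive
    stiffness).
    """
    if K_ms <= 0:
        raise ValueError("bulk modulus must be positive")
    if not 0.0 <= nu_ms < 0.5:
        raise ValueError("Poisson's ratio must lie in [0, 0.5) for a finite modulus")
    return 3.0 * K_ms * (1.0 - 2.0 * nu_ms)


@dataclass(frozen=True)
class AxonCrossSection:
    """Phase fractions and moduli of the transverse axon composite (Pa, nm)."""

    R_a: float = presets.AXON_RADIUS_NM
    t_m: float = presets.MEMBRANE_THICKNESS_NM
    t_inner: float = presets.INNER_REGION_THICKNESS_NM
    g_ratio: float | None = None
    E_m: float = presets.E_MEMBRANE
    E_i: float = presets.E_INNER
    K_ms: float = presets.K_MYELIN
    nu_ms: float = presets.NU_MYELIN
    C110: float = presets.AXON_CORE_PRONY_MEANS["C11"]["C0"]
    fractions: dict[str, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.fractions is None:
            object.__setattr__(
                self,
                "fractions",
                fractions_from_geometry(self.R_a, self.t_m, self.t_inner,
                                        self.g_ratio),
            )
        total = sum(self.fractions.values())
        if any(v < 0 for v in self.fractions.values()) or not math.isclose(
            total, 1.0, rel_tol=1e-9
        ):
            raise ValueError("phase fractions must be non-negative and sum to 1")

    @property
    def E_ms(self) -> float:
        return myelin_modulus(self.K_ms, self.nu_ms)

    def phase_table(self) -> list[tuple[str, float, float]]:
        """(phase, fraction, modulus) for the present phases."""
        moduli = {"alpha_ms": self.E_ms, "alpha_m": self.E_m,
                  "alpha_i": self.E_i, "alpha_c": self.C110}
        return [(k, self.fractions[k], moduli[k]) for k in moduli]


def reuss_transverse_modulus(x: AxonCrossSection) -> float:
    """Inverse-rule-of-mixture (harmonic, series) effective transverse modulus."""
    acc = 0.0
    for name, frac, mod in x.phase_table():
        if frac == 0.0:
            continue
        if mod <= 0:
            raise ValueError(f"phase {name} has nonzero fraction but no stiffness")
        acc += frac / mod
    return 1.0 / acc


def voigt_transverse_modulus(x: AxonCrossSection) -> float:
    """Rule-of-mixture (arithmetic, parallel) bound; upper bound on Reuss."""
    return sum(frac * mod for _, frac, mod in x.phase_table())


def sweep_alpha_i(
    x: AxonCrossSection, alpha_i_grid, target: float | None = None
) -> dict:
    """Effective modulus versus inner-region fraction.

    The core fraction absorbs the complement ``1 - alpha_ms - alpha_m -
    alpha_i`` at fixed membrane and sheath fractions.  When ``target`` is
    given (an experimental transverse modulus, Pa), the crossing alpha_i is
    solved by bisection and reported with the curve (NaN when the curve does
    not cross).
    """
    grid = np.asarray(alpha_i_grid, dtype=float)
    a_ms, a_m = x.fractions["alpha_ms"], x.fractions["alpha_m"]
    if np.any(grid < 0) or np.any(grid > 1.0 - a_ms - a_m + 1e-12):
        raise ValueError("alpha_i grid outside [0, 1 - alpha_ms - alpha_m]")

    def e1(alpha_i: float) -> float:
        fr = {"alpha_ms": a_ms, "alpha_m": a_m, "alpha_i": alpha_i,
              "alpha_c": 1.0 - a_ms - a_m - alpha_i}
        from dataclasses import replace

        return reuss_transverse_modulus(replace(x, fractions=fr))

    curve = np.array([e1(a) for a in grid])
    out = {"alpha_i": grid, "E1": curve}
    if target is not None:
        f = lambda a: e1(a) - target
        lo, hi = float(grid.min()), float(grid.max())
        out["alpha_i_at_target"] = (
            float(brentq(f, lo, hi)) if f(lo) * f(hi) < 0 else float("nan")
        )
    return out
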
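"""Hexagonal microtubule-Tau representative volume element (RVE).

The axonal cytoskeletal core is idealized as unidirectional microtubules (MT)
on a triangular (hexagonal-packing) lattice in the transverse 1-2 plane,
cross-linked by Tau protein cylinders that bridge nearest-neighbour MT
surfaces, all embedded in an axoplasmic matrix.  The RVE here is one
rectangular unit cell of the lattice: it contains two MTs (one at the cell
corners, shared, and one at the centre) and six unique Tau bonds per axial
cross-linking station, i.e. three Tau per MT per station.

Geometric conventions (documented in the methods note):

* ``d_MT`` is the transverse wall-to-wall spacing, so the lattice pitch is
  ``d_MT + 2 R_O_MT``.
* Each MT carries one axial discontinuity of length ``gap_MT`` per half-span,
  placed uniformly at random within the central ``gap_window`` fraction of
  that half-span (placement is seeded and does not affect volume fractions).
* Tau cross-linking stations are spaced ``d_tau`` apart within the central
  ``gap_window`` fraction of the RVE length; Tau cylinders run surface to
  surface (length ``d_MT``), normal to the MT axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["RVEConfig", "RVESummary", "Segment", "build_rve", "volume_fractions"]


@dataclass(frozen=True)
class RVEConfig:
    """Geometry and stiffness parameters of the MT-Tau RVE (lengths in nm)."""

    R_O_MT: float = 12.5
    R_I_MT: float = 7.0
    R_tau: float = 4.0
    d_MT: float = 20.0
    d_tau: float = 40.0
    L_half: float = 500.0
    gap_MT: float = 20.0
    gap_window: float = 0.8
    E_MT: float = 1.5e9

    def __post_init__(self) -> None:
        if not self.R_I_MT < self.R_O_MT:
            raise ValueError("MT inner radius must be smaller than outer radius")
        for name in ("R_O_MT", "R_I_MT", "R_tau", "d_MT", "d_tau", "L_half"):
            if getattr(self, name) < 0 or (
                name not in ("R_tau",) and getattr(self, name) == 0
            ):
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.gap_window <= 1.0:
            raise ValueError("gap_window must lie in (0, 1]")
        if self.gap_MT < 0 or self.gap_MT >= self.L_half:
            raise ValueError("gap_MT must lie in [0, L_half)")
        if self.pitch <= 2.0 * self.R_O_MT:
            raise ValueError("overlapping MTs: pitch must exceed the MT diameter")

    @property
    def pitch(self) -> float:
        """Centre-to-centre MT spacing: wall-to-wall distance plus one diameter."""
        return self.d_MT + 2.0 * self.R_O_MT

    @property
    def length(self) -> float:
        """Full axial length of the RVE (2L)."""
        return 2.0 * self.L_half


@dataclass(frozen=True)
class RVESummary:
    """Derived cell dimensions, counts and volume fractions."""

    a1: float
    a2: float
    a3: float
    cell_area: float
    n_MT: int
    n_tau: int
    alpha_MT: float
    alpha_tau: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_MT + self.alpha_tau < 1.0:
            raise ValueError("total fibre volume fraction must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Segment:
    """A cylindrical (or annular, for MT) solid between two axis points, nm."""

    kind: str  # "MT" | "TAU"
    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    r_outer: float
    r_inner: float = 0.0


def _tau_station_z(config: RVEConfig) -> np.ndarray:
    """Axial positions of the Tau cross-linking stations (centred window)."""
    window = config.gap_window * config.length
    n = int(math.floor(window / config.d_tau))
    if n <= 0 or config.R_tau == 0.0:
        return np.empty(0)
    center = config.L_half
    offsets = (np.arange(n) - (n - 1) / 2.0) * config.d_tau
    return center + offsets


def _bond_endpoints(config: RVEConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """In-plane endpoints of the six unique Tau bonds of the unit cell.

    The corner MT sits at (0, 0) (with periodic images at the other three
    corners) and the centre MT at (p/2, sqrt(3) p/2).  Each lattice site has
    six nearest neighbours at distance p; per cell that is six unique bonds:
    four corner-centre diagonals plus one horizontal bond on each row.
    """
    p = config.pitch
    a = np.array([0.0, 0.0])
    b = np.array([p / 2.0, math.sqrt(3.0) * p / 2.0])
    pairs = [
        (a, b),
        (np.array([p, 0.0]), b),
        (np.array([0.0, math.sqrt(3.0) * p]), b),
        (np.array([p, math.sqrt(3.0) * p]), b),
        (a, np.array([p, 0.0])),
        (b, b + np.array([p, 0.0])),
    ]
    out = []
    for q0, q1 in pairs:
        u = (q1 - q0) / np.linalg.norm(q1 - q0)
        out.append((q0 + config.R_O_MT * u, q1 - config.R_O_MT * u))
    return out


def build_rve(config: RVEConfig, seed: int = 0) -> list[Segment]:
    """Explicit segment list of the unit-cell RVE geometry.

    Returns MT segments (annular cylinders along axis 3, split at their
    seeded axial discontinuities) and Tau segments (full cylinders bridging
    nearest-neighbour MT surfaces at each cross-linking station).  Tau bonds
    to periodic images extend beyond the cell box; consumers treat the box as
    periodic.
    """
    rng = np.random.default_rng(seed)
    p = config.pitch
    sites = [(0.0, 0.0), (p / 2.0, math.sqrt(3.0) * p / 2.0)]
    segments: list[Segment] = []
    for x, y in sites:
        # one seeded gap per half-span, inside its central gap_window
        cuts: list[tuple[float, float]] = []
        for half_start in (0.0, config.L_half):
            if config.gap_MT > 0.0:
                center_lo = half_start + config.L_half * (1 - config.gap_window) / 2
                center_hi = half_start + config.L_half * (1 + config.gap_window) / 2
                c = rng.uniform(
                    max(center_lo, half_start + config.gap_MT / 2),
                    min(center_hi, half_start + config.L_half - config.gap_MT / 2),
                )
                cuts.append((c - config.gap_MT / 2, c + config.gap_MT / 2))
        z0 = 0.0
        for lo, hi in sorted(cuts):
            segments.append(
                Segment("MT", (x, y, z0), (x, y, lo), config.R_O_MT, config.R_I_MT)
            )
            z0 = hi
        segments.append(
            Segment("MT", (x, y, z0), (x, y, config.length),
                    config.R_O_MT, config.R_I_MT)
        )
    for z in _tau_station_z(config):
        for q0, q1 in _bond_endpoints(config):
            segments.append(
                Segment("TAU", (q0[0], q0[1], z), (q1[0], q1[1], z), config.R_tau)
            )
    return segments


def volume_fractions(config: RVEConfig) -> tuple[float, float]:
    """Closed-form MT and Tau volume fractions of the unit-cell RVE.

    alpha_MT = [pi (R_O^2 - R_I^2) / cell_area] * axial coverage, with
    cell_area = (sqrt(3)/2) pitch^2 per MT and coverage
    (L_half - gap_MT)/L_half.  alpha_tau counts three surface-to-surface Tau
    cylinders per MT per cross-linking station.
    """
    cell_area = (math.sqrt(3.0) / 2.0) * config.pitch**2
    coverage = (config.L_half - config.gap_MT) / config.L_half
    wall_area = math.pi * (config.R_O_MT**2 - config.R_I_MT**2)
    alpha_mt = wall_area / cell_area * coverage

    n_stations = len(_tau_station_z(config))
    v_tau = math.pi * config.R_tau**2 * config.d_MT
    cell_volume = 2.0 * cell_area * config.length  # two MTs per rectangular cell
    alpha_tau = 6.0 * n_stations * v_tau / cell_volume
    return alpha_mt, alpha_tau


def summarize(config: RVEConfig) -> RVESummary:
    """Box dimensions, counts and volume fractions for a configuration."""
    alpha_mt, alpha_tau = volume_fractions(config)
    p = config.pitch
    return RVESummary(
        a1=p,
        a2=math.sqrt(3.0) * p,
        a3=config.length,
        cell_area=(math.sqrt(3.0) / 2.0) * p**2,
        n_MT=2,
        n_tau=6 * len(_tau_station_z(config)),
        alpha_MT=alpha_mt,
        alpha_tau=alpha_tau,
    )


#: The four study configurations: the base geometry and its one-parameter
#: variants (thicker Tau, denser Tau, wider MT spacing).
RVE_PRESETS: dict[str, RVEConfig] = {
    "RVE-1": RVEConfig(),
    "RVE-2": RVEConfig(R_tau=6.0),
    "RVE-3": RVEConfig(d_tau=20.0),
    "RVE-4": RVEConfig(d_MT=38.0),
}
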
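"""Linear viscoelastic relaxation mathematics.

Stress under small strain follows the Boltzmann hereditary integral
``sigma_i(t) = int_0^t C_ij(t - tau) d eps_j/d tau d tau`` with each
relaxation function represented as a Prony series (generalized Maxwell
model)::

    C(t) = C0 * (1 - sum_k h_k * (1 - exp(-t / tau_k)))

where ``C0`` is the short-term (instantaneous) modulus, ``h_k`` the
dimensionless branch fractions and ``tau_k`` the relaxation times.
Thermodynamic admissibility requires ``C0 > 0``, ``h_k >= 0``,
``sum h_k <= 1`` and ``tau_k > 0``; it is enforced at construction.

The orthotropic cytoskeletal core needs nine independent relaxation
functions (Voigt components C11, C12, C13, C22, C23, C33, C44, C55, C66);
the relaxation-test protocol drives them with trapezoidal strain histories
(ramp, hold, unload, recovery).

Shear components use the engineering-shear convention: the applied shear
measure is gamma = delta / a (face displacement over box dimension), and
C44/C55/C66 relate shear stress to engineering shear strain.

Stress evaluation integrates the exponential kernel exactly over each
linear strain segment, so results carry no time-step sensitivity; a plain
trapezoidal quadrature of the hereditary integral is kept out of the
library and serves only as an independent oracle in the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PronyRelaxation",
    "OrthotropicRelaxationMatrix",
    "TrapezoidalLoading",
    "LoadCaseSpec",
    "TimeSeries",
    "LOAD_CASES",
    "prony_eval",
    "trapezoid_strain",
    "stress_closed_form",
    "stress_convolution",
    "orthotropic_response",
    "ramp_stress",
]

#: Voigt component labels of the nine orthotropic relaxation functions.
ORTHOTROPIC_COMPONENTS = ("C11", "C12", "C13", "C22", "C23", "C33", "C44", "C55", "C66")


@dataclass(frozen=True)
class PronyRelaxation:
    """A Prony-series relaxation function C(t) = C0 (1 - sum h_k (1 - e^{-t/tau_k})).

    Parameters
    ----------
    C0 : float
        Short-term (t = 0) modulus, Pa.
    terms : sequence of (h_k, tau_k)
        Branch fraction (dimensionless) and relaxation time (s) per Maxwell
        branch.  Thermodynamic admissibility (positivity of dissipation) is
        validated on construction.
    """

    C0: float
    terms: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple((float(h), float(tau))
                                                for h, tau in self.terms))
        if not self.C0 > 0:
            raise ValueError("short-term modulus C0 must be positive")
        for h, tau in self.terms:
            if h < 0:
                raise ValueError("branch fractions h_k must be non-negative")
            if not tau > 0:
                raise ValueError("relaxation times tau_k must be positive")
        if sum(h for h, _ in self.terms) > 1.0 + 1e-12:
            raise ValueError("sum of branch fractions must not exceed 1")

    @property
    def n(self) -> int:
        return len(self.terms)

    @property
    def h(self) -> np.ndarray:
        return np.array([h for h, _ in self.terms])

    @property
    def tau(self) -> np.ndarray:
        return np.array([tau for _, tau in self.terms])

    @property
    def long_term(self) -> float:
        """Fully relaxed modulus C0 (1 - sum h_k)."""
        return self.C0 * (1.0 - float(np.sum(self.h)))

    def __call__(self, t):
        return prony_eval(self, t)


def prony_eval(p: PronyRelaxation, t):
    """Evaluate the relaxation modulus at times ``t >= 0``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("relaxation modulus defined for t >= 0 only")
    if p.n == 0:
        return np.full_like(t, p.C0, dtype=float)
    h, tau = p.h, p.tau
    decay = np.exp(-t[..., None] / tau)
    return p.C0 * (1.0 - np.sum(h * (1.0 - decay), axis=-1))


@dataclass(frozen=True)
class OrthotropicRelaxationMatrix:
    """The nine independent relaxation functions of an orthotropic solid.

    Components are keyed C11..C66 in Voigt arrangement; the matrix is
    symmetric (C12 = C21 etc.) with zeros outside the 3x3 normal block and
    the shear diagonal.
    """

    components: dict[str, PronyRelaxation]

    def __post_init__(self) -> None:
        missing = set(ORTHOTROPIC_COMPONENTS) - set(self.components)
        extra = set(self.components) - set(ORTHOTROPIC_COMPONENTS)
        if missing or extra:
            raise ValueError(
                f"orthotropic matrix needs exactly {ORTHOTROPIC_COMPONENTS}; "
                f"missing {sorted(missing)}, unexpected {sorted(extra)}"
            )

    def __getitem__(self, key: str) -> PronyRelaxation:
        return self.components[key]

    def entry(self, i: int, j: int) -> PronyRelaxation | None:
        """Voigt-matrix entry (1-based); ``None`` where the entry is zero."""
        if i > j:
            i, j = j, i
        if i <= 3 and j <= 3:
            return self.components[f"C{i}{j}"]
        if i == j:
            return self.components[f"C{i}{i}"]
        return None


@dataclass(frozen=True)
class TrapezoidalLoading:
    """Relaxation-test strain history: ramp to ``eps_star``, hold, unload, recover.

    Times are in seconds; defaults follow the 3/12/15/40 ms protocol.
    """

    eps_star: float
    t0: float = 0.0
    t1: float = 3.0e-3
    t2: float = 12.0e-3
    t3: float = 15.0e-3
    t4: float = 40.0e-3

    def __post_init__(self) -> None:
        if not self.t0 < self.t1 < self.t2 < self.t3 < self.t4:
            raise ValueError("loading times must satisfy t0 < t1 < t2 < t3 < t4")

    def knots(self) -> tuple[np.ndarray, np.ndarray]:
        """Piecewise-linear strain knots (times, strains)."""
        return (
            np.array([self.t0, self.t1, self.t2, self.t3, self.t4]),
            np.array([0.0, self.eps_star, self.eps_star, 0.0, 0.0]),
        )


def trapezoid_strain(l: TrapezoidalLoading, t):
    """Strain and strain rate of the trapezoidal history at times ``t``.

    Returns ``(strain, rate)``; the strain is continuous piecewise-linear and
    the rate piecewise-constant (rate at the knots is taken from the segment
    to the left, consistent with the loading being defined on half-open
    intervals).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < l.t0) or np.any(t > l.t4):
        raise ValueError("time outside the loading window [t0, t4]")
    r1 = l.eps_star / (l.t1 - l.t0)
    r3 = -l.eps_star / (l.t3 - l.t2)
    strain = np.select(
        [t <= l.t1, t <= l.t2, t <= l.t3],
        [r1 * (t - l.t0), l.eps_star, l.eps_star + r3 * (t - l.t2)],
        default=0.0,
    )
    rate = np.select(
        [t <= l.t0, t <= l.t1, t <= l.t2, t <= l.t3],
        [0.0, r1, 0.0, r3],
        default=0.0,
    )
    return strain, rate


def _segment_integral(p: PronyRelaxation, t, a, b):
    """Exact ``int_a^b C(t - tau) d tau`` for eval times ``t >= b >= a``.

    The Prony kernel integrates per segment in closed form:
    C0 [ (1 - sum h)(b - a) + sum_k h_k tau_k (e^{-(t-b)/tau_k} - e^{-(t-a)/tau_k}) ].
    """
    t = np.asarray(t, dtype=float)
    b = np.broadcast_to(np.asarray(b, dtype=float), t.shape)
    h_sum = float(np.sum(p.h)) if p.n else 0.0
    out = (1.0 - h_sum) * (b - a)
    if p.n:
        h, tau = p.h, p.tau
        out = out + np.sum(
            h * tau * (np.exp(-(t[..., None] - b[..., None]) / tau)
                       - np.exp(-(t[..., None] - a) / tau)),
            axis=-1,
        )
    return p.C0 * out


def _convolve_knots(p: PronyRelaxation, knot_t: np.ndarray, knot_e: np.ndarray,
                    t_eval: np.ndarray) -> np.ndarray:
    """Hereditary-integral stress for a piecewise-linear strain history.

    Exact per linear segment (no time-step sensitivity).  ``t_eval`` must lie
    within the history span.
    """
    sigma = np.zeros_like(t_eval, dtype=float)
    for m in range(len(knot_t) - 1):
        ta, tb = knot_t[m], knot_t[m + 1]
        if tb == ta:
            continue
        rate = (knot_e[m + 1] - knot_e[m]) / (tb - ta)
        if rate == 0.0:
            continue
        active = t_eval > ta
        if not np.any(active):
            continue
        upper = np.minimum(t_eval[active], tb)
        sigma[active] += rate * _segment_integral(p, t_eval[active], ta, upper)
    return sigma


def _ramp_basis(tau: np.ndarray, t: np.ndarray, start: float, duration: float,
                with_grad: bool):
    """Basis pieces of one finite ramp of unit rate starting at ``start``.

    Returns ``(A, B, dB)`` where for a Prony model the ramp's stress
    contribution is ``rate * C0 * [(1 - sum h) A + sum_k h_k B_k]``:
    ``A`` is the elastic part min(t - start, duration) (zero before the
    ramp), ``B_k = tau_k (1 - e^{-u/tau_k})`` while the ramp is live and
    ``tau_k (e^{-(u-d)/tau_k} - e^{-u/tau_k})`` after it ends (u = t - start,
    d = duration), and ``dB`` the derivative of ``B`` with respect to
    ``tau_k`` (``None`` unless requested).  All exponents are non-positive,
    so the evaluation is overflow-safe for any tau.
    """
    u = np.maximum(t - start, 0.0)
    A = np.minimum(u, duration)
    live = u <= duration
    ul = np.where(live, u, duration)  # exponent arguments, always >= 0
    uo = u - ul  # time since ramp end (0 while live)
    e_new = np.exp(-u[:, None] / tau[None, :])
    e_old = np.exp(-uo[:, None] / tau[None, :])
    active = (u > 0)[:, None]
    B = np.where(active, tau[None, :] * (e_old - e_new), 0.0)
    dB = None
    if with_grad:
        dB = np.where(
            active,
            e_old * (1.0 + uo[:, None] / tau[None, :])
            - e_new * (1.0 + u[:, None] / tau[None, :]),
            0.0,
        )
    return A, B, dB


def trapezoid_basis(l: TrapezoidalLoading, tau: np.ndarray, t: np.ndarray,
                    with_grad: bool = False):
    """Stress basis of the trapezoidal test for relaxation times ``tau``.

    The response is the superposition of the loading ramp (rate
    eps*/(t1-t0) from t0 to t1) and the unloading ramp (rate -eps*/(t3-t2)
    from t2 to t3): ``sigma = C0 [ (1 - sum h) A + B @ h ]`` with the
    returned per-unit-strain ``A`` (shape (T,)), ``B`` (shape (T, n)) and,
    when requested, ``dB/dtau`` (shape (T, n)).
    """
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    r1 = l.eps_star / (l.t1 - l.t0)
    r3 = l.eps_star / (l.t3 - l.t2)
    A1, B1, dB1 = _ramp_basis(tau, t, l.t0, l.t1 - l.t0, with_grad)
    A3, B3, dB3 = _ramp_basis(tau, t, l.t2, l.t3 - l.t2, with_grad)
    A = r1 * A1 - r3 * A3
    B = r1 * B1 - r3 * B3
    dB = (r1 * dB1 - r3 * dB3) if with_grad else None
    return A, B, dB


def stress_closed_form(p: PronyRelaxation, l: TrapezoidalLoading, t):
    """Stress response to the trapezoidal relaxation test, in closed form.

    Evaluates the four-phase hereditary-integral solution (load ramp, hold,
    unload ramp, recovery) assuming zero initial strain; continuous across
    the phase boundaries.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if np.any(t < l.t0) or np.any(t > l.t4):
        raise ValueError("time outside the loading window [t0, t4]")
    tau = p.tau if p.n else np.array([1.0])
    h = p.h if p.n else np.zeros(1)
    A, B, _ = trapezoid_basis(l, tau, t)
    sigma = p.C0 * ((1.0 - float(h.sum())) * A + B @ h)
    return sigma[0] if scalar else sigma


@dataclass(frozen=True)
class TimeSeries:
    """A sampled strain or stress history for one Voigt component."""

    times: np.ndarray
    values: np.ndarray
    component: int = 1
    kind: str = "strain"  # "strain" | "stress"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.ndim != 1 or times.shape != values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(times) >= 2 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not 1 <= self.component <= 6:
            raise ValueError("Voigt component must be in 1..6")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)


def stress_convolution(p: PronyRelaxation, eh: TimeSeries) -> TimeSeries:
    """Hereditary-integral stress response to an arbitrary sampled strain history.

    The history is interpreted as piecewise linear between samples and the
    exponential kernel is integrated exactly over each segment.  The history
    must start from zero strain.
    """
    if eh.values[0] != 0.0:
        raise ValueError("strain history must start at zero strain")
    sigma = _convolve_knots(p, eh.times, eh.values, eh.times)
    return TimeSeries(eh.times, sigma, component=eh.component, kind="stress")


def orthotropic_response(
    M: OrthotropicRelaxationMatrix, strains: dict[int, TimeSeries]
) -> dict[int, TimeSeries]:
    """Six stress histories from applied strain histories via the Voigt matrix.

    ``strains`` maps Voigt component j (1..6) to its strain history; missing
    components are treated as identically zero.  The sparsity of the
    orthotropic matrix is used: normal stresses couple only to normal
    strains, shear stresses only to their own shear strain.
    """
    if not strains:
        raise ValueError("at least one strain history is required")
    ref = next(iter(strains.values()))
    for ts in strains.values():
        if ts.times.shape != ref.times.shape or not np.allclose(ts.times, ref.times):
            raise ValueError("strain histories must share one time grid")
    out: dict[int, TimeSeries] = {}
    for i in range(1, 7):
        total = np.zeros_like(ref.times, dtype=float)
        for j, ts in strains.items():
            comp = M.entry(i, j)
            if comp is not None:
                total += stress_convolution(comp, ts).values
        out[i] = TimeSeries(ref.times, total, component=i, kind="stress")
    return out


def ramp_stress(p: PronyRelaxation, rate: float, t):
    """Stress under a constant strain-rate ramp ``eps(t) = rate * t``.

    sigma(t) = C0 rate [ (1 - sum h) t + sum_k h_k tau_k (1 - e^{-t/tau_k}) ].
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    h = p.h if p.n else np.zeros(0)
    tau = p.tau if p.n else np.zeros(1)
    H = float(np.sum(h))
    inner = (1.0 - H) * t
    if p.n:
        inner = inner + np.sum(h * tau * (1.0 - np.exp(-t[..., None] / tau)), axis=-1)
    return p.C0 * rate * inner


@dataclass(frozen=True)
class LoadCaseSpec:
    """Displacement boundary-condition metadata for one characterization case.

    ``driven_component`` is the Voigt strain component excited by the face
    displacement delta(t); ``box_axis`` names which box dimension (a1, a2,
    a3) normalizes delta into strain; ``fitted`` maps relaxation-function
    labels to the responding stress component used to identify them.
    ``fixed_faces`` records the zero-displacement constraints of the
    remaining faces.
    """

    index: int
    driven_component: int
    driven_face: str
    driven_displacement: str
    box_axis: str
    fitted: dict[str, int]
    fixed_faces: tuple[str, ...]

    def eps_star(self, delta: float, box: dict[str, float]) -> float:
        """Plateau strain delta / a for a given box (same length units)."""
        return delta / box[self.box_axis]


#: The six displacement-controlled characterization cases: three normal
#: (driving eps1, eps2, eps3) and three shear (driving gamma23, gamma13,
#: gamma12), each with all other faces held.
LOAD_CASES: dict[int, LoadCaseSpec] = {
    1: LoadCaseSpec(1, 1, "x1=a1", "u=delta1(t)", "a1", {"C11": 1},
                    ("x1=0:u=0", "x2=0:v=0", "x2=a2:v=0", "x3=0:w=0", "x3=a3:w=0")),
    2: LoadCaseSpec(2, 2, "x2=a2", "v=delta2(t)", "a2", {"C12": 1, "C22": 2},
                    ("x1=0:u=0", "x1=a1:u=0", "x2=0:v=0", "x3=0:w=0", "x3=a3:w=0")),
    3: LoadCaseSpec(3, 3, "x3=a3", "w=delta3(t)", "a3",
                    {"C13": 1, "C23": 2, "C33": 3},
                    ("x1=0:u=0", "x1=a1:u=0", "x2=0:v=0", "x2=a2:v=0", "x3=0:w=0")),
    4: LoadCaseSpec(4, 4, "x2=a2", "w=delta4(t)", "a2", {"C44": 4},
                    ("x1=0:u=0", "x1=a1:u=0", "x2=0:v=0,w=0", "x2=a2:v=0")),
    5: LoadCaseSpec(5, 5, "x1=a1", "w=delta5(t)", "a1", {"C55": 5},
                    ("x1=0:u=0,w=0", "x1=a1:u=0", "x2=0:v=0", "x2=a2:v=0")),
    6: LoadCaseSpec(6, 6, "x1=a1", "v=delta6(t)", "a1", {"C66": 6},
                    ("x1=0:u=0,v=0", "x1=a1:u=0", "x3=0:w=0", "x3=a3:w=0")),
}
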
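"""Strain-rate-dependent failure evaluation of the cytoskeletal core.

Constant axial strain-rate ramps are applied along the microtubule direction
and the micro-strain histories of the fibres are tracked against their
failure criteria: Tau fails at 40% maximum principal strain, microtubules at
50% axial strain.  Whichever criterion is crossed first (by linear
interpolation between samples) defines the axon-level failure time; the
volume-averaged axon failure strain is ``rate * t_fail`` and the failure
stress is the linear viscoelastic ramp response of the axial relaxation
function at that time.

Two honesty notes.  First, ramps are capped at 12% axon strain by default;
with the default Tau strain concentration factor of 5.48 the Tau criterion
is reached near 7.3% axon strain, inside the cap.  Second, the reported
failure stresses come from the homogenized *linear* Prony model; a
large-strain nonlinear solve with explicit stiff fibres produces
substantially higher stresses, so user-supplied micro-stress histories can
be passed for direct criterion evaluation instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import presets
from .synthetic import SyntheticConfig, generate_damage_microfield
from .viscoelastic import PronyRelaxation, TimeSeries, ramp_stress

__all__ = [
    "RampLoading",
    "FailureCriteria",
    "DamageResult",
    "evaluate_failure",
    "rate_sweep",
    "ramp_stress",
]

#: Default sweep of applied strain rates (1/s).
DEFAULT_RATES = (10.0, 20.0, 30.0, 40.0, 50.0)


@dataclass(frozen=True)
class RampLoading:
    """Constant strain-rate ramp along one Voigt direction."""

    rate: float
    direction: int = 3
    eps_max: float = 0.12  # solver-convergence-style cap on axon strain

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("strain rate must be positive")
        if not 1 <= self.direction <= 6:
            raise ValueError("direction must be a Voigt component 1..6")
        if self.eps_max <= 0:
            raise ValueError("strain cap must be positive")

    @property
    def t_end(self) -> float:
        return self.eps_max / self.rate


@dataclass(frozen=True)
class FailureCriteria:
    """Fibre failure strains (engineering, dimensionless)."""

    eps_tau_fail: float = presets.EPS_TAU_FAIL
    eps_MT_fail: float = presets.EPS_MT_FAIL

    def __post_init__(self) -> None:
        for v in (self.eps_tau_fail, self.eps_MT_fail):
            if not 0.0 < v < 1.0:
                raise ValueError("failure strains must lie in (0, 1)")


@dataclass(frozen=True)
class DamageResult:
    """Failure point of one rate: which fibre failed, when, at what state."""

    rate: float
    failing_component: str  # "TAU" | "MT" | "none"
    axon_failure_strain: float
    axon_failure_stress: float
    time_of_failure: float


def _first_crossing(ts: TimeSeries, threshold: float) -> float | None:
    """Earliest time the series reaches ``threshold`` (linear interpolation)."""
    v, t = ts.values, ts.times
    idx = np.nonzero(v >= threshold)[0]
    if len(idx) == 0:
        return None
    i = int(idx[0])
    if i == 0 or v[i] == threshold:
        return float(t[i])
    frac = (threshold - v[i - 1]) / (v[i] - v[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def evaluate_failure(
    micro: dict[str, TimeSeries],
    p33: PronyRelaxation,
    r: RampLoading,
    c: FailureCriteria = FailureCriteria(),
) -> DamageResult:
    """Apply the fibre failure criteria to micro-strain histories.

    ``micro`` maps "TAU" and "MT" to their strain histories over the ramp
    (e.g. from the synthetic generator, or exported solver data).  The
    earliest criterion crossing defines failure; if the strain cap is
    reached first the result reports no failing component.
    """
    for key in ("TAU", "MT"):
        if key not in micro:
            raise ValueError(f"micro-strain set lacks the {key} series")
        if micro[key].times[-1] < r.t_end * (1.0 - 1e-9):
            raise ValueError("micro series must cover the ramp duration")
    crossings = {
        "TAU": _first_crossing(micro["TAU"], c.eps_tau_fail),
        "MT": _first_crossing(micro["MT"], c.eps_MT_fail),
    }
    live = {k: t for k, t in crossings.items() if t is not None and t <= r.t_end}
    if not live:
        return DamageResult(r.rate, "none", r.eps_max,
                            float(ramp_stress(p33, r.rate, r.t_end)), r.t_end)
    comp = min(live, key=live.get)
    t_fail = live[comp]
    return DamageResult(
        rate=r.rate,
        failing_component=comp,
        axon_failure_strain=r.rate * t_fail,
        axon_failure_stress=float(ramp_stress(p33, r.rate, t_fail)),
        time_of_failure=t_fail,
    )


def rate_sweep(
    cfg: SyntheticConfig | None = None,
    rates=DEFAULT_RATES,
    criteria: FailureCriteria = FailureCriteria(),
    eps_max: float = 0.12,
) -> pd.DataFrame:
    """Failure strain/stress versus applied strain rate.

    One row per rate with columns ``rate_per_s, failing_component,
    failure_strain, failure_stress_Pa, t_fail_s``.
    """
    cfg = cfg or SyntheticConfig()
    p33 = cfg.truth["C33"]
    rows = []
    for rate in rates:
        r = RampLoading(rate=float(rate), eps_max=eps_max)
        micro = generate_damage_microfield(cfg, r.rate, r.t_end)
        res = evaluate_failure(micro, p33, r, criteria)
        rows.append(
            {
                "rate_per_s": res.rate,
                "failing_component": res.failing_component,
                "failure_strain": res.axon_failure_strain,
                "failure_stress_Pa": res.axon_failure_stress,
                "t_fail_s": res.time_of_failure,
            }
        )
    return pd.DataFrame(rows)
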
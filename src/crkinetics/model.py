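"""One-compartment creatinine kinetics under a constant volume change rate.

The model: creatinine mass balance in a volume of distribution V(t) that
changes linearly, ``V(t) = V0 + (dV/dt)*t``, with a constant generation rate
``Gen`` and a first-order excretion term ``GFR_K * Cr(t)``::

    d/dt [Cr(t) * V(t)] = Gen - GFR_K * Cr(t)

whose closed-form solution is

    Cr(t) = Cr0 + [1 - (V0 / V(t)) ** (1 + GFR_K / (dV/dt))]
                * (Gen / (GFR_K + dV/dt) - Cr0)

Unit conventions follow clinical practice: V0 in litres, dV/dt in L/h,
t in hours, GFR_K in mL/min, Gen in mg/dL*mL/min, Cr0 in mg/dL. Internally
the exponent ``GFR_K/(dV/dt)`` is formed with both flows in L/h, and the
steady-state quotient ``Gen/(GFR_K + dV/dt)`` with both flows in mL/min so
that it comes out in mg/dL. The exact conversion factor between the two
flow units is the rational 50/3 (L/h -> mL/min), i.e. 1000/60.

The general formula has three removable singularities which are handled by
analytic limit branches (see :func:`cr_at_time`): dV/dt -> 0 (classic
fixed-volume kinetics), GFR_K + dV/dt -> 0 (clearance exactly cancelled by
volume loss), and GFR_K = dV/dt = 0 (pure accumulation).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

from .errors import (
    InvalidScenarioError,
    InvalidUnitError,
    NoSteadyStateError,
    VolumeExhaustedError,
)

__all__ = [
    "ML_MIN_PER_L_H",
    "L_H_PER_ML_MIN",
    "FlowRate",
    "KineticScenario",
    "convert_flow",
    "volume_at_time",
    "steady_state_cr",
    "cr_at_time",
    "ode_residual",
]

#: Exact rational conversion: 1 L/h = 1000 mL / 60 min = 50/3 mL/min.
ML_MIN_PER_L_H = 50.0 / 3.0
#: Inverse factor: 1 mL/min = 3/50 L/h.
L_H_PER_ML_MIN = 3.0 / 50.0

#: Half-width of the windows in which the analytic limit branches replace
#: the general closed form (flows in L/h).
_BRANCH_EPS = 1e-8

_UNITS = ("mL/min", "L/h")


@dataclass(frozen=True)
class FlowRate:
    """A flow with an explicit unit tag, either ``mL/min`` or ``L/h``."""

    value: float
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in _UNITS:
            raise InvalidUnitError(
                f"unknown flow unit {self.unit!r}; expected one of {_UNITS}"
            )


def convert_flow(rate: FlowRate, target_unit: str) -> FlowRate:
    """Convert a :class:`FlowRate` between mL/min and L/h.

    The factors are the exact rationals 50/3 and 3/50; converting back and
    forth reproduces the input to machine precision.
    """
    if target_unit not in _UNITS:
        raise InvalidUnitError(
            f"unknown flow unit {target_unit!r}; expected one of {_UNITS}"
        )
    if rate.unit == target_unit:
        return rate
    if rate.unit == "L/h":  # -> mL/min
        return FlowRate(rate.value * 50.0 / 3.0, target_unit)
    return FlowRate(rate.value * 3.0 / 50.0, target_unit)


@dataclass(frozen=True)
class KineticScenario:
    """The six parameters of a kinetic-creatinine scenario.

    Parameters
    ----------
    v0 : float
        Volume of distribution (total body water) at t=0, litres. Must be > 0.
    dvdt : float
        Constant volume change rate, L/h. Negative means net fluid removal
        (e.g. ultrafiltration). Must satisfy ``v0 + dvdt*t > 0``.
    t : float
        Elapsed-time horizon, hours. Must be >= 0.
    gfr_k : float
        Kinetic clearance, mL/min (renal plus any extracorporeal clearance,
        e.g. CRRT). Must be >= 0.
    gen : float
        Creatinine generation rate, mg/dL*mL/min. Must be >= 0.
    cr0 : float
        Initial creatinine concentration, mg/dL. Must be > 0.

    Validation is strict: invalid parameter sets raise rather than clamp.
    """

    v0: float
    dvdt: float
    t: float
    gfr_k: float
    gen: float
    cr0: float

    def __post_init__(self) -> None:
        if not (self.v0 > 0):
            raise InvalidScenarioError(f"v0 must be > 0 (got {self.v0})")
        if not (self.t >= 0):
            raise InvalidScenarioError(f"t must be >= 0 (got {self.t})")
        if not (self.gfr_k >= 0):
            raise InvalidScenarioError(f"gfr_k must be >= 0 (got {self.gfr_k})")
        if not (self.gen >= 0):
            raise InvalidScenarioError(f"gen must be >= 0 (got {self.gen})")
        if not (self.cr0 > 0):
            raise InvalidScenarioError(f"cr0 must be > 0 (got {self.cr0})")
        if not (self.v0 + self.dvdt * self.t > 0):
            raise VolumeExhaustedError(
                f"v0 + dvdt*t = {self.v0 + self.dvdt * self.t} <= 0: "
                f"volume exhausted within the horizon (dvdt <= -v0/t = "
                f"{-self.v0 / self.t if self.t > 0 else '-inf'})"
            )

    @property
    def gfr_k_lh(self) -> float:
        """Kinetic clearance converted to L/h."""
        return self.gfr_k * 3.0 / 50.0

    @property
    def dvdt_mlmin(self) -> float:
        """Volume change rate converted to mL/min."""
        return self.dvdt * 50.0 / 3.0

    @property
    def wall(self) -> float:
        """Leftmost admissible volume rate -v0/t in L/h (-inf when t=0)."""
        return -self.v0 / self.t if self.t > 0 else -math.inf

    def replace(self, **changes) -> "KineticScenario":
        """Return a copy with some fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)


def volume_at_time(s: KineticScenario, t: float | None = None) -> float:
    """V(t) = V0 + (dV/dt)*t in litres; raises if the volume is exhausted."""
    if t is None:
        t = s.t
    if t < 0:
        raise InvalidScenarioError(f"t must be >= 0 (got {t})")
    v = s.v0 + s.dvdt * t
    if v <= 0:
        raise VolumeExhaustedError(
            f"V({t} h) = {v} L <= 0 for dvdt = {s.dvdt} L/h (wall at "
            f"{-s.v0 / t if t > 0 else '-inf'} L/h)"
        )
    return v


def steady_state_cr(s: KineticScenario) -> float:
    """Steady-state creatinine Gen / (GFR_K + dV/dt), mg/dL.

    Both flows are harmonized to mL/min. Only defined when the combined
    clearance-plus-volume-rate is positive.
    """
    denom = s.gfr_k + s.dvdt_mlmin
    if denom <= 0:
        raise NoSteadyStateError(
            f"GFR_K + dV/dt = {denom} mL/min <= 0: no steady state"
        )
    return s.gen / denom


def _log_volume_ratio(s: KineticScenario, t: float) -> float:
    """ln(V0 / V(t)), guarded so the argument is positive."""
    volume_at_time(s, t)  # raises if V(t) <= 0
    # log1p keeps precision when dvdt*t << v0
    return -math.log1p(s.dvdt * t / s.v0)


def _evolution_fraction(s: KineticScenario, t: float) -> float:
    """The time-evolution factor 1 - (V0/V(t))**(1 + GFR_K/(dV/dt)).

    Evaluated as ``1 - exp(exponent * ln(V0/V(t)))`` (log-space power) so a
    fractional power never sees a negative base and large exponents do not
    overflow prematurely. Only valid away from the dvdt -> 0 window.
    """
    expo = 1.0 + s.gfr_k_lh / s.dvdt
    return -math.expm1(expo * _log_volume_ratio(s, t))


def cr_at_time(s: KineticScenario, t: float | None = None) -> float:
    """Serum creatinine Cr(t) in mg/dL from the closed-form trajectory.

    Dispatches to analytic limit branches near the removable singularities:

    * ``|dvdt| < 1e-8`` L/h: classic fixed-volume kinetics,
      ``Cr0 + (1 - exp(-g*t/V0)) * (Gen/GFR_K - Cr0)`` with g = GFR_K in L/h
      (and the pure-accumulation form ``Cr0 + Gen*(3/50)*t/V0`` when GFR_K
      is also ~0);
    * ``|GFR_K + dvdt| < 1e-8`` L/h: the 0*inf product resolves to
      ``Cr0 + (Gen/GFR_K) * ln(V0/V(t))`` with GFR_K in mL/min.
    """
    if t is None:
        t = s.t
    g_lh = s.gfr_k_lh
    if abs(s.dvdt) < _BRANCH_EPS:
        if g_lh < _BRANCH_EPS:
            # no clearance, no volume change: linear accumulation
            return s.cr0 + s.gen * (3.0 / 50.0) * t / s.v0
        return s.cr0 + (-math.expm1(-g_lh * t / s.v0)) * (s.gen / s.gfr_k - s.cr0)
    if abs(g_lh + s.dvdt) < _BRANCH_EPS:
        # clearance exactly balanced by volume loss
        return s.cr0 + (s.gen / s.gfr_k) * _log_volume_ratio(s, t)
    frac = _evolution_fraction(s, t)
    spread = s.gen / (s.gfr_k + s.dvdt_mlmin) - s.cr0
    return s.cr0 + frac * spread


def ode_residual(s: KineticScenario, t: float | None = None, h: float = 1e-3) -> float:
    """Residual of the mass-balance ODE at time ``t``, in mg/dL*L per h.

    Computes a central finite difference of Cr(t)*V(t) in time and subtracts
    the right-hand side ``Gen - GFR_K*Cr(t)`` converted from mg/dL*mL/min to
    mg/dL*L/h (factor 3/50). Serves as the independent correctness oracle
    for every branch of :func:`cr_at_time`; a forward-looking stencil is
    used at t=0.
    """
    if t is None:
        t = s.t
    if h <= 0:
        raise InvalidScenarioError(f"h must be > 0 (got {h})")
    t_lo = max(t - h, 0.0)
    t_hi = t + h

    def mass(tt: float) -> float:
        return cr_at_time(s, tt) * volume_at_time(s, tt)

    dmass = (mass(t_hi) - mass(t_lo)) / (t_hi - t_lo)
    rhs = (s.gen - s.gfr_k * cr_at_time(s, t)) * 3.0 / 50.0
    return dmass - rhs
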
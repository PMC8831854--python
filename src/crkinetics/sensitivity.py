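"""Partial derivatives of Cr(t) with respect to the volume change rate.

Writing u = dV/dt (L/h), G = GFR_K in L/h, c = 50/3, Gm = GFR_K in mL/min,
r = V0/V(t), L = ln r, e = 1 + G/u, y = r**e = exp(e*L), and
S = Gen/(Gm + c*u) - Cr0 (the spread to the would-be steady state), the
trajectory is Cr = Cr0 + (1 - y)*S and differentiating in u gives

    dCr/du   = y*A*S + (1 - y)*S'
    d2Cr/du2 = y*(A' - A**2)*S + 2*y*A*S' + (1 - y)*S''

with

    A  = (G/u**2)*L + e*t/V(t)              # -d(ln y)/du
    A' = -2*G*L/u**3 - 2*G*t/(u**2*V(t)) - e*t**2/V(t)**2
    S' = -Gen*c/(Gm + c*u)**2,   S'' = 2*Gen*c**2/(Gm + c*u)**3

All derivatives are taken with respect to u expressed in L/h, so the first
derivative is in mg/dL per L/h and the second in mg/dL per (L/h)^2. Every
power is formed in log space and every logarithm is guarded: u <= -V0/t
raises :class:`~crkinetics.errors.DomainError` (there the base of the
fractional power turns negative and the derivative is complex-valued).

Near the removable singularity u -> 0 (and near Gm + c*u -> 0) the 1/u**2
and 1/u**3 terms cancel analytically but not in floating point, so inside a
small window the derivatives are instead taken as symmetric finite
differences of :func:`~crkinetics.model.cr_at_time`, whose own limit
branches are exact there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError
from .model import KineticScenario, cr_at_time

__all__ = [
    "SensitivityPoint",
    "first_derivative",
    "second_derivative",
    "fd_first",
    "fd_second",
    "dcr_dgfrk_numeric",
    "sensitivity_point",
]

#: Width of the near-singular windows (L/h) inside which analytic Eq-level
#: cancellation is replaced by finite differences of the trajectory.
_SINGULAR_EPS = 1e-6
#: Symmetric step used for those near-singular finite differences.
_SINGULAR_STEP = 5e-4


@dataclass(frozen=True)
class SensitivityPoint:
    """A sampled point of the derivative-vs-volume-rate curve."""

    dvdt: float  # L/h
    d1: float  # mg/dL per L/h
    d2: float  # mg/dL per (L/h)^2


def _require_domain(s: KineticScenario, u: float) -> None:
    if s.t > 0 and u <= -s.v0 / s.t:
        raise DomainError(
            f"dvdt = {u} L/h is at or below -V0/t = {-s.v0 / s.t}: the "
            "power term has a negative base and the derivative is complex"
        )


def _terms(s: KineticScenario, u: float):
    """Shared building blocks (y, A, A', S, S', S'') at volume rate u."""
    g = s.gfr_k_lh
    vt = s.v0 + u * s.t
    logr = -math.log1p(u * s.t / s.v0)
    e = 1.0 + g / u
    y = math.exp(e * logr)
    tv = s.t / vt
    a = (g / u**2) * logr + e * tv
    ap = -2.0 * g * logr / u**3 - 2.0 * g * tv / u**2 - e * tv * tv
    c = 50.0 / 3.0
    denom = s.gfr_k + c * u
    sp = -s.gen * c / denom**2
    spp = 2.0 * s.gen * c * c / denom**3
    spread = s.gen / denom - s.cr0
    return y, a, ap, spread, sp, spp


def _near_singular(s: KineticScenario, u: float) -> bool:
    return abs(u) < _SINGULAR_EPS or abs(s.gfr_k_lh + u) < _SINGULAR_EPS


def first_derivative(s: KineticScenario, dvdt: float | None = None) -> float:
    """Analytic dCr(t)/d(dV/dt) in mg/dL per L/h, at the given volume rate
    (defaults to the scenario's own)."""
    u = s.dvdt if dvdt is None else dvdt
    _require_domain(s, u)
    if s.t == 0:
        return 0.0
    if _near_singular(s, u):
        h = _SINGULAR_STEP
        return (
            cr_at_time(s.replace(dvdt=u + h)) - cr_at_time(s.replace(dvdt=u - h))
        ) / (2.0 * h)
    y, a, _, spread, sp, _ = _terms(s, u)
    return y * a * spread + (1.0 - y) * sp


def second_derivative(s: KineticScenario, dvdt: float | None = None) -> float:
    """Analytic d2Cr(t)/d(dV/dt)^2 in mg/dL per (L/h)^2."""
    u = s.dvdt if dvdt is None else dvdt
    _require_domain(s, u)
    if s.t == 0:
        return 0.0
    if _near_singular(s, u):
        h = _SINGULAR_STEP
        c0 = cr_at_time(s.replace(dvdt=u))
        return (
            cr_at_time(s.replace(dvdt=u + h))
            - 2.0 * c0
            + cr_at_time(s.replace(dvdt=u - h))
        ) / (h * h)
    y, a, ap, spread, sp, spp = _terms(s, u)
    return y * (ap - a * a) * spread + 2.0 * y * a * sp + (1.0 - y) * spp


def fd_first(s: KineticScenario, dvdt: float, h: float | None = None) -> float:
    """Central finite difference of cr_at_time w.r.t. the volume rate.

    Oracle for :func:`first_derivative`. Default step
    ``h = max(1e-6, 1e-6*|dvdt|)`` balances truncation against cancellation
    at double precision.
    """
    if h is None:
        h = max(1e-6, 1e-6 * abs(dvdt))
    _require_domain(s, dvdt - h)
    return (
        cr_at_time(s.replace(dvdt=dvdt + h)) - cr_at_time(s.replace(dvdt=dvdt - h))
    ) / (2.0 * h)


def fd_second(s: KineticScenario, dvdt: float, h: float | None = None) -> float:
    """Central finite difference of first_derivative; oracle for
    :func:`second_derivative`."""
    if h is None:
        h = max(1e-6, 1e-6 * abs(dvdt))
    _require_domain(s, dvdt - h)
    return (
        first_derivative(s, dvdt + h) - first_derivative(s, dvdt - h)
    ) / (2.0 * h)


def dcr_dgfrk_numeric(s: KineticScenario, h: float = 1e-4) -> float:
    """Central finite difference of Cr(t) with respect to GFR_K (mL/min).

    Used only to check numerically that the sign is negative for every
    valid scenario with t > 0 (the clearance always moves the creatinine
    the opposite way). Falls back to a forward difference when GFR_K < h.
    """
    if s.gfr_k >= h:
        lo, hi = s.gfr_k - h, s.gfr_k + h
    else:
        lo, hi = s.gfr_k, s.gfr_k + h
    return (
        cr_at_time(s.replace(gfr_k=hi)) - cr_at_time(s.replace(gfr_k=lo))
    ) / (hi - lo)


def sensitivity_point(s: KineticScenario, dvdt: float | None = None) -> SensitivityPoint:
    """Bundle (dvdt, d1, d2) at one volume rate."""
    u = s.dvdt if dvdt is None else dvdt
    return SensitivityPoint(u, first_derivative(s, u), second_derivative(s, u))
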
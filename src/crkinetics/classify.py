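"""Sign-regime classification: can the creatinine move *with* the volume
rate?

Two clearance thresholds partition the GFR_K axis for a given
(Gen, Cr0, V0, t):

* ``t_low  = Gen/Cr0 + (V0/t)*(50/3)``   (mL/min)
* ``t_high = 2*(V0/t)*(50/3)``           (mL/min)

In the *bottom* domain (GFR_K < t_low) the derivative curve has neither
extremum and plunges to -inf at the left wall: the first derivative is
always negative, so creatinine and volume rate always move oppositely. In
the *middle* domain (t_low < GFR_K < t_high) the curve keeps only a
minimum and its left tail can diverge to +inf, so a positive derivative is
mathematically possible but requires a volume-removal rate near -V0/t that
would dry up the body water within the horizon — clinically unrealistic.
In the *top* domain (GFR_K > t_high) the curve has an absolute maximum
that can rise above the axis: the verdict is decided by comparing the
patient's Cr0 and Gen against the tangency benchmarks, and the positive
paradox is clinically attainable (classically: a septic patient with a low
generation rate, a high creatinine, and CRRT providing a large clearance).

The classification assumes the *permissive* ordering t_low < t_high;
the opposite ordering has its own exception taxonomy that this package
does not implement, and raises
:class:`~crkinetics.errors.UnsupportedRegimeError`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .critical import locate_extrema, positivity_interval, solve_tangency
from .errors import InvalidScenarioError, NoTangencyError, UnsupportedRegimeError
from .model import KineticScenario
from .sensitivity import first_derivative

__all__ = ["SignClassification", "thresholds", "classify"]

#: Domains of the GFR_K axis, in increasing order of clearance.
BOTTOM, MIDDLE, TOP = "bottom", "middle", "top"


@dataclass(frozen=True)
class SignClassification:
    """Verdict on whether dCr/d(dV/dt) can be positive for a scenario."""

    t_low: float  # mL/min, Gen/Cr0 + V0/t
    t_high: float  # mL/min, 2*V0/t
    permissive: bool  # t_low < t_high
    domain: str  # "bottom" | "middle" | "top"
    dvdt_star: float | None  # L/h, tangency rate (top domain only)
    benchmark_cr0: float | None  # mg/dL
    benchmark_gen: float | None  # mg/dL*mL/min
    can_be_positive: bool
    clinically_unrealistic: bool  # True for the middle-domain left-tail route
    positivity: tuple[float, float] | None  # L/h interval with d1 > 0
    sign_at_actual: int  # sign of d1 at the scenario's own dV/dt
    on_boundary: bool  # GFR_K coincided with a threshold (pushed up)


def thresholds(gen: float, cr0: float, v0: float, t: float) -> tuple[float, float]:
    """The two GFR_K domain thresholds (t_low, t_high) in mL/min.

    ``V0/t`` is a flow in L/h and is converted with the exact 50/3 factor.
    """
    if cr0 <= 0:
        raise InvalidScenarioError(f"cr0 must be > 0 (got {cr0})")
    if v0 <= 0 or t <= 0:
        raise InvalidScenarioError("thresholds require v0 > 0 and t > 0")
    vol_rate = (v0 / t) * (50.0 / 3.0)
    return (gen / cr0 + vol_rate, 2.0 * vol_rate)


def _sign(x: float, tol: float = 0.0) -> int:
    if x > tol:
        return 1
    if x < -tol:
        return -1
    return 0


def classify(s: KineticScenario) -> SignClassification:
    """Run the full sign algorithm for a scenario.

    Bottom domain: always-negative verdict. Middle domain: positivity is
    reachable only through the diverging left tail, so ``can_be_positive``
    is True but flagged clinically unrealistic. Top domain: solve the
    tangency condition, compare the patient's Cr0/Gen to the benchmarks,
    and compute the positivity interval. A GFR_K exactly on a threshold is
    classified into the higher domain and flagged ``on_boundary``.
    """
    t_low, t_high = thresholds(s.gen, s.cr0, s.v0, s.t)
    permissive = t_low < t_high
    g = s.gfr_k
    if not permissive:
        # Gen/Cr0 >= V0/t. Below both thresholds the verdict is still the
        # unambiguous always-negative one; at or above 2*V0/t the domain
        # taxonomy has exceptions this package does not implement.
        if g < t_high:
            domain = BOTTOM
        else:
            raise UnsupportedRegimeError(
                f"threshold order not permissive (t_low={t_low:.4g} >= "
                f"t_high={t_high:.4g} mL/min) with GFR_K={g:.4g} >= 2*V0/t; "
                "the exception taxonomy for this regime is not implemented"
            )
    on_boundary = g == t_low or g == t_high
    if g < min(t_low, t_high):
        domain = BOTTOM
    elif g < t_high:
        domain = MIDDLE  # g == t_low lands here: boundary pushed up
    else:
        domain = TOP

    dvdt_star = b_cr0 = b_gen = None
    interval = None
    unrealistic = False
    if domain == TOP:
        try:
            tang = solve_tangency(s)
            dvdt_star = tang.dvdt_star
            b_cr0 = tang.benchmark_cr0
            b_gen = tang.benchmark_gen
        except NoTangencyError:
            tang = None
        if tang is not None and b_cr0 is not None:
            can_be_positive = s.cr0 > b_cr0
        else:
            cp = locate_extrema(s)
            can_be_positive = cp.max_value is not None and cp.max_value > 0
        if can_be_positive:
            interval = positivity_interval(s)
    elif domain == MIDDLE:
        # positivity only via the left tail diverging toward +inf at -V0/t
        can_be_positive = True
        unrealistic = True
        wall = s.wall
        probe = wall + abs(wall) * 1e-6
        if first_derivative(s, probe) > 0:
            from .critical import _refined_roots  # deterministic scan
            import numpy as np

            grid = wall + np.geomspace(abs(wall) * 1e-6, abs(wall) * (1 - 1e-9), 200)
            roots = _refined_roots(lambda u: first_derivative(s, u), grid, strict=False)
            if roots:
                interval = (wall, roots[0])
    else:
        can_be_positive = False

    sign_at_actual = _sign(first_derivative(s))
    return SignClassification(
        t_low=t_low,
        t_high=t_high,
        permissive=permissive,
        domain=domain,
        dvdt_star=dvdt_star,
        benchmark_cr0=b_cr0,
        benchmark_gen=b_gen,
        can_be_positive=can_be_positive,
        clinically_unrealistic=unrealistic,
        positivity=interval,
        sign_at_actual=sign_at_actual,
        on_boundary=on_boundary,
    )
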
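"""Critical points of the derivative-vs-volume-rate curve and the tangency
machinery.

The first-derivative curve d1(u) = dCr(t)/du over u = dV/dt typically rises
from the left wall at u = -V0/t to an absolute maximum, falls to a relative
minimum, and then climbs asymptotically toward zero. Its extrema are the
roots of the second derivative d2(u). The *tangency* construction finds the
parameter combination at which the curve's maximum touches the x-axis: both
d1 and d2 vanish at the same u. Eliminating the spread term between
``d1(u) = 0`` and ``d2(u) = 0`` leaves a condition in u that involves only
GFR_K, V0 and t (neither Gen nor Cr0):

    2*y*A**2 - (A' - A**2)*(1 - y) - 2*c*(1 - y)*A/(Gm + c*u) = 0

(notation of :mod:`crkinetics.sensitivity`). Once the tangency rate u* is
known, setting d1(u*) = 0 and solving for the remaining free parameter
gives the *benchmark* Cr0 (for a known Gen) or the benchmark Gen (for a
known Cr0); their quotient Gen/Cr0 is a fixed attribute of (GFR_K, V0, t).
A patient whose Cr0 exceeds the benchmark Cr0 — equivalently whose Gen is
below the benchmark Gen — has a derivative maximum above the axis, so the
positive paradox is attainable.

Root finding is deterministic: a fixed scan grid (geometric near the wall,
where the curve varies fastest, linear elsewhere) brackets every sign
change, and each bracket is polished by Brent's method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .errors import (
    DegenerateTangencyError,
    DomainError,
    NoRootError,
    NoTangencyError,
)
from .model import KineticScenario, cr_at_time
from .sensitivity import _terms, first_derivative, second_derivative

__all__ = [
    "CriticalPoints",
    "TangencySolution",
    "find_root",
    "locate_extrema",
    "tangency_dvdt",
    "benchmark_cr0",
    "benchmark_gen",
    "solve_tangency",
    "positivity_interval",
    "crossing_time",
    "catchup_time",
]

#: Root tolerance on the independent variable.
XTOL = 1e-10
#: Acceptance tolerance on the function value at a returned root.
FTOL = 1e-8
#: Iteration cap for the polishing stage.
MAXITER = 200
#: Number of scan-grid points for bracketing.
N_SCAN = 400
#: Right end of the default volume-rate scan range, L/h.
U_MAX = 50.0


@dataclass(frozen=True)
class CriticalPoints:
    """Extrema of the first-derivative curve; fields are ``None`` when the
    corresponding extremum does not exist (it slides off the left wall as
    GFR_K decreases)."""

    max_dvdt: float | None  # L/h
    max_value: float | None  # mg/dL per L/h
    min_dvdt: float | None  # L/h
    min_value: float | None  # mg/dL per L/h


@dataclass(frozen=True)
class TangencySolution:
    """The simultaneous-zero solution and its benchmark parameters."""

    dvdt_star: float  # L/h
    benchmark_cr0: float | None  # mg/dL, given the scenario's Gen
    benchmark_gen: float | None  # mg/dL*mL/min, given the scenario's Cr0
    gen_cr0_ratio: float  # mL/min, fixed by (GFR_K, V0, t)


def find_root(
    f: Callable[[float], float],
    bracket: tuple[float, float],
    tol: float = XTOL,
    ftol: float = FTOL,
) -> float:
    """Root of ``f`` inside a sign-changing bracket (Brent's method).

    Deterministic for fixed inputs; the returned x re-evaluates to
    ``|f(x)| < ftol``, else :class:`NoRootError`.
    """
    a, b = bracket
    fa, fb = f(a), f(b)
    if fa == 0.0:
        return a
    if fb == 0.0:
        return b
    if fa * fb > 0:
        raise NoRootError(f"no sign change of f over [{a}, {b}]")
    x = brentq(f, a, b, xtol=tol, maxiter=MAXITER)
    if abs(f(x)) >= ftol:
        raise NoRootError(f"root polish did not reach |f| < {ftol} at x={x}")
    return float(x)


def _scan_grid(wall: float, u_max: float = U_MAX, n: int = N_SCAN) -> np.ndarray:
    """Deterministic scan grid over the admissible volume rates.

    Geometric spacing of the offset from the wall (where the curve blows
    up) over its first decades, then linear out to ``u_max``. With a
    finite wall the grid starts at ``wall * (1 - 1e-6)`` offset-wise, i.e.
    at wall + |wall|*1e-6.
    """
    if math.isinf(wall):
        return np.linspace(-u_max, u_max, n)
    n_geo = n // 2
    span = u_max - wall
    offsets = np.geomspace(abs(wall) * 1e-6 if wall != 0 else 1e-6, span, n_geo)
    geo = wall + offsets[:-1]
    lin = np.linspace(wall + span * 0.05, u_max, n - n_geo + 1)
    grid = np.unique(np.concatenate([geo, lin]))
    return grid


def _refined_roots(
    f: Callable[[float], float], grid: np.ndarray, strict: bool = True
) -> list[float]:
    """All roots of f bracketed by sign changes on the grid, polished.

    With ``strict=False`` a bracket whose polished point does not pass the
    |f| < FTOL check is silently dropped (used where a scan may graze
    numerically noisy regions; genuine roots are re-verified downstream).
    """
    vals = np.array([f(u) for u in grid])
    roots: list[float] = []
    finite = np.isfinite(vals)
    for i in range(len(grid) - 1):
        if not (finite[i] and finite[i + 1]):
            continue
        if vals[i] == 0.0:
            roots.append(float(grid[i]))
        elif vals[i] * vals[i + 1] < 0:
            try:
                roots.append(find_root(f, (float(grid[i]), float(grid[i + 1]))))
            except NoRootError:
                if strict:
                    raise
    return roots


def locate_extrema(s: KineticScenario, u_max: float = U_MAX) -> CriticalPoints:
    """Extrema of the first-derivative curve over (-V0/t, u_max].

    Scans the second derivative for sign changes and classifies each root:
    d2 going + -> - marks a maximum of the first derivative, - -> + a
    minimum. Absent extrema are encoded as ``None``, not errors.
    """
    if s.t == 0:
        return CriticalPoints(None, None, None, None)
    grid = _scan_grid(s.wall, u_max)
    d2 = lambda u: second_derivative(s, u)
    roots = _refined_roots(d2, grid, strict=False)
    max_u = max_v = min_u = min_v = None
    h = 1e-5
    for r in roots:
        sign_left = d2(r - h)
        if sign_left > 0:  # d1 increasing then decreasing: maximum
            if max_u is None or first_derivative(s, r) > max_v:
                max_u, max_v = r, first_derivative(s, r)
        else:
            if min_u is None or first_derivative(s, r) < min_v:
                min_u, min_v = r, first_derivative(s, r)
    return CriticalPoints(max_u, max_v, min_u, min_v)


def _tangency_equation(gfr_k: float, v0: float, t: float) -> Callable[[float], float]:
    """The Gen/Cr0-free condition whose root makes d1 and d2 vanish
    simultaneously (see module docstring)."""
    c = 50.0 / 3.0
    probe = KineticScenario(v0=v0, dvdt=-1e-9, t=t, gfr_k=gfr_k, gen=1.0, cr0=1.0)

    def f(u: float) -> float:
        y, a, ap, _, _, _ = _terms(probe, u)
        return 2.0 * y * a * a - (ap - a * a) * (1.0 - y) - 2.0 * c * (1.0 - y) * a / (
            gfr_k + c * u
        )

    return f


def tangency_dvdt(gfr_k: float, v0: float, t: float) -> float:
    """Volume rate u* (L/h) at which the derivative curve's maximum is
    tangent to the x-axis, for a given (GFR_K, V0, t).

    Searches (-V0/t, 0); every printed tangency rate is negative, and the
    construction is meaningful in the top domain GFR_K > 2*V0/t. Raises
    :class:`NoTangencyError` when no root exists in that range.
    """
    if t <= 0 or v0 <= 0:
        raise DomainError("tangency requires v0 > 0 and t > 0")
    wall = -v0 / t
    f = _tangency_equation(gfr_k, v0, t)
    offsets = np.geomspace(abs(wall) * 1e-9, abs(wall) * (1.0 - 1e-9), N_SCAN)
    grid = wall + offsets
    roots = _refined_roots(f, grid, strict=False)
    # keep roots at which the benchmark construction really zeroes d1 & d2
    good = []
    for r in roots:
        try:
            c0 = benchmark_cr0(1.0, gfr_k, v0, t, r)
        except DegenerateTangencyError:
            continue
        if c0 <= 0:
            continue
        sc = KineticScenario(v0=v0, dvdt=r, t=t, gfr_k=gfr_k, gen=1.0, cr0=c0)
        if abs(first_derivative(sc)) < FTOL and abs(second_derivative(sc)) < FTOL:
            good.append(r)
    if not good:
        raise NoTangencyError(
            f"no tangency volume rate in ({wall}, 0) for GFR_K={gfr_k}, "
            f"V0={v0}, t={t} (is GFR_K > 2*V0/t = {2 * v0 / t * 50 / 3:.4g} mL/min?)"
        )
    return good[0]


def _bench_terms(gfr_k: float, v0: float, t: float, dvdt_star: float):
    probe = KineticScenario(v0=v0, dvdt=dvdt_star, t=t, gfr_k=gfr_k, gen=1.0, cr0=1.0)
    y, a, _, _, _, _ = _terms(probe, dvdt_star)
    return y, a


def benchmark_cr0(
    gen: float, gfr_k: float, v0: float, t: float, dvdt_star: float
) -> float:
    """Initial creatinine (mg/dL) that places the curve's maximum exactly on
    the x-axis, from d1(u*) = 0 solved for Cr0.

    ``dvdt_star`` must be the tangency rate for (GFR_K, V0, t) — not the
    patient's actual volume rate.
    """
    y, a = _bench_terms(gfr_k, v0, t, dvdt_star)
    c = 50.0 / 3.0
    denom = gfr_k + c * dvdt_star
    if y * a == 0 or denom == 0:
        raise DegenerateTangencyError("singular denominator in benchmark Cr0")
    sp = -gen * c / denom**2
    return gen / denom + (1.0 - y) * sp / (y * a)


def benchmark_gen(
    cr0: float, gfr_k: float, v0: float, t: float, dvdt_star: float
) -> float:
    """Generation rate (mg/dL*mL/min) that places the curve's maximum on the
    x-axis, from d1(u*) = 0 solved for Gen."""
    y, a = _bench_terms(gfr_k, v0, t, dvdt_star)
    c = 50.0 / 3.0
    denom = gfr_k + c * dvdt_star
    if denom == 0:
        raise DegenerateTangencyError("singular denominator in benchmark Gen")
    quot = y * a / denom - (1.0 - y) * c / denom**2
    if quot == 0:
        raise DegenerateTangencyError("singular denominator in benchmark Gen")
    return y * a * cr0 / quot


def solve_tangency(s: KineticScenario) -> TangencySolution:
    """Full tangency solution for a scenario: the tangency rate, both
    benchmarks (from the scenario's own Gen and Cr0), and the fixed
    Gen/Cr0 ratio in mL/min."""
    u_star = tangency_dvdt(s.gfr_k, s.v0, s.t)
    b_cr0 = benchmark_cr0(s.gen, s.gfr_k, s.v0, s.t, u_star) if s.gen > 0 else None
    b_gen = benchmark_gen(s.cr0, s.gfr_k, s.v0, s.t, u_star)
    ratio = b_gen / s.cr0
    return TangencySolution(u_star, b_cr0, b_gen, ratio)


def positivity_interval(
    s: KineticScenario, u_max: float = U_MAX
) -> tuple[float, float] | None:
    """Maximal volume-rate interval on which the first derivative is
    positive, or ``None`` when the curve's maximum is absent or <= 0.

    The endpoints are the two roots of d1 bracketing the positive maximum;
    each re-evaluates to |d1| < 1e-8.
    """
    cp = locate_extrema(s, u_max)
    if cp.max_dvdt is None or cp.max_value is None or cp.max_value <= 0:
        return None
    d1 = lambda u: first_derivative(s, u)
    wall = s.wall
    # left root: between the wall and the maximum
    left_grid = wall + np.geomspace(
        abs(wall) * 1e-9 if math.isfinite(wall) else 1e-9,
        cp.max_dvdt - wall,
        N_SCAN // 2,
    ) if math.isfinite(wall) else np.linspace(cp.max_dvdt - 100.0, cp.max_dvdt, N_SCAN // 2)
    left_roots = [r for r in _refined_roots(d1, left_grid, strict=False) if r < cp.max_dvdt]
    # right root: between the maximum and the far right (d1 -> 0 from below
    # past the minimum, so a sign change exists whenever the max is > 0)
    right_grid = np.linspace(cp.max_dvdt, u_max, N_SCAN // 2)
    right_roots = [r for r in _refined_roots(d1, right_grid, strict=False) if r > cp.max_dvdt]
    if not left_roots or not right_roots:
        return None
    lo, hi = max(left_roots), min(right_roots)
    return (lo, hi)


def _gap(s: KineticScenario, dvdt_a: float, dvdt_b: float) -> Callable[[float], float]:
    sa = s.replace(dvdt=dvdt_a)
    sb = s.replace(dvdt=dvdt_b)
    return lambda tt: cr_at_time(sa, tt) - cr_at_time(sb, tt)


def crossing_time(
    s_base: KineticScenario, dvdt_a: float, dvdt_b: float
) -> float | None:
    """Time in (0, horizon] at which the trajectories for two volume rates
    intersect, or ``None`` when they never cross (t=0, where the curves are
    trivially equal, is excluded; the search starts at 1e-3 h).

    Symmetric in the two rates; equal rates are degenerate and return
    ``None``.
    """
    if dvdt_a == dvdt_b:
        return None
    for u in (dvdt_a, dvdt_b):
        if s_base.v0 + u * s_base.t <= 0:
            raise DomainError(f"dvdt={u} exhausts the volume within the horizon")
    g = _gap(s_base, dvdt_a, dvdt_b)
    grid = np.linspace(1e-3, s_base.t, N_SCAN)
    roots = _refined_roots(g, grid)
    return roots[0] if roots else None


def catchup_time(
    s_base: KineticScenario, dvdt_a: float, dvdt_b: float
) -> float | None:
    """Time at which the gap Cr(t; a) - Cr(t; b) is largest in magnitude,
    i.e. when the trailing trajectory starts to catch up.

    Located as the root of the gap's time derivative (central finite
    difference); ``None`` when there is no interior extremum or the rates
    are equal.
    """
    if dvdt_a == dvdt_b:
        return None
    g = _gap(s_base, dvdt_a, dvdt_b)
    h = 1e-4
    dg = lambda tt: (g(tt + h) - g(tt - h)) / (2.0 * h)
    grid = np.linspace(2 * h, s_base.t - 2 * h, N_SCAN)
    roots = _refined_roots(dg, grid)
    return roots[0] if roots else None
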
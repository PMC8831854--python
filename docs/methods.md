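# Methods

## Model and assumptions

The package implements one-compartment creatinine kinetics with a linearly
changing volume of distribution. The state is the serum creatinine
concentration Cr(t) (mg/dL) in a volume V(t) = V₀ + u·t (L), where
u = ΔV/Δt is a constant volume change rate in L/h. Creatinine enters at a
constant generation rate Gen (mg/dL·mL/min, i.e. mass rate divided by
100 mL/dL so that Gen/clearance is a concentration) and leaves at
GFR_K·Cr(t), where GFR_K (mL/min) is a *kinetic* clearance — any
combination of residual renal function and extracorporeal clearance. The
mass balance d/dt[Cr·V] = Gen − GFR_K·Cr has the closed form

    Cr(t) = Cr₀ + [1 − r^e] · (Gen/(GFR_K + u) − Cr₀),
    r = V₀/V(t),  e = 1 + GFR_K/u.

Assumptions: Gen, GFR_K and u are constant over the horizon; creatinine
distributes instantly in a single well-mixed compartment (total body
water); V(t) stays positive, which bounds u > −V₀/t ("the wall"). Nothing
else changes — the model deliberately isolates the volume-rate effect.

## Units

Flows appear in two unit systems and are harmonized with the exact
rational factor 50/3 (mL/min per L/h): the exponent e uses both flows in
L/h, the steady-state quotient Gen/(GFR_K + u) uses both in mL/min so it
comes out in mg/dL. All derivatives with respect to u are reported per
L/h. Thresholds are reported in mL/min.

## Sensitivity derivatives

With y = r^e, A = −d(ln y)/du, S = Gen/(GFR_K + u) − Cr₀:

    ∂Cr/∂u   = y·A·S + (1 − y)·S′
    ∂²Cr/∂u² = y·(A′ − A²)·S + 2·y·A·S′ + (1 − y)·S″

where A = (G/u²)·ln r + e·t/V(t) (G = GFR_K in L/h),
A′ = −2G·ln r/u³ − 2G·t/(u²V(t)) − e·t²/V(t)², and S′, S″ are elementary.
These compact factored forms are this package's own differentiation of
the closed form; correctness is established against central
finite-difference oracles (relative 10⁻⁶ for the first derivative, 10⁻⁵
for the second, with a 10⁻⁹/10⁻⁸ absolute floor where the curve passes
through zero) and against the mass-balance residual, rather than against
any transcribed expanded expression.

## Numerical choices

* **Log-space powers.** r^e is always computed as exp(e·ln r) with
  ln r = −log1p(u·t/V₀); the domain guard V(t) > 0 runs first, so a
  fractional power never sees a negative base. At or below the wall the
  derivative is complex-valued and the library raises a domain error.
* **Removable singularities.** The closed form is analytic in u but its
  textbook expression is 0·∞ at u = 0 and at GFR_K + u = 0 (flows in
  L/h). Inside windows of half-width 10⁻⁸ L/h the trajectory dispatches
  to the analytic limits: the classic fixed-volume single exponential
  (u → 0), Cr₀ + (Gen/GFR_K)·ln(V₀/V(t)) (clearance cancelled by volume
  loss), and linear accumulation Cr₀ + Gen·(3/50)·t/V₀ (both zero). The
  derivative formulas contain 1/u² and 1/u³ terms that cancel
  analytically but not in floating point, so inside wider windows of
  10⁻⁶ L/h the derivatives fall back to symmetric finite differences of
  the trajectory (step 5·10⁻⁴ L/h), which is accurate there because the
  trajectory itself is branch-exact.
* **Root finding.** All roots come from bracketing plus Brent polish
  (xtol 10⁻¹⁰, iteration cap 200), with a |f| < 10⁻⁸ verification at
  every returned root. Scans use a fixed 400-point grid, geometrically
  spaced in the offset from the wall (where the curve changes fastest)
  and linear out to +50 L/h, so results are deterministic. The tangency
  search is restricted to (−V₀/t, 0), where all published roots lie;
  candidate roots are kept only if the reconstructed benchmark scenario
  really zeroes both derivatives below 10⁻⁸ — this also discards
  spurious sign flips where the tangency expression is evaluated in its
  numerically noisy near-zero region.
* **Degenerate inputs.** Scenario validation is strict (reject, never
  clamp). Equal volume rates make crossing/catch-up times degenerate and
  return absent rather than zero. A GFR_K exactly on a domain threshold
  is classified into the higher domain and flagged `on_boundary`; the
  underlying inequalities are strict and equality is a measure-zero case
  the source taxonomy never addresses.

## Tangency and benchmarks

Setting ∂Cr/∂u = 0 and ∂²Cr/∂u² = 0 simultaneously and eliminating S
yields a condition free of Gen and Cr₀:

    2yA² − (A′ − A²)(1 − y) − 2c(1 − y)A/(GFR_K + c·u) = 0,  c = 50/3,

whose root u* depends only on (GFR_K, V₀, t). Back-substituting u* into
∂Cr/∂u = 0 gives the benchmark Cr₀ for a known Gen, or the benchmark Gen
for a known Cr₀; Gen/Cr₀ at tangency is therefore a fixed ratio for a
given (GFR_K, V₀, t). A patient above the benchmark Cr₀ (below the
benchmark Gen) has a derivative maximum above the axis.

## Classifier

Two thresholds partition the clearance axis: t_low = Gen/Cr₀ + (V₀/t)·c
and t_high = 2(V₀/t)·c, both mL/min. In the permissive order
t_low < t_high: below t_low the derivative curve has no extrema and is
negative everywhere (bottom); between them only a minimum survives and
positivity exists solely through a left tail diverging at the wall, which
is reported `can_be_positive=True` but flagged clinically unrealistic
(the required removal rate would exhaust total body water within the
horizon); above t_high the absolute maximum exists and the
benchmark comparison decides (top). In the non-permissive order the
domain taxonomy has exceptions whose treatment is not available to this
package: scenarios below both thresholds are still classified
bottom/always-negative (that regime is unambiguous, and the canonical
AKI example lives there); at or above 2V₀/t an `UnsupportedRegimeError`
is raised rather than guessing.

## Worked-example fixtures

`paper_scenarios()` encodes the study conditions: the AKI case (Gen=100,
Cr₀=1, GFR_K=20), the Gen-family (10–100 at Cr₀=8, GFR_K=100), the
Cr₀-family (2–10 at Gen=60), the GFR_K-family (90 down to 30 at Gen=60,
Cr₀=8, straddling both thresholds), and the CRRT case (Gen=40, Cr₀=8,
GFR_K=80, baseline u=−0.1 L/h); all share V₀=42 L, t=24 h. These are
exact parameter sets, not synthetic data: the model is deterministic, so
tests exercise closed-form evaluation and root-finding, not statistical
recovery. What passing tests do *not* show is anything about real
patients — measurement noise, time-varying clearance or generation, and
multi-compartment distribution are all outside the model.

## Problem sizes

Everything is desk-scale: scan grids of 400 points, property sweeps of
100–200 random scenarios, finite-difference oracles at single points. The
full suite plus the acceptance script runs in a few seconds on one CPU.

## Known limitations

* Constant GFR_K, Gen and u only; no noise model and no inference.
* The non-permissive threshold order above 2V₀/t is unsupported (see
  above).
* Left-wall behaviour is evaluated only down to offsets of ~10⁻⁹·V₀/t;
  the divergence toward ±∞ is checked as a trend, not a limit.
* The middle-domain positivity interval is reported from a wall-side
  scan; exceptions in which the left tail does not diverge are not
  modelled.
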
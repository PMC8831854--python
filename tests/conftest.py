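import numpy as np
import pytest

from crkinetics import KineticScenario, paper_scenarios


@pytest.fixture(scope="session")
def fig5():
    """Septic CRRT case: V0=42 L, Gen=40, Cr0=8 mg/dL, GFR_K=80 mL/min,
    baseline ultrafiltration -0.1 L/h over 24 h."""
    return paper_scenarios()["fig5_crrt"]


@pytest.fixture(scope="session")
def fig1():
    """AKI case whose derivative is negative for every volume rate."""
    return paper_scenarios()["fig1_aki"]


@pytest.fixture(scope="session")
def tangency_family():
    """Curve family of the tangency worked example: Cr0=8, GFR_K=100."""
    return KineticScenario(v0=42.0, dvdt=-0.5, t=24.0, gfr_k=100.0, gen=70.0, cr0=8.0)


def random_scenarios(
    rng: np.random.Generator,
    n: int,
    dvdt_margin: float = 0.0,
    gfr_min: float = 0.0,
):
    """Draw n valid scenarios over clinically plausible ranges.

    ``dvdt_margin`` keeps the volume rate away from 0 and from -GFR_K (in
    L/h) by at least that much, so tests of the analytic derivative paths
    do not straddle the finite-difference fallback windows.
    """
    out = []
    while len(out) < n:
        v0 = rng.uniform(25.0, 55.0)
        t = rng.uniform(6.0, 48.0)
        gfr_k = rng.uniform(gfr_min, 150.0)
        gen = rng.uniform(0.0, 150.0)
        cr0 = rng.uniform(0.5, 14.0)
        wall = -v0 / t
        dvdt = rng.uniform(0.85 * wall, 2.0)
        if dvdt_margin > 0:
            if abs(dvdt) < dvdt_margin:
                continue
            if abs(gfr_k * 3.0 / 50.0 + dvdt) < dvdt_margin:
                continue
        out.append(KineticScenario(v0=v0, dvdt=dvdt, t=t, gfr_k=gfr_k, gen=gen, cr0=cr0))
    return out
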
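"""Exception hierarchy.

All library errors derive from :class:`CrKineticsError` so callers can catch
one base class. Domain violations (inputs outside the model's mathematical
domain) and convergence failures (root finder gave up) are kept distinct
because the CLI maps them to different exit codes.
"""


class CrKineticsError(Exception):
    """Base class for all crkinetics errors."""


class InvalidUnitError(CrKineticsError, ValueError):
    """Unknown flow-rate unit tag."""


class InvalidScenarioError(CrKineticsError, ValueError):
    """Scenario parameters violate a physiological invariant."""


class VolumeExhaustedError(InvalidScenarioError):
    """V0 + (dV/dt)*t <= 0: the volume of distribution would be used up
    within the time horizon (dV/dt <= -V0/t)."""


class NoSteadyStateError(CrKineticsError):
    """GFR_K + dV/dt <= 0 in harmonized units: no finite steady-state
    creatinine exists for these parameters."""


class DomainError(CrKineticsError):
    """Evaluation requested outside the mathematical domain, e.g. a
    volume rate at or below -V0/t where the power term turns complex."""


class NoRootError(CrKineticsError):
    """Root finder found no sign change / did not converge."""


class NoTangencyError(NoRootError):
    """The tangency equation has no root in the searched volume-rate range."""


class DegenerateTangencyError(CrKineticsError):
    """Benchmark closed form hit a singular denominator."""


class UnsupportedRegimeError(CrKineticsError):
    """Threshold ordering Gen/Cr0 + V0/t < 2*V0/t does not hold; the
    exception taxonomy for that regime is out of scope."""
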
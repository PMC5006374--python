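"""Exception hierarchy."""


class WelchPlanError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(WelchPlanError, ValueError):
    """A design, cost model, or allocation violates an invariant."""


class InfeasibleDesignError(WelchPlanError):
    """The power target cannot be reached (e.g. psi equals the null value)."""


class ConvergenceError(WelchPlanError):
    """The continuous optimizer failed to produce a feasible solution."""


class DegenerateSampleError(WelchPlanError):
    """All observations relevant to the contrast are constant (zero variance)."""
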
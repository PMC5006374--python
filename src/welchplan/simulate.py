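"""Monte Carlo estimation of the true power of the Welch-Satterthwaite test.

For each replication the engine draws N_ij independent normal variates per
cell from the design's means and variances, applies the level-alpha
Welch-Satterthwaite test of H0: psi = psi_0, and reports the rejection
proportion together with its binomial standard error and the difference from
the noncentral-t approximate power.  The per-replication test is vectorized
across replications but is formula-identical to
:func:`welchplan.inference.welch_satterthwaite_test` (a parity test in the
suite checks bitwise-equal rejection decisions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import Allocation, DesignSpec, approximate_power
from .errors import InvalidDesignError

__all__ = ["SimulationSettings", "SimulationResult", "simulate_power"]


@dataclass(frozen=True)
class SimulationSettings:
    """replications: number of synthetic data sets; alpha: overrides the
    design's level when not None."""

    replications: int = 10_000
    seed: int = 0
    alpha: float | None = None

    def __post_init__(self):
        if self.replications < 1:
            raise InvalidDesignError("replications must be >= 1")
        if self.alpha is not None and not 0 < self.alpha < 1:
            raise InvalidDesignError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass(frozen=True)
class SimulationResult:
    simulated_power: float
    mc_standard_error: float
    approximate_power: float
    error: float          # simulated - approximate
    rejections: int
    replications: int


def simulate_power(
    spec: DesignSpec, alloc: Allocation, settings: SimulationSettings | None = None
) -> SimulationResult:
    """Estimate the test's true power at an integer allocation.

    Deterministic given ``settings.seed`` (cell streams are drawn in flat cell
    order from a single numpy Generator).

    Raises
    ------
    InvalidDesignError
        If the allocation is not integer-valued.
    """
    settings = settings or SimulationSettings()
    if not alloc.is_integer:
        raise InvalidDesignError("Monte Carlo simulation requires integer cell sizes")
    alpha = settings.alpha if settings.alpha is not None else spec.alpha
    reps = settings.replications
    sizes = alloc.as_int().ravel()
    mu = spec.means.ravel()
    sd = np.sqrt(spec.variances).ravel()
    L = spec.contrast.ravel()

    rng = np.random.default_rng(settings.seed)
    means = np.empty((reps, 4))
    variances = np.empty((reps, 4))
    for k in range(4):
        draws = rng.normal(mu[k], sd[k], size=(reps, sizes[k]))
        means[:, k] = draws.mean(axis=1)
        variances[:, k] = draws.var(axis=1, ddof=1)

    omega2 = (L**2 * variances / sizes).sum(axis=1)
    psi_hat = means @ L
    statistic = (psi_hat - spec.null_value) / np.sqrt(omega2)
    df_hat = omega2**2 / (L**4 * variances**2 / (sizes**2 * (sizes - 1.0))).sum(axis=1)
    critical = stats.t.ppf(1.0 - alpha / 2.0, df_hat)
    rejections = int(np.count_nonzero(np.abs(statistic) > critical))

    p = rejections / reps
    approx = approximate_power(spec, alloc).power
    return SimulationResult(
        simulated_power=p,
        mc_standard_error=float(np.sqrt(p * (1.0 - p) / reps)),
        approximate_power=approx,
        error=p - approx,
        rejections=rejections,
        replications=reps,
    )
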
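"""The Welch-Satterthwaite test applied to raw 2x2 factorial samples.

Given observations in the four cells, the contrast estimate is
``psi_hat = sum_ij L_ij Xbar_ij`` with estimated variance
``omega_hat^2 = sum_ij L_ij^2 S_ij^2 / N_ij``.  The statistic
``T* = (psi_hat - psi_0)/omega_hat`` is referred to a t distribution whose
degrees of freedom ``nu_hat`` plug the sample variances into the Satterthwaite
formula.  H0: psi = psi_0 is rejected at level alpha when
``|T*| > t_{nu_hat, alpha/2}``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import as_contrast
from .errors import DegenerateSampleError, InvalidDesignError

__all__ = ["FactorialSample", "TestOutcome", "contrast_estimate", "welch_satterthwaite_test"]


@dataclass(frozen=True)
class FactorialSample:
    """Raw observations, one variable-length vector per cell.

    ``cells`` is a tuple of four 1-D float arrays in (1,1),(1,2),(2,1),(2,2)
    order; every cell needs at least two observations.
    """

    cells: tuple

    def __post_init__(self):
        if len(self.cells) != 4:
            raise InvalidDesignError("a factorial sample needs exactly 4 cells")
        arrays = []
        for k, cell in enumerate(self.cells):
            arr = np.asarray(cell, dtype=float).ravel()
            if arr.size < 2:
                raise InvalidDesignError(
                    f"cell {k} ((i,j) = {divmod(k, 2)[0] + 1},{k % 2 + 1}) has "
                    f"{arr.size} observation(s); at least 2 are required"
                )
            if not np.all(np.isfinite(arr)):
                raise InvalidDesignError(f"cell {k} contains non-finite observations")
            arrays.append(arr)
        object.__setattr__(self, "cells", tuple(arrays))

    @property
    def sizes(self) -> np.ndarray:
        return np.array([c.size for c in self.cells]).reshape(2, 2)

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean() for c in self.cells]).reshape(2, 2)

    @property
    def variances(self) -> np.ndarray:
        """Unbiased (ddof=1) sample variances S_ij^2."""
        return np.array([c.var(ddof=1) for c in self.cells]).reshape(2, 2)


@dataclass(frozen=True)
class TestOutcome:
    """Result of the data-level Welch-Satterthwaite test."""

    estimate: float       # psi_hat
    statistic: float      # T*
    df_estimate: float    # nu_hat
    critical_value: float # t_{nu_hat, alpha/2}
    p_value: float
    reject: bool


def contrast_estimate(sample: FactorialSample, contrast) -> float:
    """Unbiased estimate psi_hat = sum_ij L_ij Xbar_ij."""
    L = as_contrast(contrast)
    return float(np.sum(L * sample.means))


def welch_satterthwaite_test(
    sample: FactorialSample,
    contrast,
    null_value: float = 0.0,
    alpha: float = 0.05,
) -> TestOutcome:
    """Two-sided Welch-Satterthwaite test of H0: psi = psi_0.

    The p-value is reported as 2 P{t(nu_hat) > |T*|}, consistent with the
    rejection rule |T*| > t_{nu_hat, alpha/2}.

    Raises
    ------
    DegenerateSampleError
        If every cell with a nonzero coefficient has zero sample variance, so
        omega_hat = 0 and the statistic is undefined.
    """
    if not 0 < alpha < 1:
        raise InvalidDesignError(f"alpha must be in (0, 1), got {alpha}")
    L = as_contrast(contrast)
    if not np.any(L != 0):
        raise InvalidDesignError("at least one contrast coefficient must be nonzero")
    n = sample.sizes.astype(float)
    s2 = sample.variances
    omega2 = float(np.sum(L**2 * s2 / n))
    if omega2 <= 0:
        raise DegenerateSampleError(
            "all observations relevant to the contrast are constant; "
            "the Welch-Satterthwaite statistic is undefined"
        )
    psi_hat = float(np.sum(L * sample.means))
    statistic = (psi_hat - null_value) / np.sqrt(omega2)
    df_hat = omega2**2 / float(np.sum(L**4 * s2**2 / (n**2 * (n - 1.0))))
    critical = float(stats.t.ppf(1.0 - alpha / 2.0, df_hat))
    p_value = float(2.0 * stats.t.sf(abs(statistic), df_hat))
    return TestOutcome(
        estimate=psi_hat,
        statistic=float(statistic),
        df_estimate=float(df_hat),
        critical_value=critical,
        p_value=p_value,
        reject=bool(abs(statistic) > critical),
    )
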
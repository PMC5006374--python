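"""Domain types and deterministic power/cost mathematics for 2x2 factorial designs.

A 2x2 factorial study observes independent normal responses
``X_ijk ~ N(mu_ij, sigma_ij^2)`` in four treatment cells indexed by the levels
of two factors, with no assumption that the four error variances are equal
(heteroscedasticity).  Scientific hypotheses about main effects and the
interaction are expressed as a linear combination of the cell means,

    psi = sum_ij L_ij * mu_ij,

tested with the Welch-Satterthwaite statistic, whose nonnull distribution is
approximately noncentral t with degrees of freedom nu given by the
Satterthwaite formula evaluated at the population variances.  This module
implements that approximation: the effect psi, the variance of its estimator
omega^2, the degrees of freedom nu, the approximate power

    pi(delta) = P{ |t(nu, delta)| > t_{nu, alpha/2} },    delta = (psi - psi_0)/omega,

and the linear study cost ``C_T = C_O + sum_ij C_ij * N_ij``.

Cells are indexed row-major: the flat order is (1,1), (1,2), (2,1), (2,2),
where the first index is the level of factor A and the second of factor B.
All four-element inputs (means, variances, contrasts, sizes, costs) accept
either a 2x2 array or a length-4 sequence in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InvalidDesignError

__all__ = [
    "CONTRASTS",
    "DesignSpec",
    "CostModel",
    "Allocation",
    "PowerResult",
    "effect_size",
    "estimator_variance",
    "satterthwaite_df",
    "approximate_power",
    "total_cost",
]

#: Named contrast presets.  ``interaction`` is mu11 - mu12 - mu21 + mu22,
#: ``main_a`` compares the two levels of factor A (mu11 + mu12 - mu21 - mu22),
#: ``main_b`` the two levels of factor B (mu11 - mu12 + mu21 - mu22).
CONTRASTS: dict[str, np.ndarray] = {
    "interaction": np.array([[1.0, -1.0], [-1.0, 1.0]]),
    "main_a": np.array([[1.0, 1.0], [-1.0, -1.0]]),
    "main_b": np.array([[1.0, -1.0], [1.0, -1.0]]),
}


def as_contrast(values) -> np.ndarray:
    """Coerce a contrast given as coefficients or a preset name to (2, 2)."""
    if isinstance(values, str):
        try:
            values = CONTRASTS[values]
        except KeyError:
            raise InvalidDesignError(
                f"unknown contrast preset {values!r}; "
                f"choose from {sorted(CONTRASTS)} or give coefficients"
            ) from None
    return as_cells(values, "contrast")


def as_cells(values, name: str = "value") -> np.ndarray:
    """Coerce a 2x2 array or length-4 row-major sequence to a float (2, 2) array."""
    arr = np.asarray(values, dtype=float)
    if arr.shape == (4,):
        arr = arr.reshape(2, 2)
    if arr.shape != (2, 2):
        raise InvalidDesignError(
            f"{name} must be a 2x2 array or a length-4 sequence in "
            f"(1,1),(1,2),(2,1),(2,2) order; got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise InvalidDesignError(f"{name} contains non-finite entries")
    return arr


@dataclass(frozen=True)
class DesignSpec:
    """Planning values for a heteroscedastic 2x2 factorial design.

    Parameters
    ----------
    means : array-like
        Cell means ``mu_ij`` (response-scale units), 2x2 or flat row-major.
    variances : array-like
        Cell error variances ``sigma_ij^2`` (squared response units), all > 0.
    contrast : array-like or str
        Contrast coefficients ``L_ij``, or one of the :data:`CONTRASTS` preset
        names (``"interaction"``, ``"main_a"``, ``"main_b"``).
    null_value : float
        Null effect ``psi_0`` of H0: psi = psi_0.
    alpha : float
        Two-sided significance level, in (0, 1).
    target_power : float
        Desired power ``1 - beta``, in (0, 1).
    """

    means: np.ndarray
    variances: np.ndarray
    contrast: np.ndarray = field(default="interaction")
    null_value: float = 0.0
    alpha: float = 0.05
    target_power: float = 0.80

    def __post_init__(self):
        object.__setattr__(self, "means", as_cells(self.means, "means"))
        object.__setattr__(self, "variances", as_cells(self.variances, "variances"))
        object.__setattr__(self, "contrast", as_contrast(self.contrast))
        if np.any(self.variances <= 0):
            raise InvalidDesignError("all cell variances must be strictly positive")
        if not np.any(self.contrast != 0):
            raise InvalidDesignError("at least one contrast coefficient must be nonzero")
        if not 0 < self.alpha < 1:
            raise InvalidDesignError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.target_power < 1:
            raise InvalidDesignError(
                f"target_power must be in (0, 1), got {self.target_power}"
            )

    @classmethod
    def from_sds(cls, means, sds, **kwargs) -> "DesignSpec":
        """Build a spec from cell standard deviations instead of variances."""
        sds = as_cells(sds, "sds")
        if np.any(sds <= 0):
            raise InvalidDesignError("all cell standard deviations must be positive")
        return cls(means=means, variances=sds**2, **kwargs)

    @property
    def effect(self) -> float:
        """The planned effect psi = sum_ij L_ij mu_ij."""
        return float(np.sum(self.contrast * self.means))


@dataclass(frozen=True)
class CostModel:
    """Linear study cost: overhead C_O plus per-subject unit costs C_ij."""

    unit_costs: np.ndarray = field(default_factory=lambda: np.ones((2, 2)))
    overhead: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "unit_costs", as_cells(self.unit_costs, "unit_costs"))
        if np.any(self.unit_costs <= 0):
            raise InvalidDesignError("every unit cost must be strictly positive")
        if self.overhead < 0:
            raise InvalidDesignError("overhead cost must be nonnegative")


@dataclass(frozen=True)
class Allocation:
    """Per-cell sample sizes N_ij.

    Sizes may be fractional: the continuous stage of the cost optimizer
    evaluates the power function at non-integer allocations.  Every cell needs
    N_ij >= 2 so that each sample variance has at least one degree of freedom.
    """

    sizes: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "sizes", as_cells(self.sizes, "sizes"))
        if np.any(self.sizes < 2):
            raise InvalidDesignError(
                f"every cell size must be >= 2, got {self.sizes.ravel().tolist()}"
            )

    @property
    def flat(self) -> np.ndarray:
        """Sizes as a flat length-4 vector in (1,1),(1,2),(2,1),(2,2) order."""
        return self.sizes.ravel()

    @property
    def is_integer(self) -> bool:
        return bool(np.all(self.sizes == np.floor(self.sizes)))

    @property
    def total(self) -> float:
        return float(self.sizes.sum())

    def as_int(self) -> np.ndarray:
        if not self.is_integer:
            raise InvalidDesignError(f"allocation {self.flat.tolist()} is not integer")
        return self.sizes.astype(int)


@dataclass(frozen=True)
class PowerResult:
    """Approximate-power evaluation at one allocation.

    Attributes
    ----------
    df : float
        Satterthwaite degrees of freedom nu (population variances).
    noncentrality : float
        delta = (psi - psi_0) / omega.
    power : float
        pi(delta) = P{|t(nu, delta)| > t_{nu, alpha/2}}.
    effect : float
        psi.
    variance_of_estimator : float
        omega^2 = Var(psi_hat).
    """

    df: float
    noncentrality: float
    power: float
    effect: float
    variance_of_estimator: float


def effect_size(spec: DesignSpec) -> float:
    """Return the linear combination of cell means psi = sum_ij L_ij mu_ij."""
    return spec.effect


def estimator_variance(spec: DesignSpec, alloc: Allocation) -> float:
    """Return omega^2 = Var(psi_hat) = sum_ij L_ij^2 sigma_ij^2 / N_ij."""
    return float(np.sum(spec.contrast**2 * spec.variances / alloc.sizes))


def _satterthwaite_df_flat(variances, contrast, sizes):
    """Vectorized nu over a trailing axis of flat size vectors (..., 4)."""
    sizes = np.asarray(sizes, dtype=float)
    l2s2 = (contrast**2 * variances).ravel()
    l4s4 = l2s2**2
    num = np.sum(l2s2 / sizes, axis=-1) ** 2
    den = np.sum(l4s4 / (sizes**2 * (sizes - 1.0)), axis=-1)
    return num / den


def satterthwaite_df(spec: DesignSpec, alloc: Allocation) -> float:
    """Welch-Satterthwaite degrees of freedom at population variances.

    nu = (sum L^2 s^2 / N)^2 / sum L^4 s^4 / [N^2 (N - 1)].  With equal
    variances, |L_ij| all equal, and a balanced allocation of n per cell this
    reduces to 4(n - 1).  Fractional N are allowed (N_ij > 1 required).
    """
    if np.any(alloc.sizes <= 1):
        raise InvalidDesignError("satterthwaite_df requires every N_ij > 1")
    return float(_satterthwaite_df_flat(spec.variances, spec.contrast, alloc.flat))


def power_at_sizes(spec: DesignSpec, sizes) -> np.ndarray:
    """Approximate power at one or many flat size vectors (vectorized over (..., 4)).

    Where scipy's noncentral-t CDF overflows to NaN (very large df), the
    normal limit t(nu, delta) -> N(delta, 1) is substituted.
    """
    sizes = np.asarray(sizes, dtype=float)
    omega2 = np.sum((spec.contrast**2 * spec.variances).ravel() / sizes, axis=-1)
    delta = (spec.effect - spec.null_value) / np.sqrt(omega2)
    df = _satterthwaite_df_flat(spec.variances, spec.contrast, sizes)
    tcrit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
    power = stats.nct.sf(tcrit, df, delta) + stats.nct.cdf(-tcrit, df, delta)
    bad = ~np.isfinite(power)
    if np.any(bad):
        zcrit = stats.norm.ppf(1.0 - spec.alpha / 2.0)
        limit = stats.norm.sf(zcrit - delta) + stats.norm.cdf(-zcrit - delta)
        power = np.where(bad, limit, power)
    return power


def approximate_power(spec: DesignSpec, alloc: Allocation) -> PowerResult:
    """Approximate power of the two-sided Welch-Satterthwaite test.

    The test statistic is approximately t(nu, delta) with nu from
    :func:`satterthwaite_df` and delta = (psi - psi_0)/omega, so

        pi(delta) = P{t(nu, delta) > t_{nu, alpha/2}}
                    + P{t(nu, delta) < -t_{nu, alpha/2}}.

    At delta = 0 this equals alpha (the size of the test).  Continuous
    allocations are accepted.
    """
    df = satterthwaite_df(spec, alloc)
    omega2 = estimator_variance(spec, alloc)
    delta = (spec.effect - spec.null_value) / np.sqrt(omega2)
    power = float(power_at_sizes(spec, alloc.flat))
    return PowerResult(
        df=df,
        noncentrality=delta,
        power=power,
        effect=spec.effect,
        variance_of_estimator=omega2,
    )


def total_cost(cost: CostModel, alloc: Allocation) -> float:
    """Return C_T = C_O + sum_ij C_ij N_ij."""
    return float(cost.overhead + np.sum(cost.unit_costs * alloc.sizes))
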
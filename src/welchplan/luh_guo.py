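"""Two-step normal/t sample-size allocation of Luh and Guo, for comparison.

This earlier procedure fixes the allocation ratios at the normal-theory
optimum r_ij = (sigma_ij / sigma_11) * sqrt(C_11 / C_ij) (cell sizes
proportional to the cell standard deviation divided by the square root of the
unit cost), then sizes the design in two passes:

1. *Normal stage*: with w^2 = sum_ij L_ij^2 sigma_ij^2 / r_ij, the anchor size
   is N_Z11 = (z_{alpha/2} + z_beta)^2 w^2 / (psi - psi_0)^2 and
   N_Zij = N_Z11 r_ij, kept fractional.
2. *t stage*: approximate degrees of freedom upsilon are computed by the
   Satterthwaite formula at the fractional {N_Zij}; the anchor is re-sized with
   t quantiles, N_T11 = (t_{upsilon,alpha/2} + t_{upsilon,beta})^2 w^2 /
   (psi - psi_0)^2, N_Tij = N_T11 r_ij, and the final integer sizes are
   N_LGij = floor(N_Tij) + 1.

The procedure never evaluates the noncentral-t power function and rounds each
cell independently, so its result is generally not cost-optimal; the
systematic optimizer in :mod:`welchplan.allocation` is the recommended method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import CostModel, DesignSpec, _satterthwaite_df_flat
from .errors import InfeasibleDesignError

__all__ = ["LuhGuoTrace", "allocation_ratios", "luh_guo_sizes"]


@dataclass(frozen=True)
class LuhGuoTrace:
    """Every intermediate of the two-step calculation, for auditability."""

    ratios: np.ndarray              # r_ij, r_11 = 1
    w_squared: float
    normal_stage_sizes: np.ndarray  # fractional {N_Zij}
    df_stage: float                 # upsilon
    t_stage_sizes: np.ndarray       # fractional {N_Tij}
    final_sizes: np.ndarray         # integer {N_LGij}


def allocation_ratios(spec: DesignSpec, cost: CostModel) -> np.ndarray:
    """Normal-theory allocation ratios r_ij = (sigma_ij/sigma_11) sqrt(C_11/C_ij)."""
    sd = np.sqrt(spec.variances)
    c = cost.unit_costs
    return (sd / sd[0, 0]) * np.sqrt(c[0, 0] / c)


def luh_guo_sizes(
    spec: DesignSpec, cost: CostModel, rounding: str = "plus_one"
) -> LuhGuoTrace:
    """Run the two-step comparator and return its full trace.

    Parameters
    ----------
    spec, cost
        Design planning values and unit costs.
    rounding : {"plus_one", "ceiling"}
        Final integer rule.  ``"plus_one"`` (default) is the literal
        floor(N_T) + 1, which yields N + 1 when N_T is an exact integer;
        ``"ceiling"`` is the true ceiling.

    Raises
    ------
    InfeasibleDesignError
        If psi equals the null value (no effect to size for).
    """
    if rounding not in ("plus_one", "ceiling"):
        raise ValueError(f"rounding must be 'plus_one' or 'ceiling', got {rounding!r}")
    effect = spec.effect - spec.null_value
    if effect == 0:
        raise InfeasibleDesignError(
            "psi equals the null value; no finite sample size attains the target power"
        )
    alpha, beta = spec.alpha, 1.0 - spec.target_power
    r = allocation_ratios(spec, cost)
    w2 = float(np.sum(spec.contrast**2 * spec.variances / r))

    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(1.0 - beta)
    nz11 = (z_a + z_b) ** 2 * w2 / effect**2
    nz = nz11 * r

    upsilon = float(_satterthwaite_df_flat(spec.variances, spec.contrast, nz.ravel()))
    t_a = stats.t.ppf(1.0 - alpha / 2.0, upsilon)
    t_b = stats.t.ppf(1.0 - beta, upsilon)
    nt11 = (t_a + t_b) ** 2 * w2 / effect**2
    nt = nt11 * r

    if rounding == "plus_one":
        final = np.floor(nt).astype(int) + 1
    else:
        final = np.ceil(nt).astype(int)
    final = np.maximum(final, 2)

    return LuhGuoTrace(
        ratios=r,
        w_squared=w2,
        normal_stage_sizes=nz,
        df_stage=upsilon,
        t_stage_sizes=nt,
        final_sizes=final,
    )
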
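"""Built-in worked examples and their reference-table reproduction.

Two planning scenarios ship with the package:

* ``asthma`` — a 2x2 study of asthma attack context (recent/stable) by panic
  fear (low/high), with planning means {1.23, 0.42, 0.13, 0.38}, variances
  {0.6889, 0.5184, 0.1156, 0.5929}, and per-subject emergency-service unit
  costs C_U = {784.74, 267.96, 82.94, 242.44} (or equal costs C_E).  All three
  standard contrasts are of interest (psi_I = 1.06, psi_A = 1.14,
  psi_B = 0.56).
* ``graded`` — a hypothetical design with means {1, 0, 0, 1} and strongly
  graded variances {1, 4, 9, 16}, interaction effect psi_I = 2, exercised
  under six unit-cost patterns.

Both use alpha = 0.05, target power 0.8, psi_0 = 0, zero overhead.
``reference_scenarios`` enumerates the twelve (design, cost) combinations and
``reproduce_reference_tables`` recomputes the optimizer and comparator rows
for each.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .allocation import OptimizerSettings, optimize_allocation
from .design import Allocation, CostModel, DesignSpec, total_cost
from .luh_guo import luh_guo_sizes
from .simulate import SimulationSettings, simulate_power

__all__ = [
    "asthma_design",
    "asthma_costs",
    "graded_variance_design",
    "graded_variance_costs",
    "reference_scenarios",
    "reproduce_reference_tables",
]


def asthma_design(contrast: str = "interaction") -> DesignSpec:
    """Asthma attack-context by panic-fear planning example."""
    return DesignSpec(
        means=[1.23, 0.42, 0.13, 0.38],
        variances=[0.6889, 0.5184, 0.1156, 0.5929],
        contrast=contrast,
        null_value=0.0,
        alpha=0.05,
        target_power=0.80,
    )


def asthma_costs() -> dict[str, CostModel]:
    """Unequal (C_U) and equal (C_E) unit-cost structures for the asthma example."""
    return {
        "C_U": CostModel(unit_costs=[784.74, 267.96, 82.94, 242.44]),
        "C_E": CostModel(unit_costs=[1.0, 1.0, 1.0, 1.0]),
    }


def graded_variance_design() -> DesignSpec:
    """Hypothetical interaction design with variances graded 1:4:9:16."""
    return DesignSpec(
        means=[1.0, 0.0, 0.0, 1.0],
        variances=[1.0, 4.0, 9.0, 16.0],
        contrast="interaction",
        null_value=0.0,
        alpha=0.05,
        target_power=0.80,
    )


def graded_variance_costs() -> list[CostModel]:
    """The six unit-cost patterns exercised with the graded-variance design."""
    patterns = [
        [1, 1, 1, 1],
        [1, 2, 3, 4],
        [4, 3, 2, 1],
        [1, 1, 2, 5],
        [5, 2, 1, 1],
        [1, 3, 3, 1],
    ]
    return [CostModel(unit_costs=np.asarray(p, float)) for p in patterns]


def reference_scenarios() -> list[tuple[str, DesignSpec, CostModel]]:
    """All twelve built-in (label, design, cost) scenarios."""
    out = []
    costs = asthma_costs()
    for contrast in ("interaction", "main_a", "main_b"):
        for cname, cm in costs.items():
            out.append((f"asthma/{contrast}/{cname}", asthma_design(contrast), cm))
    for cm in graded_variance_costs():
        label = "graded/" + "".join(str(int(c)) for c in cm.unit_costs.ravel())
        out.append((label, graded_variance_design(), cm))
    return out


def _fmt_sizes(sizes) -> str:
    return "{" + ", ".join(str(int(v)) for v in np.ravel(sizes)) + "}"


def reproduce_reference_tables(
    simulate: bool = False,
    seed: int = 0,
    replications: int = 10_000,
    settings: OptimizerSettings | None = None,
) -> pd.DataFrame:
    """Recompute both methods' rows for every built-in scenario.

    Returns one row per (scenario, method) with the allocation, total cost,
    total sample size, and approximate power; with ``simulate=True`` the Monte
    Carlo power and its difference from the approximation are appended.
    """
    rows = []
    for idx, (label, spec, cm) in enumerate(reference_scenarios()):
        res = optimize_allocation(spec, cm, settings)
        lg = luh_guo_sizes(spec, cm)
        lg_alloc = Allocation(lg.final_sizes.astype(float))
        from .design import approximate_power  # local to avoid cycle at import

        for method, alloc, cost_val in (
            ("proposed", res.optimal, res.total_cost),
            ("luh_guo", lg_alloc, total_cost(cm, lg_alloc)),
        ):
            row = {
                "scenario": label,
                "method": method,
                "sizes": _fmt_sizes(alloc.sizes),
                "total_cost": cost_val,
                "total_n": int(alloc.total),
                "approx_power": approximate_power(spec, alloc).power,
            }
            if simulate:
                sim = simulate_power(
                    spec,
                    alloc,
                    SimulationSettings(
                        replications=replications, seed=seed + 1000 * idx
                    ),
                )
                row["simulated_power"] = sim.simulated_power
                row["error"] = sim.error
            rows.append(row)
    return pd.DataFrame(rows)
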
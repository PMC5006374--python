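"""Run configuration (YAML) and long-format CSV reading.

A run configuration is a small YAML document; four-cell arrays are written in
(1,1),(1,2),(2,1),(2,2) order.  Example::

    design:
      means: [1.23, 0.42, 0.13, 0.38]
      variances: [0.6889, 0.5184, 0.1156, 0.5929]   # or sds: [...]
      contrast: interaction      # preset name or 4 coefficients
      null_value: 0.0
      alpha: 0.05
      target_power: 0.8
    cost:
      overhead: 0.0
      unit_costs: [784.74, 267.96, 82.94, 242.44]
    methods: [proposed, luh_guo]
    simulation:                  # optional
      replications: 10000
      seed: 1
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .design import CostModel, DesignSpec
from .errors import InvalidDesignError
from .inference import FactorialSample
from .simulate import SimulationSettings

__all__ = ["RunConfig", "load_config", "save_config", "read_long_csv"]

_METHODS = ("proposed", "luh_guo")


@dataclass(frozen=True)
class RunConfig:
    design: DesignSpec
    cost: CostModel = field(default_factory=CostModel)
    methods: tuple = _METHODS
    simulation: SimulationSettings | None = None

    def __post_init__(self):
        bad = [m for m in self.methods if m not in _METHODS]
        if bad:
            raise InvalidDesignError(
                f"unknown method(s) {bad}; choose from {list(_METHODS)}"
            )


def _design_from_mapping(d: dict) -> DesignSpec:
    if not isinstance(d, dict):
        raise InvalidDesignError("config section 'design' must be a mapping")
    kwargs = {
        k: d[k] for k in ("contrast", "null_value", "alpha", "target_power") if k in d
    }
    if "means" not in d:
        raise InvalidDesignError("design.means is required")
    if "sds" in d and "variances" in d:
        raise InvalidDesignError("give design.sds or design.variances, not both")
    if "sds" in d:
        return DesignSpec.from_sds(d["means"], d["sds"], **kwargs)
    if "variances" not in d:
        raise InvalidDesignError("design.variances (or design.sds) is required")
    return DesignSpec(means=d["means"], variances=d["variances"], **kwargs)


def _config_from_mapping(doc: dict) -> RunConfig:
    if not isinstance(doc, dict) or "design" not in doc:
        raise InvalidDesignError("config must be a mapping with a 'design' section")
    design = _design_from_mapping(doc["design"])
    cost_doc = doc.get("cost") or {}
    cost = CostModel(
        unit_costs=cost_doc.get("unit_costs", [1.0, 1.0, 1.0, 1.0]),
        overhead=float(cost_doc.get("overhead", 0.0)),
    )
    sim = None
    if doc.get("simulation"):
        s = doc["simulation"]
        sim = SimulationSettings(
            replications=int(s.get("replications", 10_000)),
            seed=int(s.get("seed", 0)),
            alpha=s.get("alpha"),
        )
    methods = tuple(doc.get("methods", list(_METHODS)))
    return RunConfig(design=design, cost=cost, methods=methods, simulation=sim)


def load_config(path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _config_from_mapping(doc)


def save_config(config: RunConfig, path) -> None:
    """Write a configuration back to YAML (round-trips through load_config)."""
    doc = {
        "design": {
            "means": config.design.means.ravel().tolist(),
            "variances": config.design.variances.ravel().tolist(),
            "contrast": config.design.contrast.ravel().tolist(),
            "null_value": config.design.null_value,
            "alpha": config.design.alpha,
            "target_power": config.design.target_power,
        },
        "cost": {
            "overhead": config.cost.overhead,
            "unit_costs": config.cost.unit_costs.ravel().tolist(),
        },
        "methods": list(config.methods),
    }
    if config.simulation is not None:
        doc["simulation"] = {
            "replications": config.simulation.replications,
            "seed": config.simulation.seed,
        }
        if config.simulation.alpha is not None:
            doc["simulation"]["alpha"] = config.simulation.alpha
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_long_csv(path) -> FactorialSample:
    """Read a long-format CSV (columns factorA, factorB, response) into cells.

    Factor levels must be 1 or 2; every one of the four cells needs at least
    two rows.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("factorA", "factorB", "response") if c not in df.columns]
    if missing:
        raise InvalidDesignError(f"CSV is missing column(s): {', '.join(missing)}")
    resp = pd.to_numeric(df["response"], errors="coerce")
    if resp.isna().any():
        row = int(resp.index[resp.isna()][0]) + 2  # 1-based incl. header
        raise InvalidDesignError(f"non-numeric response value at CSV line {row}")
    cells = []
    for i in (1, 2):
        for j in (1, 2):
            sel = resp[(df["factorA"] == i) & (df["factorB"] == j)]
            if len(sel) < 2:
                raise InvalidDesignError(
                    f"cell ({i},{j}) has {len(sel)} observation(s); need at least 2"
                )
            cells.append(sel.to_numpy(dtype=float))
    known = df["factorA"].isin((1, 2)) & df["factorB"].isin((1, 2))
    if not known.all():
        bad = df.loc[~known, ["factorA", "factorB"]].iloc[0].tolist()
        raise InvalidDesignError(f"unknown factor levels {bad}; levels must be 1 or 2")
    return FactorialSample(cells=tuple(cells))
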
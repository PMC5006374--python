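import numpy as np
import pytest

import welchplan as wp


@pytest.fixture(scope="session")
def asthma_interaction():
    return wp.asthma_design("interaction")


@pytest.fixture(scope="session")
def graded_design():
    return wp.graded_variance_design()


@pytest.fixture(scope="session")
def unequal_costs():
    return wp.asthma_costs()["C_U"]


@pytest.fixture(scope="session")
def equal_costs():
    return wp.CostModel(unit_costs=np.ones(4))


@pytest.fixture(scope="session")
def reference_results():
    """Optimizer + comparator output for all 12 built-in scenarios, computed once."""
    out = {}
    for label, spec, cm in wp.reference_scenarios():
        res = wp.optimize_allocation(spec, cm)
        lg = wp.luh_guo_sizes(spec, cm)
        out[label] = (spec, cm, res, lg)
    return out
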
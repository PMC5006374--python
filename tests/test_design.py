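"""Core power/cost mathematics: effect, estimator variance, df, power, cost."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import welchplan as wp

MEANS = [1.23, 0.42, 0.13, 0.38]
VARS = [0.6889, 0.5184, 0.1156, 0.5929]


@pytest.mark.parametrize(
    "contrast,expected",
    [("interaction", 1.06), ("main_a", 1.14), ("main_b", 0.56)],
)
def test_effect_size_of_standard_contrasts(contrast, expected):
    spec = wp.DesignSpec(means=MEANS, variances=VARS, contrast=contrast)
    assert wp.effect_size(spec) == pytest.approx(expected, abs=1e-12)


def test_effect_size_zero_for_equal_means():
    spec = wp.DesignSpec(means=[3.0] * 4, variances=[1.0] * 4, contrast="interaction")
    assert wp.effect_size(spec) == pytest.approx(0.0, abs=1e-12)


def test_all_zero_contrast_rejected():
    with pytest.raises(wp.InvalidDesignError):
        wp.DesignSpec(means=MEANS, variances=VARS, contrast=[0, 0, 0, 0])


@pytest.mark.parametrize(
    "bad",
    [
        dict(variances=[1, 1, 0, 1]),
        dict(variances=[1, 1, -2, 1]),
        dict(alpha=0.0),
        dict(alpha=1.0),
        dict(target_power=1.0),
    ],
)
def test_invalid_design_parameters_rejected(bad):
    kwargs = dict(means=MEANS, variances=VARS, contrast="interaction")
    kwargs.update(bad)
    with pytest.raises(wp.InvalidDesignError):
        wp.DesignSpec(**kwargs)


def test_estimator_variance_equal_sizes():
    spec = wp.DesignSpec(means=[0, 0, 0, 0], variances=[1, 4, 9, 16],
                         contrast="interaction")
    alloc = wp.Allocation([10, 10, 10, 10])
    assert wp.estimator_variance(spec, alloc) == pytest.approx(3.0, rel=1e-14)


def test_estimator_variance_hand_summation():
    # independent term-by-term summation, fixed before wiring the formula
    spec = wp.DesignSpec(means=MEANS, variances=VARS, contrast="interaction")
    alloc = wp.Allocation([11, 16, 13, 19])
    expected = 0.6889 / 11 + 0.5184 / 16 + 0.1156 / 13 + 0.5929 / 19
    assert wp.estimator_variance(spec, alloc) == pytest.approx(expected, rel=1e-14)


def test_estimator_variance_halves_when_sizes_double():
    spec = wp.DesignSpec(means=MEANS, variances=VARS, contrast="interaction")
    a1 = wp.Allocation([11, 16, 13, 19])
    a2 = wp.Allocation([22, 32, 26, 38])
    assert wp.estimator_variance(spec, a2) == pytest.approx(
        wp.estimator_variance(spec, a1) / 2, rel=1e-14
    )


@pytest.mark.parametrize("n", [2, 5, 20, 100])
def test_satterthwaite_df_balanced_equal_variance_closed_form(n):
    spec = wp.DesignSpec(means=[0, 0, 0, 0], variances=[2.5] * 4,
                         contrast="interaction")
    df = wp.satterthwaite_df(spec, wp.Allocation([n] * 4))
    assert df == pytest.approx(4 * (n - 1), rel=1e-12)


def test_satterthwaite_df_independent_arithmetic():
    # spreadsheet-style evaluation of the two sums, written out term by term
    s2 = np.array([1.0, 4.0, 9.0, 16.0])
    n = np.array([20.0, 40.0, 60.0, 79.0])
    num = (1 / 20 + 4 / 40 + 9 / 60 + 16 / 79) ** 2
    den = (
        1.0 / (20**2 * 19)
        + 16.0 / (40**2 * 39)
        + 81.0 / (60**2 * 59)
        + 256.0 / (79**2 * 78)
    )
    spec = wp.DesignSpec(means=[1, 0, 0, 1], variances=s2, contrast="interaction")
    df = wp.satterthwaite_df(spec, wp.Allocation(n))
    assert df == pytest.approx(num / den, rel=1e-12)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    s2=st.lists(st.floats(0.05, 50.0), min_size=4, max_size=4),
    sizes=st.lists(st.integers(2, 80), min_size=4, max_size=4),
    coeffs=st.lists(st.sampled_from([-2.0, -1.0, 1.0, 2.0]), min_size=4, max_size=4),
)
def test_satterthwaite_df_bounds(s2, sizes, coeffs):
    """nu lies between min(N-1) and sum(N-1) over cells with nonzero weight."""
    spec = wp.DesignSpec(means=[0, 0, 0, 0], variances=s2, contrast=coeffs)
    n = np.asarray(sizes, float)
    df = wp.satterthwaite_df(spec, wp.Allocation(n))
    active = np.asarray(coeffs) != 0
    assert min(n[active] - 1) - 1e-9 <= df <= sum(n[active] - 1) + 1e-9


def test_power_matches_reference_allocations(asthma_interaction, graded_design):
    res1 = wp.approximate_power(asthma_interaction, wp.Allocation([11, 16, 13, 19]))
    assert res1.power == pytest.approx(0.8005, abs=5e-5)
    res2 = wp.approximate_power(graded_design, wp.Allocation([20, 40, 60, 79]))
    assert res2.power == pytest.approx(0.8016, abs=5e-5)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    s2=st.lists(st.floats(0.1, 20.0), min_size=4, max_size=4),
    sizes=st.lists(st.integers(2, 60), min_size=4, max_size=4),
    alpha=st.floats(0.005, 0.2),
)
def test_power_equals_alpha_under_null(s2, sizes, alpha):
    """Size of the test: pi(0) = alpha to 1e-10 for any configuration."""
    spec = wp.DesignSpec(means=[1.0, 1.0, 1.0, 1.0], variances=s2,
                         contrast="interaction", alpha=alpha)
    res = wp.approximate_power(spec, wp.Allocation(sizes))
    assert res.noncentrality == 0.0
    assert res.power == pytest.approx(alpha, abs=1e-10)


def test_power_strictly_increasing_in_each_cell_size(graded_design):
    base = np.array([8.0, 12.0, 16.0, 20.0])
    p0 = wp.approximate_power(graded_design, wp.Allocation(base)).power
    for k in range(4):
        bumped = base.copy()
        bumped[k] += 1
        assert wp.approximate_power(graded_design, wp.Allocation(bumped)).power > p0


def test_power_invariant_to_contrast_negation(asthma_interaction):
    alloc = wp.Allocation([11, 16, 13, 19])
    neg = wp.DesignSpec(
        means=asthma_interaction.means,
        variances=asthma_interaction.variances,
        contrast=-asthma_interaction.contrast,
    )
    a = wp.approximate_power(asthma_interaction, alloc)
    b = wp.approximate_power(neg, alloc)
    assert b.noncentrality == pytest.approx(-a.noncentrality, rel=1e-12)
    assert b.power == pytest.approx(a.power, rel=1e-12)


def test_fractional_allocations_supported(asthma_interaction):
    res = wp.approximate_power(asthma_interaction, wp.Allocation([10.5, 15.2, 12.8, 18.1]))
    assert 0 < res.power < 1 and res.df > 0


def test_allocation_floor_enforced():
    with pytest.raises(wp.InvalidDesignError):
        wp.Allocation([1, 10, 10, 10])


def test_total_cost_reference_and_unit_cases(asthma_interaction, unequal_costs):
    assert wp.total_cost(unequal_costs, wp.Allocation([11, 16, 13, 19])) == pytest.approx(
        18604.08, abs=5e-3
    )
    equal = wp.CostModel(unit_costs=np.ones(4))
    assert wp.total_cost(equal, wp.Allocation([56, 49, 23, 52])) == 180
    overhead = wp.CostModel(unit_costs=np.ones(4), overhead=100.0)
    assert wp.total_cost(overhead, wp.Allocation([2, 2, 2, 2])) == 108
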
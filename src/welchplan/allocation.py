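"""Cost-minimal sample-size allocation under a power constraint.

The optimal-allocation problem is

    minimize    C_T(N) = C_O + sum_ij C_ij N_ij
    subject to  pi(delta(N)) >= 1 - beta,   N_ij >= 2,

where pi is the approximate noncentral-t power of the Welch-Satterthwaite
test.  No closed form exists in general, so the search proceeds in stages:

1. *Continuous relaxation*: treat the N_ij as real numbers and solve the
   smooth constrained program with SLSQP.  The constraint surface is not
   convex, so the solver is multistarted from several allocation-ratio
   directions scaled onto the power boundary by 1-D root finding.
2. *Integer screening*: evaluate power and cost for all 2^4 = 16 floor/ceiling
   roundings of the continuous solution and keep the cheapest feasible one
   (ties broken by largest power, then smallest total size, then
   lexicographically).
3. *Local refinement*: the 16-candidate box can miss the true integer optimum
   when the continuous optimum sits near a fold of the constraint surface, so
   the screened winner is polished by repeated search of the +/-2 integer box
   around the incumbent, accepting strictly cheaper feasible candidates until
   a fixed point.

Every candidate examined in stages 2-3 is recorded in the result's audit
trail.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .design import Allocation, CostModel, DesignSpec, power_at_sizes
from .errors import ConvergenceError, InfeasibleDesignError
from .luh_guo import luh_guo_sizes

__all__ = [
    "OptimizerSettings",
    "Candidate",
    "OptimizationResult",
    "continuous_optimum",
    "screen_integer_candidates",
    "optimize_allocation",
]

# Slack when testing a candidate's power against the target: guards against
# knife-edge exclusion of allocations whose power equals 1 - beta to rounding.
_FEASIBILITY_SLACK = 1e-10


@dataclass(frozen=True)
class OptimizerSettings:
    """Tuning knobs for the allocation search.

    power_tolerance is subtracted from the target when judging feasibility of
    the continuous solution (the screening stage always uses machine slack);
    multistart_count is the number of randomized extra starting directions;
    refine_radius is the half-width of the local integer polishing box
    (0 disables refinement, leaving the literal 16-candidate screen).
    """

    power_tolerance: float = 0.0
    max_iterations: int = 500
    multistart_count: int = 12
    cell_floor: int = 2
    refine_radius: int = 2
    seed: int = 12345

    def __post_init__(self):
        if not 0 <= self.power_tolerance <= 1e-6:
            raise ValueError("power_tolerance must lie in [0, 1e-6]")
        if self.max_iterations < 1 or self.multistart_count < 0:
            raise ValueError("max_iterations >= 1 and multistart_count >= 0 required")
        if self.cell_floor < 2:
            raise ValueError("cell_floor must be at least 2")
        if self.refine_radius < 0:
            raise ValueError("refine_radius must be nonnegative")


@dataclass(frozen=True)
class Candidate:
    """One examined integer allocation."""

    sizes: tuple
    power: float
    cost: float
    feasible: bool
    stage: str  # "screen" or "refine"


@dataclass(frozen=True)
class OptimizationResult:
    continuous_solution: Allocation
    optimal: Allocation
    attained_power: float
    total_cost: float
    total_n: int
    candidates: list = field(default_factory=list)


def _cost_of(cost: CostModel, flat_sizes: np.ndarray) -> np.ndarray:
    return cost.overhead + flat_sizes @ cost.unit_costs.ravel()


def _scale_to_boundary(spec: DesignSpec, direction: np.ndarray, target: float) -> np.ndarray:
    """Scale a positive direction vector so power(max(s*r, 2)) = target."""
    direction = np.maximum(direction, 1e-8)

    def gap(s):
        return float(power_at_sizes(spec, np.maximum(s * direction, 2.0))) - target

    hi = 1.0
    for _ in range(80):
        if gap(hi) >= 0:
            break
        hi *= 2.0
    else:  # pragma: no cover - power -> 1 as sizes grow whenever delta != 0
        raise ConvergenceError("could not bracket the power boundary")
    lo = hi / 2.0
    while gap(lo) > 0 and lo > 1e-8:
        lo /= 2.0
    s = optimize.brentq(gap, lo, hi, xtol=1e-10)
    return np.maximum(s * direction, 2.0)


def _start_directions(spec: DesignSpec, cost: CostModel, settings: OptimizerSettings):
    sd = np.sqrt(spec.variances).ravel()
    c = cost.unit_costs.ravel()
    lg_ratio = sd / np.sqrt(c)
    dirs = [lg_ratio, np.ones(4), sd, 1.0 / c]
    try:  # the comparator's t-stage sizes are usually an excellent start
        dirs.insert(0, luh_guo_sizes(spec, cost).t_stage_sizes.ravel())
    except InfeasibleDesignError:
        pass
    rng = np.random.default_rng(settings.seed)
    for _ in range(settings.multistart_count):
        dirs.append(lg_ratio * np.exp(rng.normal(0.0, 0.5, 4)))
    return dirs


def continuous_optimum(
    spec: DesignSpec, cost: CostModel, settings: OptimizerSettings | None = None
) -> Allocation:
    """Stage 1: minimize cost over real-valued allocations meeting the power target.

    Multistarted SLSQP with the exact (linear) cost gradient; each start lies
    on the power-constraint boundary.  Solutions that end a hair below the
    target (within solver tolerance) are repaired by scaling back onto the
    boundary along their ray, so the returned allocation is always feasible.

    Raises
    ------
    InfeasibleDesignError
        If psi = psi_0, in which case power never exceeds alpha.
    ConvergenceError
        If no start yields a feasible solution.
    """
    settings = settings or OptimizerSettings()
    if spec.effect == spec.null_value:
        raise InfeasibleDesignError(
            "psi equals the null value: power equals alpha at every allocation "
            "and the target power is unattainable"
        )
    target = spec.target_power - settings.power_tolerance
    cvec = cost.unit_costs.ravel()
    floor = float(settings.cell_floor)
    constraints = [
        {"type": "ineq", "fun": lambda n: float(power_at_sizes(spec, n)) - target}
    ]

    best, best_cost = None, np.inf
    for direction in _start_directions(spec, cost, settings):
        try:
            x0 = _scale_to_boundary(spec, np.asarray(direction, float), target)
        except (ConvergenceError, ValueError):
            continue
        res = optimize.minimize(
            lambda n: float(n @ cvec),
            x0,
            jac=lambda n: cvec,
            method="SLSQP",
            bounds=[(floor, None)] * 4,
            constraints=constraints,
            options={"maxiter": settings.max_iterations, "ftol": 1e-12},
        )
        x = np.maximum(res.x, floor)
        if float(power_at_sizes(spec, x)) < target:
            try:  # repair onto the boundary along the ray from the origin
                s = optimize.brentq(
                    lambda s: float(power_at_sizes(spec, np.maximum(s * x, floor)))
                    - target,
                    1.0,
                    8.0,
                    xtol=1e-13,
                )
                x = np.maximum(s * x, floor)
            except ValueError:
                continue
        c = float(x @ cvec)
        if c < best_cost:
            best, best_cost = x, c
    if best is None:
        raise ConvergenceError(
            "continuous optimization failed from every starting point"
        )
    return Allocation(best.reshape(2, 2))


def _rank_key(costs, powers, sizes):
    """Paper ordering: least cost, then largest power, then smallest total N,
    then lexicographic sizes (determinism)."""
    def key(i):
        return (costs[i], -powers[i], sizes[i].sum(), tuple(sizes[i]))
    return key


def screen_integer_candidates(
    spec: DesignSpec,
    cost: CostModel,
    continuous: Allocation,
    settings: OptimizerSettings | None = None,
) -> OptimizationResult:
    """Stage 2: exhaustive screen of the 16 floor/ceiling integer roundings.

    Floors below the cell floor are clamped (duplicates deduplicated).  The
    all-ceiling candidate has power at least that of the feasible continuous
    solution, so a feasible candidate always exists.
    """
    settings = settings or OptimizerSettings()
    floors = np.maximum(np.floor(continuous.flat), settings.cell_floor)
    grid = floors + np.array(list(itertools.product((0.0, 1.0), repeat=4)))
    grid = np.unique(grid, axis=0)
    powers = np.atleast_1d(power_at_sizes(spec, grid))
    costs = _cost_of(cost, grid)
    feasible = powers >= spec.target_power - _FEASIBILITY_SLACK

    candidates = [
        Candidate(
            sizes=tuple(int(v) for v in grid[i]),
            power=float(powers[i]),
            cost=float(costs[i]),
            feasible=bool(feasible[i]),
            stage="screen",
        )
        for i in range(len(grid))
    ]
    feasible_idx = np.where(feasible)[0]
    if feasible_idx.size == 0:  # pragma: no cover - all-ceiling is feasible
        raise ConvergenceError("no feasible candidate in the floor/ceiling screen")
    winner = min(feasible_idx, key=_rank_key(costs, powers, grid.astype(int)))
    best = Allocation(grid[winner].reshape(2, 2))
    return OptimizationResult(
        continuous_solution=continuous,
        optimal=best,
        attained_power=float(powers[winner]),
        total_cost=float(costs[winner]),
        total_n=int(grid[winner].sum()),
        candidates=candidates,
    )


def _refine(spec, cost, settings, sizes0, cost0):
    """Stage 3: iterated +/-radius integer box descent, strict cost improvement."""
    radius = settings.refine_radius
    extra: list[Candidate] = []
    if radius == 0:
        return np.asarray(sizes0, float), float(cost0), extra
    deltas = np.array(
        list(itertools.product(range(-radius, radius + 1), repeat=4)), dtype=float
    )
    current = np.asarray(sizes0, float)
    current_cost = float(cost0)
    for _ in range(200):
        box = np.maximum(current + deltas, settings.cell_floor)
        box = np.unique(box, axis=0)
        costs = _cost_of(cost, box)
        cheaper = costs < current_cost - 1e-9
        if not np.any(cheaper):
            break
        box, costs = box[cheaper], costs[cheaper]
        powers = np.atleast_1d(power_at_sizes(spec, box))
        feas = powers >= spec.target_power - _FEASIBILITY_SLACK
        extra.extend(
            Candidate(
                sizes=tuple(int(v) for v in box[i]),
                power=float(powers[i]),
                cost=float(costs[i]),
                feasible=bool(feas[i]),
                stage="refine",
            )
            for i in range(len(box))
        )
        idx = np.where(feas)[0]
        if idx.size == 0:
            break
        winner = min(idx, key=_rank_key(costs, powers, box.astype(int)))
        current, current_cost = box[winner], float(costs[winner])
    return current, current_cost, extra


def optimize_allocation(
    spec: DesignSpec, cost: CostModel, settings: OptimizerSettings | None = None
) -> OptimizationResult:
    """Full pipeline: continuous relaxation, 16-candidate screen, local polish.

    The returned allocation meets the power target, is the cheapest allocation
    examined, and (with the default refine radius) is a local optimum of the
    integer program in the +/-2 box around itself.
    """
    settings = settings or OptimizerSettings()
    continuous = continuous_optimum(spec, cost, settings)
    screened = screen_integer_candidates(spec, cost, continuous, settings)
    sizes, total, extra = _refine(
        spec, cost, settings, screened.optimal.flat, screened.total_cost
    )
    best = Allocation(sizes.reshape(2, 2))
    return OptimizationResult(
        continuous_solution=continuous,
        optimal=best,
        attained_power=float(power_at_sizes(spec, best.flat)),
        total_cost=float(_cost_of(cost, best.flat)),
        total_n=int(best.total),
        candidates=screened.candidates + extra,
    )
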
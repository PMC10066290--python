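"""Profit objective for the per-state edge-node count and its optimizers.

The profit of deploying k edge nodes (out of a fixed budget K across all
states) trades three terms: delay reduction (proportional to 1/k), the gap
between the state's share of nodes and its share of dangerous bite outcomes,
and the purchase cost of the nodes:

    profit(k) = 1/k - (k/K - (p + d)/n) - C(k)

The maximizer over the integers 1..K is found either exhaustively (the
oracle), by particle swarm optimization, or by quantum-behaved PSO. Both
swarms move in continuous 1-D space; candidate positions are rounded and
clamped to [1, K] at evaluation time so the published update rules apply
unchanged while the answer stays integral.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .synthetic_data import StateEpidemiology


class PlannerError(ValueError):
    pass


@dataclass(frozen=True)
class PlannerProblem:
    budget: int  # K, total nodes across all states
    epi: StateEpidemiology
    cost: Callable[[int], float] = lambda k: 0.0
    delay_constant: float = 1.0

    def __post_init__(self) -> None:
        if self.budget < 1:
            raise PlannerError("budget K must be >= 1")

    @staticmethod
    def with_per_node_cost(budget: int, epi: StateEpidemiology,
                           cost_per_node: float = 0.0,
                           delay_constant: float = 1.0) -> "PlannerProblem":
        if cost_per_node < 0:
            raise PlannerError("cost per node must be >= 0")
        return PlannerProblem(budget=budget, epi=epi,
                              cost=lambda k: cost_per_node * k,
                              delay_constant=delay_constant)


@dataclass(frozen=True)
class SwarmConfig:
    swarm_size: int = 30
    iterations: int = 100
    inertia: float = 0.7
    c1: float = 1.5
    c2: float = 1.5
    alpha: float = 0.7  # contraction-expansion coefficient (QPSO)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise PlannerError("swarm size must be >= 2")
        if self.iterations < 1:
            raise PlannerError("iterations must be >= 1")
        if not (0.0 < self.alpha <= 1.0):
            raise PlannerError("alpha must lie in (0, 1]")
        if not (0.0 <= self.inertia <= 1.0):
            raise PlannerError("inertia must lie in [0, 1]")


@dataclass
class SwarmState:
    positions: np.ndarray  # (s,) continuous positions
    velocities: np.ndarray  # PSO only; zeros for QPSO
    personal_best: np.ndarray
    personal_best_value: np.ndarray
    global_best: float
    global_best_value: float
    bounds: tuple[float, float]
    rng: np.random.Generator = field(repr=False, default=None)


def delay(k: int, delay_constant: float = 1.0) -> float:
    """Hop delay, inversely proportional to the node count."""
    if k < 1:
        raise PlannerError(f"k must be >= 1, got {k}")
    return delay_constant / k


def danger_gap(k: int, K: int, epi: StateEpidemiology) -> float:
    """k/K - (p + d)/n: signed mismatch between node share and danger share."""
    if epi.n == 0:
        raise PlannerError("epidemiology n must be >= 1")
    return k / K - (epi.p + epi.d) / epi.n


def profit(k: int, problem: PlannerProblem) -> float:
    """1/k - danger_gap(k) - C(k), the maximization objective."""
    if not float(k).is_integer() or k < 1:
        raise PlannerError(f"k must be an integer >= 1, got {k!r}")
    k = int(k)
    return 1.0 / k - danger_gap(k, problem.budget, problem.epi) - problem.cost(k)


def _evaluate(objective: Callable[[int], float], position: float,
              bounds: tuple[float, float]) -> float:
    k = int(np.clip(round(position), bounds[0], bounds[1]))
    return objective(k)


def init_swarm(config: SwarmConfig, objective: Callable[[int], float],
               bounds: tuple[float, float]) -> SwarmState:
    rng = np.random.default_rng(config.seed)
    positions = rng.uniform(bounds[0], bounds[1], size=config.swarm_size)
    values = np.array([_evaluate(objective, x, bounds) for x in positions])
    best = int(values.argmax())
    return SwarmState(
        positions=positions,
        velocities=np.zeros(config.swarm_size),
        personal_best=positions.copy(),
        personal_best_value=values.copy(),
        global_best=float(positions[best]),
        global_best_value=float(values[best]),
        bounds=bounds,
        rng=rng)


def _refresh_bests(state: SwarmState, objective: Callable[[int], float]) -> None:
    values = np.array([_evaluate(objective, x, state.bounds)
                       for x in state.positions])
    improved = values > state.personal_best_value
    state.personal_best[improved] = state.positions[improved]
    state.personal_best_value[improved] = values[improved]
    best = int(state.personal_best_value.argmax())
    if state.personal_best_value[best] > state.global_best_value:
        state.global_best = float(state.personal_best[best])
        state.global_best_value = float(state.personal_best_value[best])


def pso_step(state: SwarmState, config: SwarmConfig,
             objective: Callable[[int], float]) -> SwarmState:
    """One velocity/position update with fresh seeded draws per particle."""
    s = len(state.positions)
    phi1 = state.rng.uniform(0.0, 1.0, size=s)
    phi2 = state.rng.uniform(0.0, 1.0, size=s)
    state.velocities = (
        config.inertia * state.velocities
        + config.c1 * phi1 * (state.personal_best - state.positions)
        + config.c2 * phi2 * (state.global_best - state.positions))
    state.positions = np.clip(state.positions + state.velocities,
                              state.bounds[0], state.bounds[1])
    _refresh_bests(state, objective)
    return state


def qpso_step(state: SwarmState, config: SwarmConfig,
              objective: Callable[[int], float]) -> SwarmState:
    """One quantum-behaved update: sample around the local attractor.

    Per particle: attractor PP = phi*P + (1-phi)*Pg; new position
    PP +/- alpha * |m_best - x| * ln(1/u), sign decided by a fair draw,
    where m_best is the mean of all personal bests.
    """
    s = len(state.positions)
    phi = state.rng.uniform(0.0, 1.0, size=s)
    attractors = phi * state.personal_best + (1.0 - phi) * state.global_best
    m_best = float(state.personal_best.mean())
    # u drawn from the open interval so ln(1/u) stays finite
    u = state.rng.uniform(np.finfo(float).tiny, 1.0, size=s)
    b = state.rng.uniform(0.0, 1.0, size=s)
    spread = config.alpha * np.abs(m_best - state.positions) * np.log(1.0 / u)
    sign = np.where(b >= 0.5, 1.0, -1.0)
    state.positions = np.clip(attractors + sign * spread,
                              state.bounds[0], state.bounds[1])
    _refresh_bests(state, objective)
    return state


@dataclass
class PlanResult:
    k_star: int
    best_profit: float
    trace: list[float]
    method: str


def optimize(problem: PlannerProblem, config: SwarmConfig | None = None,
             method: str = "qpso") -> PlanResult:
    """Maximize the profit objective over k in {1..K}.

    ``brute`` scans every k (the oracle); ``pso`` and ``qpso`` run the
    corresponding swarm with round-at-evaluation integer handling. The trace
    records the best profit seen per iteration and is non-decreasing.
    """
    cfg = config or SwarmConfig()
    objective = lambda k: profit(k, problem)  # noqa: E731
    K = problem.budget
    if method == "brute":
        values = [objective(k) for k in range(1, K + 1)]
        best = int(np.argmax(values))
        return PlanResult(k_star=best + 1, best_profit=values[best],
                          trace=[values[best]], method=method)
    if method not in ("pso", "qpso"):
        raise PlannerError(
            f"unknown method {method!r}; options: brute, pso, qpso")
    step = pso_step if method == "pso" else qpso_step
    state = init_swarm(cfg, objective, bounds=(1.0, float(K)))
    trace = [state.global_best_value]
    for _ in range(cfg.iterations):
        state = step(state, cfg, objective)
        trace.append(state.global_best_value)
    k_star = int(np.clip(round(state.global_best), 1, K))
    return PlanResult(k_star=k_star, best_profit=state.global_best_value,
                      trace=trace, method=method)
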
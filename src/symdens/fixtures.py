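"""Tiny model instances with brute-force reference solutions.

The fixtures exist so the dynamic-programming solver can be checked against
an independent oracle: a grid-free recursion over the continuous dynamics
that maximizes over the candidate actions at every step.  The fixture
parameters are chosen so the dynamics are *closed on the state grid*:
``alpha = beta = 1`` makes the next density equal to the (integer)
allocation, and ``mu = 0`` with integer ``omega``, ``N`` and actions keeps
reserves on the integer lattice.  Reproduction is scheduled only at the
horizon, because its proportional reserve drain maps any lattice off
itself; terminal values are evaluated exactly at the nodes, so bilinear
interpolation is exact everywhere and the grid solver is comparable to the
oracle to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import (
    immediate_fitness,
    metabolic_expenditure,
    reproduction_event,
    reserve_transition,
    survival_probability,
    symbiont_transition,
)
from .params import ModelParams, ScenarioConfig
from .solver import StateGrid

__all__ = ["Fixture", "FIXTURE_NAMES", "make_fixture", "brute_force_values"]


def brute_force_value(
    E: float,
    W: float,
    t: int,
    params: ModelParams,
    scenario: ScenarioConfig,
    actions: np.ndarray,
) -> float:
    """Reproductive value by exhaustive recursion over the action tree.

    Operates on exact continuous states (no grid, no interpolation); only
    feasible on very short horizons with few actions.
    """
    E_prime = metabolic_expenditure(E, params)
    E_dprime, W_prime, E_rep, W_rep, _ = reproduction_event(
        E_prime, W, t, params, scenario
    )
    if t == params.T:
        return float(immediate_fitness(E_rep, W_rep, scenario))
    best = -np.inf
    for u in actions:
        W_next = symbiont_transition(W_prime, u, params)
        E_next = reserve_transition(E_dprime, u, params)
        S = survival_probability(E_next, W_next, t, params, scenario)
        B = immediate_fitness(E_rep, W_rep, scenario)
        H = B + S * brute_force_value(E_next, W_next, t + 1, params, scenario, actions)
        if H > best:
            best = H
    return float(best)


def brute_force_values(
    params: ModelParams, scenario: ScenarioConfig, grid: StateGrid
) -> np.ndarray:
    """Oracle value table ``(T, nE, nW)`` at every grid node and time."""
    T = params.T
    out = np.empty((T, len(grid.e_values), len(grid.w_values)))
    for ti in range(T):
        for i, e in enumerate(grid.e_values):
            for j, w in enumerate(grid.w_values):
                out[ti, i, j] = brute_force_value(
                    e, w, ti + 1, params, scenario, grid.u_values
                )
    return out


@dataclass(frozen=True)
class Fixture:
    """A named tiny instance plus its brute-force value table."""

    name: str
    params: ModelParams
    scenario: ScenarioConfig
    grid: StateGrid
    oracle_values: np.ndarray


def _grid_closed_params(T: int) -> ModelParams:
    # alpha=beta=1 => W(t+1)=u exactly; mu=0 and integer omega/N/u keep E on
    # the integer lattice, so every stored successor state is a grid node.
    # Reproduction only at the horizon (its proportional drain would leave
    # the lattice); terminal values are exact at nodes.
    return ModelParams(
        T=T,
        E_max=4.0,
        W_max=4.0,
        E_crit=1.0,
        W_crit=1.0,
        N=2.0,
        mu=0.0,
        omega=1.0,
        alpha=1.0,
        beta=1.0,
        lambda_rep=0.5,
        gamma=0.5,
        repro_first=T,
        repro_interval=2,
        e_grid_step=1.0,
        w_grid_step=1.0,
        u_step=1.0,
    )


_BUILDERS = {
    "tiny-T4": lambda: _grid_closed_params(4),
    "tiny-T6": lambda: _grid_closed_params(6),
}

FIXTURE_NAMES = tuple(_BUILDERS)


def make_fixture(name: str, seed: int = 0) -> Fixture:
    """Build a named fixture and its oracle solution.

    The instances are deterministic; ``seed`` is accepted for interface
    uniformity and regeneration is byte-identical for any value.
    """
    if name not in _BUILDERS:
        raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
    params = _BUILDERS[name]()
    scenario = ScenarioConfig()
    grid = StateGrid.from_params(params)
    values = brute_force_values(params, scenario, grid)
    return Fixture(name=name, params=params, scenario=scenario, grid=grid, oracle_values=values)
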
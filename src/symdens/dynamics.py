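"""Within-time-step dynamics of the host-symbiont model.

Each time step runs six events in a fixed order:

1. metabolic expenditure drains the reserves,
2. reproduction (if scheduled and both state thresholds are met) transfers a
   fraction of reserves and of the symbiont population to offspring,
3. the host feeds, gaining ``N`` units of energy,
4. the host decides the allocation ``u`` of that energy to the symbiont,
5. the symbiont population updates according to ``u`` and its maintenance
   cost,
6. the remaining dietary energy is stored in the reserves.

Survival to the next step increases asymptotically with both post-step
states; the immediate fitness contribution is the product of the energy and
symbiont transferred to offspring.  All functions broadcast over numpy
arrays so the solver and the cohort simulator can evaluate whole state
grids at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Union

import numpy as np

from .params import ModelParams, ScenarioConfig

__all__ = [
    "HostState",
    "StepOutcome",
    "metabolic_expenditure",
    "reproduction_event",
    "symbiont_transition",
    "reserve_transition",
    "survival_probability",
    "immediate_fitness",
    "step",
    "step_arrays",
]

ArrayLike = Union[float, np.ndarray]


@dataclass
class HostState:
    """State of one host at the start of a time step."""

    E: float
    W: float
    t: int
    alive: bool = True


class StepOutcome(NamedTuple):
    """Every intermediate quantity of one composed time step."""

    E_exp: ArrayLike
    E_prime: ArrayLike
    E_dprime: ArrayLike
    E_tprime: ArrayLike
    W_prime: ArrayLike
    W_dprime: ArrayLike
    E_rep: ArrayLike
    W_rep: ArrayLike
    reproduced: ArrayLike
    B: ArrayLike
    S: ArrayLike
    u: ArrayLike


def metabolic_expenditure(E: ArrayLike, params: ModelParams) -> ArrayLike:
    """Reserves after background metabolic expenditure (event 1).

    ``E' = E - (mu E + omega)``.  The result may be negative; it is an
    intermediate value, clamping happens only when the next-step state is
    stored.
    """
    return E - (params.mu * np.asarray(E, dtype=float) + params.omega)


def reproduction_event(
    E_prime: ArrayLike,
    W: ArrayLike,
    t: int,
    params: ModelParams,
    scenario: ScenarioConfig,
):
    """Reproduction (event 2).

    On a scheduled step, hosts with ``E' >= E_crit`` and ``W >= W_crit``
    invest ``E_rep = lambda E'`` and transmit ``W_rep = gamma W`` to
    offspring.  Returns ``(E'', W', E_rep, W_rep, reproduced)``.
    """
    E_prime = np.asarray(E_prime, dtype=float)
    W = np.asarray(W, dtype=float)
    if params.is_reproductive(t):
        w_crit = scenario.effective_w_crit(params)
        reproduced = (E_prime >= params.E_crit) & (W >= w_crit)
    else:
        reproduced = np.zeros(np.broadcast(E_prime, W).shape, dtype=bool)
    E_rep = np.where(reproduced, params.lambda_rep * E_prime, 0.0)
    W_rep = np.where(reproduced, params.gamma * W, 0.0)
    return E_prime - E_rep, W - W_rep, E_rep, W_rep, reproduced


def _check_allocation(u: ArrayLike, params: ModelParams) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or np.any(u > params.N):
        raise ValueError(f"allocation u must lie in [0, {params.N}]")
    return u


def symbiont_transition(W_prime: ArrayLike, u: ArrayLike, params: ModelParams) -> ArrayLike:
    """Symbiont density at the next step (event 5).

    ``W(t+1) = W' + (u - alpha W') beta`` for ``W' > 0``, clamped to
    ``[0, W_max]``; an extinct population (``W' = 0``) stays extinct
    regardless of allocation.
    """
    u = _check_allocation(u, params)
    W_prime = np.asarray(W_prime, dtype=float)
    grown = W_prime + (u - params.alpha * W_prime) * params.beta
    out = np.where(W_prime > 0, np.clip(grown, 0.0, params.W_max), 0.0)
    return out if out.ndim else float(out)


def reserve_transition(E_dprime: ArrayLike, u: ArrayLike, params: ModelParams) -> ArrayLike:
    """Energy reserves at the next step (event 6): ``clamp(E'' + N - u)``."""
    u = _check_allocation(u, params)
    out = np.clip(np.asarray(E_dprime, dtype=float) + params.N - u, 0.0, params.E_max)
    return out if out.ndim else float(out)


def survival_probability(
    E_tprime: ArrayLike,
    W_dprime: ArrayLike,
    t: int,
    params: ModelParams,
    scenario: ScenarioConfig,
) -> ArrayLike:
    """Probability of surviving from ``t`` to ``t + 1``.

    Base case: ``S = (1 - exp(-s E''')) (1 - exp(-s W''))``.  The
    non-essential ecology shifts the density factor by a constant offset;
    the temporary-benefit ecology drops the density factor entirely once the
    host has matured.  Inputs may be negative intermediates; each factor is
    floored at 0 so ``S`` always lies in ``[0, 1]``.
    """
    E_tprime = np.asarray(E_tprime, dtype=float)
    W_dprime = np.asarray(W_dprime, dtype=float)
    f_e = np.maximum(1.0 - np.exp(-params.s * E_tprime), 0.0)
    if scenario.variant == "temporary_benefit" and t >= scenario.maturation_step:
        out = f_e
    else:
        w_eff = W_dprime
        if scenario.variant == "non_essential":
            w_eff = W_dprime + scenario.nonessential_survival_shift
        f_w = np.maximum(1.0 - np.exp(-params.s * w_eff), 0.0)
        out = f_e * f_w
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def immediate_fitness(
    E_rep: ArrayLike,
    W_rep: ArrayLike,
    scenario: ScenarioConfig,
    objective: str | None = None,
    reproduced: ArrayLike | None = None,
) -> ArrayLike:
    """Immediate fitness contribution ``B`` of one time step.

    Host objective: ``B = E_rep W_rep``.  In the non-essential ecology the
    contribution of a reproductive event is ``0.5 E_rep W_rep + 5`` (the
    offset represents the symbiont-independent component of offspring
    fitness and accrues only when reproduction occurs).  Symbiont
    objective: ``B = W_rep``.  ``objective`` overrides the scenario's
    objective; the cohort simulator passes ``"host"`` so lifetime host
    fitness is accounted in host terms even under a symbiont-optimal
    policy.  ``reproduced`` gates the non-essential offset; when omitted it
    is inferred from ``E_rep > 0``.
    """
    obj = scenario.objective if objective is None else objective
    E_rep = np.asarray(E_rep, dtype=float)
    W_rep = np.asarray(W_rep, dtype=float)
    if obj == "symbiont":
        out = W_rep + np.zeros_like(E_rep)
    elif scenario.variant == "non_essential":
        if reproduced is None:
            reproduced = E_rep > 0
        out = np.where(
            reproduced,
            scenario.nonessential_fitness_scale * E_rep * W_rep
            + scenario.nonessential_fitness_offset,
            0.0,
        )
    else:
        out = E_rep * W_rep
    return out if out.ndim else float(out)


def step_arrays(
    E: ArrayLike,
    W: ArrayLike,
    t: int,
    u: ArrayLike,
    params: ModelParams,
    scenario: ScenarioConfig,
    objective: str | None = None,
) -> StepOutcome:
    """Run events 1-6 for (arrays of) states and allocations.

    Deterministic: survival is returned as a probability, not drawn.  The
    next-step states are ``E_tprime`` and ``W_dprime`` (already clamped into
    the state bounds).
    """
    E = np.asarray(E, dtype=float)
    E_prime = metabolic_expenditure(E, params)
    E_exp = E - E_prime
    E_dprime, W_prime, E_rep, W_rep, reproduced = reproduction_event(
        E_prime, W, t, params, scenario
    )
    W_dprime = symbiont_transition(W_prime, u, params)
    E_tprime = reserve_transition(E_dprime, u, params)
    S = survival_probability(E_tprime, W_dprime, t, params, scenario)
    B = immediate_fitness(E_rep, W_rep, scenario, objective=objective, reproduced=reproduced)
    return StepOutcome(
        E_exp=E_exp,
        E_prime=E_prime,
        E_dprime=E_dprime,
        E_tprime=E_tprime,
        W_prime=W_prime,
        W_dprime=W_dprime,
        E_rep=E_rep,
        W_rep=W_rep,
        reproduced=reproduced,
        B=B,
        S=S,
        u=np.asarray(u, dtype=float),
    )


def step(
    state: HostState,
    u: float,
    params: ModelParams,
    scenario: ScenarioConfig | None = None,
) -> StepOutcome:
    """Run one full time step for a single host state.

    Raises if the host is dead or the allocation is infeasible.
    """
    if scenario is None:
        scenario = ScenarioConfig()
    if not state.alive:
        raise ValueError("cannot step a dead host")
    if not 1 <= state.t <= params.T:
        raise ValueError(f"t={state.t} outside horizon 1..{params.T}")
    out = step_arrays(state.E, state.W, state.t, u, params, scenario)
    return StepOutcome(*(np.asarray(x)[()] for x in out))
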
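"""Forward Monte-Carlo simulation of host cohorts.

A cohort covers every initial state on the integer ``(E, W)`` grid
``{1..E_max} x {1..W_max}`` with a fixed number of replicate hosts per
state (10 by default, 4000 hosts in the base case).  Each host iterates the
within-step dynamics under an allocation strategy, accrues its immediate
fitness, and survives to the next step with the step's survival probability
(Bernoulli draw; a deterministic mode skips the draws so every host reaches
the horizon).  Lifetime host fitness is ``V_H = sum_t B(t)`` and symbiont
fitness ``V_S = sum_t W_rep(t)``, summed over the steps the host was alive.

Strategies
----------
optimal / symbiont_optimal
    Interpolated lookup of a solved policy table.
imperfect
    Optimal allocation plus uniform noise of half-width 1, clamped to
    ``[0, N]``.
fixed
    A state-independent constant (default ``u = 3``).
proportional
    ``u = 0.3 W``, clamped to ``[0, N]``.

A single root seed spawns one independent random stream per host, so
results for a given host do not depend on the cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import step_arrays
from .params import ModelParams, ScenarioConfig
from .solver import DPSolution

__all__ = [
    "StrategySpec",
    "PerturbationSpec",
    "CohortResult",
    "decide_allocation",
    "simulate_host",
    "simulate_cohort",
    "simulate_perturbed_cohort",
    "cohort_summary",
]

STRATEGY_KINDS = ("optimal", "imperfect", "fixed", "proportional", "symbiont_optimal")


@dataclass
class StrategySpec:
    """An allocation strategy for forward simulation."""

    kind: str = "optimal"
    fixed_u: float = 3.0
    prop_factor: float = 0.3
    imperfect_halfwidth: float = 1.0
    policy: Optional[DPSolution] = None

    def __post_init__(self) -> None:
        if self.kind not in STRATEGY_KINDS:
            raise ValueError(f"unknown strategy kind {self.kind!r}")
        if self.prop_factor <= 0:
            raise ValueError("prop_factor must be positive")
        if self.needs_policy and self.policy is None:
            raise ValueError(f"strategy {self.kind!r} requires a solved policy table")

    @property
    def needs_policy(self) -> bool:
        return self.kind in ("optimal", "imperfect", "symbiont_optimal")

    @property
    def needs_noise(self) -> bool:
        return self.kind == "imperfect"


@dataclass(frozen=True)
class PerturbationSpec:
    """Reset each surviving host's state to its own t = 1 values at the
    given times (before the step's first event)."""

    times: tuple[int, ...] = (7, 24, 39)

    def validate(self, params: ModelParams) -> None:
        for t in self.times:
            if not 1 <= t <= params.T:
                raise ValueError(f"perturbation time {t} outside horizon 1..{params.T}")


def _allocations(
    strategy: StrategySpec,
    E: np.ndarray,
    W: np.ndarray,
    t: int,
    params: ModelParams,
    noise: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Vectorized allocation decision for all hosts at time ``t``."""
    if strategy.kind == "fixed":
        u = np.full_like(np.asarray(E, dtype=float), strategy.fixed_u)
    elif strategy.kind == "proportional":
        u = strategy.prop_factor * np.asarray(W, dtype=float)
    else:
        u = np.asarray(strategy.policy.allocation(E, W, t), dtype=float)
        if strategy.kind == "imperfect":
            if noise is None:
                raise ValueError("imperfect strategy needs uniform noise draws")
            u = u + (2.0 * noise - 1.0) * strategy.imperfect_halfwidth
    return np.clip(u, 0.0, params.N)


def decide_allocation(
    strategy: StrategySpec,
    state,
    rng: Optional[np.random.Generator] = None,
    params: Optional[ModelParams] = None,
) -> float:
    """Single-host allocation decision (scalar convenience wrapper)."""
    if params is None:
        params = ModelParams()
    if not state.alive:
        raise ValueError("cannot decide for a dead host")
    noise = None
    if strategy.needs_noise:
        if rng is None:
            raise ValueError("imperfect strategy needs an rng")
        noise = rng.random()
    u = _allocations(
        strategy,
        np.asarray(state.E, dtype=float),
        np.asarray(state.W, dtype=float),
        state.t,
        params,
        noise=None if noise is None else np.asarray(noise),
    )
    return float(u)


@dataclass
class CohortResult:
    """Trajectories and lifetime fitnesses of one simulated cohort.

    Trajectory arrays are ``(n_hosts, T)``; entries after a host's death are
    NaN (``alive`` marks the steps a host started alive).  ``E``/``W`` are
    the states at the *start* of each step, ``u``/``B``/``W_rep``/``S`` the
    step's decision and outcomes.
    """

    E0: np.ndarray
    W0: np.ndarray
    E: np.ndarray
    W: np.ndarray
    u: np.ndarray
    B: np.ndarray
    W_rep: np.ndarray
    S: np.ndarray
    alive: np.ndarray
    V_H: np.ndarray
    V_S: np.ndarray
    seed: Optional[int]
    strategy_kind: str
    deterministic: bool
    replicates: int
    params: ModelParams
    scenario: ScenarioConfig

    @property
    def n_hosts(self) -> int:
        return len(self.E0)

    def host(self, i: int) -> dict:
        """Single-host record as a dict of per-step series and fitnesses."""
        return {
            "E0": float(self.E0[i]),
            "W0": float(self.W0[i]),
            "E": self.E[i],
            "W": self.W[i],
            "u": self.u[i],
            "B": self.B[i],
            "W_rep": self.W_rep[i],
            "alive": self.alive[i],
            "V_H": float(self.V_H[i]),
            "V_S": float(self.V_S[i]),
        }

    def fitness_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "host": np.arange(self.n_hosts),
                "E0": self.E0,
                "W0": self.W0,
                "V_H": self.V_H,
                "V_S": self.V_S,
                "lifespan": self.alive.sum(axis=1),
            }
        )

    def trajectory_frame(self) -> pd.DataFrame:
        n, T = self.E.shape
        return pd.DataFrame(
            {
                "host": np.repeat(np.arange(n), T),
                "t": np.tile(np.arange(1, T + 1), n),
                "E": self.E.reshape(-1),
                "W": self.W.reshape(-1),
                "u": self.u.reshape(-1),
                "B": self.B.reshape(-1),
                "W_rep": self.W_rep.reshape(-1),
                "alive": self.alive.reshape(-1),
            }
        )


def _default_initial_states(params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Integer grid {1..E_max} x {1..W_max}; 0 excluded (absorbing/dead)."""
    e0 = np.arange(1, int(params.E_max) + 1, dtype=float)
    w0 = np.arange(1, int(params.W_max) + 1, dtype=float)
    ee, ww = np.meshgrid(e0, w0, indexing="ij")
    return ee.reshape(-1), ww.reshape(-1)


def _host_draws(seed: Optional[int], n: int, T: int) -> np.ndarray:
    """(n, T, 2) uniforms, one independent spawned stream per host."""
    ss = np.random.SeedSequence(0 if seed is None else seed)
    draws = np.empty((n, T, 2))
    for i, child in enumerate(ss.spawn(n)):
        draws[i] = np.random.Generator(np.random.PCG64(child)).random((T, 2))
    return draws


def simulate_cohort(
    strategy: StrategySpec,
    params: ModelParams,
    scenario: ScenarioConfig | None = None,
    *,
    replicates: int = 10,
    seed: Optional[int] = 0,
    deterministic: bool = False,
    perturbation: Optional[PerturbationSpec] = None,
    initial_states: Optional[tuple[Sequence[float], Sequence[float]]] = None,
) -> CohortResult:
    """Simulate a full cohort under one allocation strategy.

    Each initial state on the integer grid is replicated ``replicates``
    times (4000 hosts with the defaults).  ``deterministic=True`` skips the
    survival draws so every host reaches the horizon; otherwise survival
    from ``t`` to ``t + 1`` is a Bernoulli draw with the step's ``S``.
    """
    if scenario is None:
        scenario = ScenarioConfig()
    params = scenario.apply_to(params)
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if perturbation is not None:
        perturbation.validate(params)
    if initial_states is None:
        e0, w0 = _default_initial_states(params)
    else:
        e0 = np.asarray(initial_states[0], dtype=float)
        w0 = np.asarray(initial_states[1], dtype=float)
    E0 = np.repeat(e0, replicates)
    W0 = np.repeat(w0, replicates)
    n, T = len(E0), params.T
    need_draws = (not deterministic) or strategy.needs_noise
    draws = _host_draws(seed, n, T) if need_draws else None

    E = E0.copy()
    W = W0.copy()
    alive = np.ones(n, dtype=bool)
    traj = {k: np.full((n, T), np.nan) for k in ("E", "W", "u", "B", "W_rep", "S")}
    alive_traj = np.zeros((n, T), dtype=bool)
    V_H = np.zeros(n)
    V_S = np.zeros(n)
    pert_times = set(perturbation.times) if perturbation is not None else set()

    for t in range(1, T + 1):
        if t in pert_times:
            E = np.where(alive, E0, E)
            W = np.where(alive, W0, W)
        alive_traj[:, t - 1] = alive
        if t < T:
            noise = draws[:, t - 1, 1] if strategy.needs_noise else None
            u = _allocations(strategy, E, W, t, params, noise=noise)
        else:
            u = np.zeros(n)  # no decision at the horizon
        out = step_arrays(E, W, t, u, params, scenario, objective="host")
        traj["E"][alive, t - 1] = E[alive]
        traj["W"][alive, t - 1] = W[alive]
        if t < T:
            traj["u"][alive, t - 1] = u[alive]
        traj["B"][alive, t - 1] = np.asarray(out.B)[alive]
        traj["W_rep"][alive, t - 1] = np.asarray(out.W_rep)[alive]
        traj["S"][alive, t - 1] = np.asarray(out.S)[alive]
        V_H += np.where(alive, out.B, 0.0)
        V_S += np.where(alive, out.W_rep, 0.0)
        if t < T:
            if not deterministic:
                alive = alive & (draws[:, t - 1, 0] < np.asarray(out.S))
            E = np.asarray(out.E_tprime, dtype=float).copy()
            W = np.asarray(out.W_dprime, dtype=float).copy()

    return CohortResult(
        E0=E0,
        W0=W0,
        E=traj["E"],
        W=traj["W"],
        u=traj["u"],
        B=traj["B"],
        W_rep=traj["W_rep"],
        S=traj["S"],
        alive=alive_traj,
        V_H=V_H,
        V_S=V_S,
        seed=seed,
        strategy_kind=strategy.kind,
        deterministic=deterministic,
        replicates=replicates,
        params=params,
        scenario=scenario,
    )


def simulate_host(
    E0: float,
    W0: float,
    strategy: StrategySpec,
    params: ModelParams,
    scenario: ScenarioConfig | None = None,
    *,
    seed: Optional[int] = 0,
    deterministic: bool = False,
) -> dict:
    """Simulate a single host; returns its trajectory and fitnesses."""
    cohort = simulate_cohort(
        strategy,
        params,
        scenario,
        replicates=1,
        seed=seed,
        deterministic=deterministic,
        initial_states=([E0], [W0]),
    )
    return cohort.host(0)


def simulate_perturbed_cohort(
    strategy: StrategySpec,
    perturbation: PerturbationSpec,
    params: ModelParams,
    scenario: ScenarioConfig | None = None,
    **kwargs,
) -> CohortResult:
    """As :func:`simulate_cohort`, with state resets at the perturbation times."""
    return simulate_cohort(strategy, params, scenario, perturbation=perturbation, **kwargs)


def cohort_summary(cohort: CohortResult) -> pd.DataFrame:
    """Per-time-step summary over surviving hosts.

    Columns: mean/min/max of W, mean/min/max of E, mean u, fraction alive.
    Cohort-level fitness means and SDs are attached as ``DataFrame.attrs``.
    """
    if cohort.n_hosts == 0:
        raise ValueError("empty cohort")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices after extinction
        df = pd.DataFrame(
            {
                "t": np.arange(1, cohort.params.T + 1),
                "mean_W": np.nanmean(cohort.W, axis=0),
                "min_W": np.nanmin(cohort.W, axis=0),
                "max_W": np.nanmax(cohort.W, axis=0),
                "mean_E": np.nanmean(cohort.E, axis=0),
                "min_E": np.nanmin(cohort.E, axis=0),
                "max_E": np.nanmax(cohort.E, axis=0),
                "mean_u": np.nanmean(cohort.u, axis=0),
                "frac_alive": cohort.alive.mean(axis=0),
            }
        )
    df.attrs["V_H_mean"] = float(np.mean(cohort.V_H))
    df.attrs["V_H_sd"] = float(np.std(cohort.V_H, ddof=1)) if cohort.n_hosts > 1 else 0.0
    df.attrs["V_S_mean"] = float(np.mean(cohort.V_S))
    df.attrs["V_S_sd"] = float(np.std(cohort.V_S, ddof=1)) if cohort.n_hosts > 1 else 0.0
    return df
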
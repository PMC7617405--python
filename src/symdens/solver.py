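"""Backward-induction solution of the allocation problem.

The reproductive value of a host in state ``(E, W)`` at time ``t`` choosing
allocation ``u`` is

    H(E, W; u) = B(E, W; u) + S(E, W; u) V(E(t+1), W(t+1))

where ``B`` is the immediate fitness of the step, ``S`` the survival
probability to ``t + 1`` and ``V`` the reproductive value of the successor
state under optimal behaviour.  At the horizon ``V(E(T), W(T)) = B(E(T),
W(T))``.  Iterating backwards from ``T`` fills value and policy tables on a
discretized ``(E, W)`` grid; successor states produced by the continuous
dynamics fall between nodes and are valued by bilinear interpolation.

The within-step quantities depend on ``t`` only through the reproduction
gate (and, for the temporary-benefit ecology, the survival switch), so the
stage arrays are computed once per distinct (reproductive?, survival-regime)
pattern and reused across time steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import (
    immediate_fitness,
    metabolic_expenditure,
    reproduction_event,
    step_arrays,
)
from .params import ModelParams, ScenarioConfig

__all__ = [
    "StateGrid",
    "DPSolution",
    "terminal_values",
    "interpolate_value",
    "expected_objective",
    "best_action",
    "backward_induction",
]


@dataclass(frozen=True)
class StateGrid:
    """Discretization of the state space and of the candidate actions."""

    e_values: np.ndarray
    w_values: np.ndarray
    u_values: np.ndarray

    def __post_init__(self) -> None:
        for name in ("e_values", "w_values", "u_values"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.ndim != 1 or len(v) < 2 or np.any(np.diff(v) <= 0):
                raise ValueError(f"{name} must be strictly increasing with >= 2 entries")

    @classmethod
    def from_params(cls, params: ModelParams) -> "StateGrid":
        """Default grid: E and W from 0 to their bounds, u from 0 to N."""
        ne = int(round(params.E_max / params.e_grid_step))
        nw = int(round(params.W_max / params.w_grid_step))
        nu = int(round(params.N / params.u_step))
        return cls(
            e_values=np.linspace(0.0, params.E_max, ne + 1),
            w_values=np.linspace(0.0, params.W_max, nw + 1),
            u_values=np.linspace(0.0, params.N, nu + 1),
        )


def _bilinear(values: np.ndarray, xs: np.ndarray, ys: np.ndarray, xq, yq):
    """Bilinear interpolation on a uniform rectangular grid.

    Queries are clamped into the grid bounds; exact at grid nodes.
    """
    xq = np.clip(np.asarray(xq, dtype=float), xs[0], xs[-1])
    yq = np.clip(np.asarray(yq, dtype=float), ys[0], ys[-1])
    px = (xq - xs[0]) / (xs[1] - xs[0])
    py = (yq - ys[0]) / (ys[1] - ys[0])
    i0 = np.minimum(px.astype(np.intp), len(xs) - 2)
    j0 = np.minimum(py.astype(np.intp), len(ys) - 2)
    fx = px - i0
    fy = py - j0
    return (
        (1 - fx) * (1 - fy) * values[i0, j0]
        + fx * (1 - fy) * values[i0 + 1, j0]
        + (1 - fx) * fy * values[i0, j0 + 1]
        + fx * fy * values[i0 + 1, j0 + 1]
    )


def interpolate_value(value_slice: np.ndarray, grid: StateGrid, E, W):
    """Value of off-grid states by bilinear interpolation of one time slice."""
    return _bilinear(value_slice, grid.e_values, grid.w_values, E, W)


def terminal_values(grid: StateGrid, params: ModelParams, scenario: ScenarioConfig) -> np.ndarray:
    """Terminal slice ``V(., ., T) = B(., ., T)``.

    Events 1-2 run at ``t = T``; with the base schedule (last reproduction
    before the horizon) the slice is identically zero.
    """
    E = grid.e_values[:, None]
    W = grid.w_values[None, :]
    E_prime = metabolic_expenditure(E, params)
    _, _, E_rep, W_rep, _ = reproduction_event(E_prime, W, params.T, params, scenario)
    return np.asarray(immediate_fitness(E_rep, W_rep, scenario), dtype=float) + np.zeros(
        (len(grid.e_values), len(grid.w_values))
    )


def expected_objective(
    E,
    W,
    t: int,
    u,
    value_next: np.ndarray,
    grid: StateGrid,
    params: ModelParams,
    scenario: ScenarioConfig,
):
    """``H = B + S * V(next state)`` for (arrays of) states and actions."""
    out = step_arrays(E, W, t, u, params, scenario)
    v = interpolate_value(value_next, grid, out.E_tprime, out.W_dprime)
    return out.B + out.S * v


def best_action(
    E: float,
    W: float,
    t: int,
    value_next: np.ndarray,
    grid: StateGrid,
    params: ModelParams,
    scenario: ScenarioConfig,
) -> tuple[float, float]:
    """Maximize ``H`` over the candidate actions.

    Exact ties resolve to the *largest* allocation: a host indifferent
    between allocations (e.g. after its final reproductive opportunity,
    when the continuation value is zero) passes its surplus energy to the
    symbiont rather than withholding it.
    """
    H = np.asarray(expected_objective(E, W, t, grid.u_values, value_next, grid, params, scenario))
    k = len(H) - 1 - int(np.argmax(H[::-1]))
    return float(grid.u_values[k]), float(H[k])


@dataclass
class DPSolution:
    """Optimal value and policy tables.

    ``V[t - 1]`` is the reproductive value at time ``t`` (t = 1..T);
    ``policy[t - 1]`` the optimal allocation at time ``t`` (t = 1..T-1; no
    decision is taken at the horizon).
    """

    grid: StateGrid
    params: ModelParams
    scenario: ScenarioConfig
    V: np.ndarray
    policy: np.ndarray

    def value(self, E, W, t: int):
        return interpolate_value(self.V[t - 1], self.grid, E, W)

    def allocation(self, E, W, t: int):
        """Policy lookup for off-grid states (bilinear, clamped to [0, N])."""
        u = _bilinear(self.policy[t - 1], self.grid.e_values, self.grid.w_values, E, W)
        return np.clip(u, 0.0, self.params.N)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (t, E, W, u_star, V); u_star is NaN at t = T."""
        T = self.params.T
        ne, nw = len(self.grid.e_values), len(self.grid.w_values)
        t_col = np.repeat(np.arange(1, T + 1), ne * nw)
        e_col = np.tile(np.repeat(self.grid.e_values, nw), T)
        w_col = np.tile(self.grid.w_values, ne * T)
        u_full = np.full((T, ne, nw), np.nan)
        u_full[: T - 1] = self.policy
        return pd.DataFrame(
            {
                "t": t_col,
                "E": e_col,
                "W": w_col,
                "u_star": u_full.reshape(-1),
                "V": self.V.reshape(-1),
            }
        )


class _StagePattern:
    """Pre-computed arrays for one within-step pattern.

    Everything except the successor-value gather is independent of ``t``
    given the reproduction gate and the survival regime.
    """

    __slots__ = ("B", "S", "i0", "j0", "fe", "fw")

    def __init__(self, t: int, grid: StateGrid, params: ModelParams, scenario: ScenarioConfig):
        E = grid.e_values[:, None, None]
        W = grid.w_values[None, :, None]
        u = grid.u_values[None, None, :]
        out = step_arrays(E, W, t, u, params, scenario)
        self.B = np.asarray(out.B)
        self.S = np.asarray(out.S)
        xs, ys = grid.e_values, grid.w_values
        pe = (np.clip(out.E_tprime, xs[0], xs[-1]) - xs[0]) / (xs[1] - xs[0])
        pw = (np.clip(out.W_dprime, ys[0], ys[-1]) - ys[0]) / (ys[1] - ys[0])
        self.i0 = np.minimum(pe.astype(np.intp), len(xs) - 2)
        self.j0 = np.minimum(pw.astype(np.intp), len(ys) - 2)
        self.fe = pe - self.i0
        self.fw = pw - self.j0

    def objective(self, value_next: np.ndarray) -> np.ndarray:
        i0, j0, fe, fw = self.i0, self.j0, self.fe, self.fw
        v = (
            (1 - fe) * (1 - fw) * value_next[i0, j0]
            + fe * (1 - fw) * value_next[i0 + 1, j0]
            + (1 - fe) * fw * value_next[i0, j0 + 1]
            + fe * fw * value_next[i0 + 1, j0 + 1]
        )
        return self.B + self.S * v


def _pattern_key(t: int, params: ModelParams, scenario: ScenarioConfig):
    regime = None
    if scenario.variant == "temporary_benefit":
        regime = t >= scenario.maturation_step
    return (params.is_reproductive(t), regime)


def backward_induction(
    params: ModelParams,
    scenario: ScenarioConfig | None = None,
    grid: StateGrid | None = None,
) -> DPSolution:
    """Solve for the optimal allocation policy by backward induction.

    Decisions are taken at ``t = 1 .. T-1``; the horizon contributes only
    its terminal value.  Deterministic: identical inputs give bit-identical
    tables.
    """
    if scenario is None:
        scenario = ScenarioConfig()
    params = scenario.apply_to(params)
    if grid is None:
        grid = StateGrid.from_params(params)
    T = params.T
    ne, nw = len(grid.e_values), len(grid.w_values)
    V = np.zeros((T, ne, nw))
    policy = np.zeros((max(T - 1, 0), ne, nw))
    V[T - 1] = terminal_values(grid, params, scenario)
    patterns: dict = {}
    for t in range(T - 1, 0, -1):
        key = _pattern_key(t, params, scenario)
        if key not in patterns:
            patterns[key] = _StagePattern(t, grid, params, scenario)
        H = patterns[key].objective(V[t])
        # argmax on the reversed action axis: exact ties go to the largest u
        nu = H.shape[-1]
        k = nu - 1 - np.argmax(H[..., ::-1], axis=-1)
        V[t - 1] = np.take_along_axis(H, k[..., None], axis=-1)[..., 0]
        policy[t - 1] = grid.u_values[k]
    return DPSolution(grid=grid, params=params, scenario=scenario, V=V, policy=policy)
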
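"""Model parameters and ecological scenario configuration.

The model describes an iteroparous host carrying a compartmentalized,
vertically transmitted symbiont.  The host's state is its energy reserves
``E`` and its within-host symbiont density ``W``; each discrete time step
corresponds to one meal, and the single decision per step is how much of the
dietary energy ``N`` to allocate to the symbiont population.

:class:`ModelParams` holds every scalar of the base-case model plus the grid
resolutions used by the dynamic-programming solver.  :class:`ScenarioConfig`
selects one of five host-symbiont ecologies and the objective maximized by
the solver (host fitness or symbiont fitness).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = ["ModelParams", "ScenarioConfig", "VARIANTS"]

#: Recognised host-symbiont ecologies.
VARIANTS = (
    "base",
    "symbiont_optimal",
    "non_essential",
    "temporary_benefit",
    "post_reproductive",
)

_OBJECTIVES = ("host", "symbiont")


@dataclass(frozen=True)
class ModelParams:
    """All scalar parameters of the model, defaulting to the base case.

    Parameters
    ----------
    T
        Time horizon: maximum number of time steps a host can live.
    E_max, W_max
        Upper bounds of the energy-reserve and symbiont-density state
        variables (energy units / density units).
    E_crit, W_crit
        Minimum reserves and minimum symbiont density required to reproduce.
    N
        Dietary energy acquired per time step (one meal).
    mu
        Proportional increase of metabolic expenditure with reserves.
    omega
        Fixed metabolic expenditure per time step (energy units).
    alpha
        Maintenance cost of the symbiont population (energy per density unit).
    beta
        Symbiont density gained per unit of net energy invested.
    lambda_rep
        Proportion of post-expenditure reserves invested in reproduction.
    gamma
        Proportion of the symbiont population transmitted to offspring.
    s
        Shape coefficient of the asymptotic survival function (default 0.3).
    repro_first, repro_interval, repro_last
        Reproductive schedule: reproduction is possible at
        ``repro_first, repro_first + repro_interval, ...`` up to
        ``repro_last`` (``None`` means up to the horizon ``T``).
    e_grid_step, w_grid_step, u_step
        Resolutions of the state grid and of the candidate-action grid used
        by the solver.
    """

    T: int = 50
    E_max: float = 20.0
    W_max: float = 20.0
    E_crit: float = 6.0
    W_crit: float = 6.0
    N: float = 8.0
    mu: float = 0.2
    omega: float = 2.0
    alpha: float = 0.5
    beta: float = 0.5
    lambda_rep: float = 0.3
    gamma: float = 0.2
    s: float = 0.3
    repro_first: int = 8
    repro_interval: int = 4
    repro_last: Optional[int] = None
    e_grid_step: float = 1.0
    w_grid_step: float = 1.0
    u_step: float = 0.1

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError(f"T must be >= 1, got {self.T}")
        for name in ("E_max", "W_max", "N", "omega", "alpha", "beta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.N <= 0:
            raise ValueError("N must be positive")
        if self.E_max <= 0 or self.W_max <= 0:
            raise ValueError("state bounds must be positive")
        if not 0 < self.lambda_rep < 1:
            raise ValueError(f"lambda_rep must be in (0, 1), got {self.lambda_rep}")
        # gamma = 0 (no vertical transmission) is a degenerate but analytically
        # useful boundary: it forces W_rep = 0 and hence zero fitness everywhere.
        if not 0 <= self.gamma < 1:
            raise ValueError(f"gamma must be in [0, 1), got {self.gamma}")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if not 0 <= self.E_crit <= self.E_max:
            raise ValueError("E_crit must lie in [0, E_max]")
        if not 0 <= self.W_crit <= self.W_max:
            raise ValueError("W_crit must lie in [0, W_max]")
        if self.repro_first < 1 or self.repro_interval < 1:
            raise ValueError("reproductive schedule must use positive steps")
        for name in ("e_grid_step", "w_grid_step", "u_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def repro_last_effective(self) -> int:
        """Last time step at which reproduction can occur."""
        if self.repro_last is None:
            return self.T
        return min(self.repro_last, self.T)

    def reproductive_schedule(self) -> tuple[int, ...]:
        """Time steps at which reproduction is possible."""
        return tuple(
            range(self.repro_first, self.repro_last_effective + 1, self.repro_interval)
        )

    def is_reproductive(self, t: int) -> bool:
        """Whether ``t`` is a reproductive time step."""
        last = self.repro_last_effective
        if t < self.repro_first or t > last:
            return False
        return (t - self.repro_first) % self.repro_interval == 0

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ScenarioConfig:
    """Which host-symbiont ecology is active and which objective the solver
    maximizes.

    Variants
    --------
    base
        Obligate symbiont, host-fitness objective.
    symbiont_optimal
        Base-case ecology, but the solver maximizes the symbiont's share of
        reproduction (``W_rep``) instead of host fitness.
    non_essential
        The symbiont is not required for reproduction (``W_crit`` treated as
        0), contributes to survival only through an offset density, and the
        host's immediate fitness is ``0.5 E_rep W_rep + 5`` at every step.
    temporary_benefit
        The symbiont contributes to survival only before host maturation
        (``t < maturation_step``); afterwards survival depends on reserves
        alone.
    post_reproductive
        Base-case ecology with the final reproductive event capped (default
        ``t = 32``), leaving a post-reproductive life stage.
    """

    variant: str = "base"
    objective: Optional[str] = None
    nonessential_fitness_scale: float = 0.5
    nonessential_fitness_offset: float = 5.0
    nonessential_survival_shift: float = 2.0
    maturation_step: int = 8
    post_repro_last: int = 32

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        obj = self.objective
        if obj is None:
            obj = "symbiont" if self.variant == "symbiont_optimal" else "host"
            object.__setattr__(self, "objective", obj)
        if self.objective not in _OBJECTIVES:
            raise ValueError(f"objective must be one of {_OBJECTIVES}")

    def effective_w_crit(self, params: ModelParams) -> float:
        """Reproduction density threshold under this ecology."""
        if self.variant == "non_essential":
            return 0.0
        return params.W_crit

    def apply_to(self, params: ModelParams) -> ModelParams:
        """Apply variant-specific parameter overrides.

        The post-reproductive ecology caps the reproductive schedule at
        ``post_repro_last`` unless the caller set ``repro_last`` explicitly.
        """
        if self.variant == "post_reproductive" and params.repro_last is None:
            return params.replace(repro_last=self.post_repro_last)
        return params

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
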
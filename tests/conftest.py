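import numpy as np
import pytest

from symdens import (
    ModelParams,
    ScenarioConfig,
    StrategySpec,
    backward_induction,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def base_params():
    return ModelParams()


@pytest.fixture(scope="session")
def base_solution(base_params):
    """Base-case optimal policy (shared: the solve is deterministic)."""
    return backward_induction(base_params)


@pytest.fixture(scope="session")
def symbiont_solution(base_params):
    return backward_induction(base_params, ScenarioConfig(variant="symbiont_optimal"))


@pytest.fixture(scope="session")
def base_cohort_det(base_params, base_solution):
    """Full 4000-host cohort under the optimal policy, deterministic survival."""
    return simulate_cohort(
        StrategySpec(kind="optimal", policy=base_solution),
        base_params,
        replicates=10,
        seed=1,
        deterministic=True,
    )


@pytest.fixture(scope="session")
def strategy_cohorts(base_params, base_solution, symbiont_solution):
    """One stochastic cohort per allocation strategy (fixed seeds)."""
    specs = {
        "optimal": StrategySpec(kind="optimal", policy=base_solution),
        "imperfect": StrategySpec(kind="imperfect", policy=base_solution),
        "fixed": StrategySpec(kind="fixed"),
        "symbiont_optimal": StrategySpec(kind="symbiont_optimal", policy=symbiont_solution),
        "proportional": StrategySpec(kind="proportional"),
    }
    return {
        name: simulate_cohort(spec, base_params, replicates=10, seed=300 + j)
        for j, (name, spec) in enumerate(specs.items())
    }
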
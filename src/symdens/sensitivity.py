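"""Latin-hypercube sensitivity analysis of the plateau symbiont density.

Ten parameters are swept over their admissible ranges by Latin hypercube
sampling; for every sample the full pipeline runs (solve the DP, simulate a
cohort, compute the plateau statistic) and each parameter is then
correlated with the plateau by Pearson's r.

The plateau statistic is the mean symbiont density over all time steps of
the reproductive phase of life (from the first scheduled reproduction to
the horizon), averaged over surviving hosts.  Samples where no host
survives to the first reproductive step have no plateau and are excluded
listwise from the correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .params import ModelParams, ScenarioConfig
from .simulate import CohortResult, StrategySpec, simulate_cohort
from .solver import backward_induction

__all__ = [
    "DEFAULT_RANGES",
    "SweepDesign",
    "SweepResult",
    "lhs_sample",
    "plateau_statistic",
    "run_sweep",
    "pearson_correlations",
]

#: Sweep ranges of the ten free parameters (state bounds stay fixed).
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "T": (40, 60),
    "E_crit": (1, 14),
    "W_crit": (1, 12),
    "N": (6, 15),
    "mu": (0.0, 2.0),
    "omega": (0.0, 5.0),
    "alpha": (0.1, 1.5),
    "beta": (0.01, 5.0),
    "lambda_rep": (0.1, 0.9),
    "gamma": (0.1, 0.9),
}


@dataclass(frozen=True)
class SweepDesign:
    """Sampling plan of the sensitivity sweep."""

    ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    n: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("n must be >= 3 for a correlation to exist")
        for name, (lo, hi) in self.ranges.items():
            if name not in DEFAULT_RANGES:
                raise ValueError(f"unknown sweep parameter {name!r}")
            if hi < lo:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")


def lhs_sample(design: SweepDesign) -> pd.DataFrame:
    """Stratified parameter matrix: one draw per equal-width interval per
    parameter, intervals independently permuted across parameters.

    ``T`` is rounded to an integer; degenerate ranges (lo == hi) are held
    constant.
    """
    names = list(design.ranges)
    sampler = qmc.LatinHypercube(d=len(names), seed=design.seed)
    unit = sampler.random(design.n)
    lows = np.array([design.ranges[p][0] for p in names], dtype=float)
    highs = np.array([design.ranges[p][1] for p in names], dtype=float)
    values = qmc.scale(unit, lows, highs)
    df = pd.DataFrame(values, columns=names)
    if "T" in df:
        df["T"] = np.rint(df["T"]).astype(int)
    return df


def plateau_statistic(cohort: CohortResult) -> float:
    """Mean W over all (surviving host, reproductive-phase step) pairs.

    Returns NaN when no host survives to the first scheduled reproduction.
    """
    schedule = cohort.params.reproductive_schedule()
    if not schedule:
        return float("nan")
    t0 = schedule[0]
    window = cohort.W[:, t0 - 1 :]
    if np.all(np.isnan(window)):
        return float("nan")
    return float(np.nanmean(window))


def run_sweep(
    design: SweepDesign,
    base_params: Optional[ModelParams] = None,
    scenario: Optional[ScenarioConfig] = None,
    *,
    replicates: int = 2,
) -> "SweepResult":
    """Run the solve-then-simulate pipeline for every LHS sample.

    Cohorts use stochastic survival with ``replicates`` hosts per initial
    state (2 by default for speed; pass 10 for full-size cohorts).
    """
    if base_params is None:
        base_params = ModelParams()
    if scenario is None:
        scenario = ScenarioConfig()
    samples = lhs_sample(design)
    seeds = np.random.SeedSequence(design.seed).generate_state(design.n) % (2**31)
    plateaus = np.full(design.n, np.nan)
    for i, row in samples.iterrows():
        overrides = row.to_dict()
        overrides["T"] = int(overrides["T"])
        params = base_params.replace(**overrides)
        solution = backward_induction(params, scenario)
        cohort = simulate_cohort(
            StrategySpec(kind="optimal", policy=solution),
            params,
            scenario,
            replicates=replicates,
            seed=int(seeds[i]),
        )
        plateaus[i] = plateau_statistic(cohort)
    result = SweepResult(design=design, samples=samples, plateau=pd.Series(plateaus, name="plateau"))
    if result.valid.sum() >= 3:
        result.correlations = pearson_correlations(result)
    return result


@dataclass
class SweepResult:
    """Samples, plateau values and (once computed) the correlation table."""

    design: SweepDesign
    samples: pd.DataFrame
    plateau: pd.Series
    correlations: Optional[pd.DataFrame] = None

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.plateau.to_numpy())


def pearson_correlations(sweep: SweepResult, alpha: float = 0.05) -> pd.DataFrame:
    """Pearson r of each swept parameter against the plateau density.

    Two-sided p-values from the t distribution with ``n - 2`` degrees of
    freedom; zero-variance parameter columns get NaN.
    """
    ok = sweep.valid
    if ok.sum() < 3:
        raise ValueError("need at least 3 valid samples for correlations")
    y = sweep.plateau.to_numpy()[ok]
    rows = []
    for name in sweep.samples.columns:
        x = sweep.samples[name].to_numpy(dtype=float)[ok]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((name, np.nan, np.nan, False))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((name, float(r), float(p), bool(p < alpha)))
    return pd.DataFrame(rows, columns=["parameter", "R", "p", "significant"])
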
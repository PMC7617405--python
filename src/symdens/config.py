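"""Run configuration, serialization and output writing.

A run configuration is a YAML (or JSON) file with up to four sections —
``params``, ``scenario``, ``strategy``, ``simulation`` — plus a top-level
``seed``.  Every field is optional: an empty file reproduces the base-case
model exactly.  Unknown keys are rejected so typos cannot silently fall
back to defaults.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .params import ModelParams, ScenarioConfig
from .simulate import CohortResult, StrategySpec, cohort_summary

__all__ = ["SimulationSettings", "RunConfig", "load_config", "save_config", "write_outputs"]


@dataclass(frozen=True)
class SimulationSettings:
    """Cohort-level simulation switches."""

    replicates: int = 10
    deterministic: bool = False
    perturbation_times: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one run."""

    params: ModelParams = field(default_factory=ModelParams)
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    strategy_kind: str = "optimal"
    strategy_options: dict = field(default_factory=dict)
    simulation: SimulationSettings = field(default_factory=SimulationSettings)
    seed: int = 0

    def build_strategy(self, policy=None) -> StrategySpec:
        return StrategySpec(kind=self.strategy_kind, policy=policy, **self.strategy_options)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "scenario": self.scenario.to_dict(),
            "strategy": {"kind": self.strategy_kind, **self.strategy_options},
            "simulation": dataclasses.asdict(self.simulation),
            "seed": self.seed,
        }


def _build_section(cls, data: dict, section: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(
            f"unknown keys in section {section!r}: {sorted(unknown)}; "
            f"allowed: {sorted(fields)}"
        )
    if section == "simulation" and "perturbation_times" in data:
        data = {**data, "perturbation_times": tuple(data["perturbation_times"])}
    return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a run configuration file.

    An empty or missing-section file yields base-case defaults; schema
    violations name the offending fields.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {"params", "scenario", "strategy", "simulation", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown top-level keys: {sorted(unknown)}; allowed: {sorted(known)}")
    strategy = dict(raw.get("strategy") or {})
    kind = strategy.pop("kind", "optimal")
    allowed_opts = {"fixed_u", "prop_factor", "imperfect_halfwidth"}
    bad = set(strategy) - allowed_opts
    if bad:
        raise ValueError(f"unknown keys in section 'strategy': {sorted(bad)}")
    return RunConfig(
        params=_build_section(ModelParams, dict(raw.get("params") or {}), "params"),
        scenario=_build_section(ScenarioConfig, dict(raw.get("scenario") or {}), "scenario"),
        strategy_kind=kind,
        strategy_options=strategy,
        simulation=_build_section(
            SimulationSettings, dict(raw.get("simulation") or {}), "simulation"
        ),
        seed=int(raw.get("seed", 0)),
    )


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config file that round-trips through :func:`load_config`."""
    data = config.to_dict()
    data["simulation"]["perturbation_times"] = list(
        data["simulation"]["perturbation_times"]
    )
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def write_outputs(
    out_dir: str | Path,
    *,
    config: Optional[RunConfig] = None,
    seed: Optional[int] = None,
    solution=None,
    cohort: Optional[CohortResult] = None,
    trajectories: bool = False,
    sweep=None,
    comparison=None,
) -> list[Path]:
    """Write whatever results are given as CSV/JSON plus a run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _w(name: str, df) -> None:
        p = out / name
        df.to_csv(p, index=False)
        written.append(p)

    if solution is not None:
        _w("policy.csv", solution.to_frame())
    if cohort is not None:
        _w("fitness.csv", cohort.fitness_frame())
        _w("summary.csv", cohort_summary(cohort))
        if trajectories:
            _w("trajectories.csv", cohort.trajectory_frame())
    if sweep is not None:
        _w("samples.csv", sweep.samples.assign(plateau=sweep.plateau))
        if sweep.correlations is not None:
            _w("correlations.csv", sweep.correlations)
    if comparison is not None:
        _w("strategy_summary.csv", comparison.summary)
        for fitness, mat in comparison.pairwise_holm.items():
            _w(f"pairwise_{fitness}_holm.csv", mat.reset_index(names="strategy"))
        for fitness, mat in comparison.pairwise_raw.items():
            _w(f"pairwise_{fitness}_raw.csv", mat.reset_index(names="strategy"))
    manifest = {
        "seed": seed if seed is not None else (config.seed if config else None),
        "config": config.to_dict() if config else None,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "files": [p.name for p in written],
    }
    from . import __version__

    manifest["version"] = __version__
    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, default=str))
    written.append(mp)
    return written
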
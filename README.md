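# symdens

**Host-controlled regulation of endosymbiont density by optimal energy
allocation.**

Many animals harbour obligate, vertically transmitted bacterial symbionts
confined to specialized tissues — *Wigglesworthia* in tsetse, *Buchnera* in
aphids, *Blochmannia* in carpenter ants.  Compartmentalization gives the
host control over the energy its symbionts receive, and there is growing
evidence that hosts actively regulate symbiont density to their own
requirements.  `symdens` is a simulation and optimization toolkit for
studying when and how such regulation is adaptive, for the host *and* for
the symbiont.

## The model

A host is described by two state variables, energy reserves `E` and
symbiont density `W`.  Each discrete time step (one meal) the host loses
`μE + ω` to metabolism, may reproduce (investing `E_rep = λE'` and
transmitting `W_rep = γW` when reserves and density exceed thresholds on a
4-step schedule), feeds (`N` units), and decides how much of the meal,
`u ∈ [0, N]`, to allocate to the symbiont, whose density then follows

    W(t+1) = W' + (u − αW')β      (0 if extinct)

Survival to the next step rises asymptotically with both states,
`S = (1 − e^{−0.3E'''})(1 − e^{−0.3W''})`, and the immediate fitness of a
step is `B = E_rep·W_rep`.  The optimal allocation policy `u*(E, W, t)`
maximizes the dynamic-programming recursion

    H(E, W; u) = B(E, W; u) + S(E, W; u) · V(E(t+1), W(t+1))

solved by backward induction on a discretized state grid with bilinear
interpolation of the value function.  Forward Monte-Carlo cohorts (10 hosts
from every initial state on the 20×20 grid, 4000 total) then yield the
emergent density dynamics, lifetime host fitness `V_H = ΣB` and symbiont
fitness `V_S = ΣW_rep` under five allocation strategies, a Latin-hypercube
sensitivity analysis of the density plateau, and nonparametric
(Kruskal-Wallis / Wilcoxon rank-sum) strategy comparisons.  Four
host-symbiont ecologies are built in: the base case, a non-essential
symbiont, a symbiont needed only until host maturation, and a host with a
post-reproductive life stage.

## Worked example

```python
import numpy as np
from symdens import ModelParams, StrategySpec, backward_induction, simulate_cohort

params = ModelParams()                      # base case
policy = backward_induction(params)         # optimal allocation policy
cohort = simulate_cohort(
    StrategySpec(kind="optimal", policy=policy),
    params, replicates=10, seed=1, deterministic=True,
)
W = cohort.W
print(f"density range at t=8:  {np.nanmax(W[:, 7]) - np.nanmin(W[:, 7]):.2f}")
print(f"plateau (mean W, t>=8): {np.nanmean(W[:, 7:]):.2f}")
mean_w = np.nanmean(W, axis=0)
print(f"converged cycle:        {mean_w[19:44].min():.2f} - {mean_w[19:44].max():.2f}")
```

prints

```
density range at t=8:  2.16
plateau (mean W, t>=8): 6.40
converged cycle:        5.85 - 6.56
```

— the initial 19-unit spread of symbiont densities collapses to ~2 units by
the first reproduction at `t = 8`, after which density is regulated onto a
stable oscillation (trough just after each reproduction, peak just before
the next) around a constant plateau.  The `examples/` directory has one
short script per capability: `base_case.py`, `scenarios.py`,
`perturbation.py`, `strategy_comparison.py`, `sensitivity_sweep.py`.

A thin CLI wraps the same pipeline stages:

```sh
symdens solve --out out/           # policy + value tables as CSV
symdens simulate --strategy fixed --seed 3 --out out/
symdens perturb --times 7,24,39 --out out/
symdens sensitivity --n 400 --seed 1 --out out/
symdens compare --seed 1 --out out/
```

An empty (or absent) YAML config reproduces the base case; every model
parameter can be overridden from the file.

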
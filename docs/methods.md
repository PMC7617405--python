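# Methods

`symdens` models a female iteroparous host that carries an obligate,
compartmentalized, vertically transmitted endosymbiont and controls the
symbiont population solely through the allocation of dietary energy.  This
note documents the model, the numerical choices, and the points where the
design was genuinely open.

## State dynamics

The host's state is its energy reserve `E ∈ [0, E_max]` and the within-host
symbiont density `W ∈ [0, W_max]`.  Time is discrete; each step is one meal.
Six events run in fixed order:

1. **Metabolism** — `E' = E − (μE + ω)`; expenditure rises linearly with
   reserves.
2. **Reproduction** — on scheduled steps (every `repro_interval = 4` steps
   from `repro_first = 8`), if `E' ≥ E_crit` and `W ≥ W_crit`, the host
   invests `E_rep = λE'` and transmits `W_rep = γW` to offspring.
3. **Feeding** — intake of `N` energy units (deterministic; a stochastic
   feeding hook exists but is untested).
4. **Decision** — allocation `u ∈ [0, N]` of the meal to the symbiont.
5. **Symbiont update** — `W(t+1) = W' + (u − αW')β` for `W' > 0`; an
   extinct population cannot be recovered.  `α` is the per-density
   maintenance cost, `β` the density gained per unit net energy.  The
   sustainable ceiling is `N/α = 16` with defaults; with `u = 0` density
   decays by the factor `1 − αβ = 0.75` per step.
6. **Storage** — `E(t+1) = E'' + N − u`.

Stored states are clamped to `[0, E_max] × [0, W_max]`; intermediate
quantities may be negative.  Survival to the next step is
`S = (1 − e^{−sE'''})(1 − e^{−sW''})` with shape `s = 0.3`, evaluated on the
clamped next-step states (the states that actually persist); each factor is
floored at 0 so `S ∈ [0, 1]` for any input.  The immediate fitness of a step
is `B = E_rep · W_rep`.

Defaults: `T = 50`, `E_max = W_max = 20`, `E_crit = W_crit = 6`, `N = 8`,
`μ = 0.2`, `ω = 2`, `α = β = 0.5`, `λ = 0.3`, `γ = 0.2`.

## Dynamic programming

The reproductive value satisfies `H(E, W; u) = B + S · V(E(t+1), W(t+1))`
with terminal condition `V(·, ·, T) = B(·, ·, T)` (identically zero when the
horizon is not a scheduled reproduction).  Backward induction from `T` fills
value and policy tables on an integer `21 × 21` state grid with the action
grid `u ∈ {0, 0.1, …, 8}`.  Successor states are continuous, so `V(t+1)` is
valued by bilinear interpolation (exact at nodes); nearest-node snapping was
rejected because the forward dynamics visit non-integer densities.

**Tie-breaking.**  When several allocations attain the same `H` exactly, the
*largest* is chosen: a host that is indifferent — notably after its final
reproductive opportunity, when the continuation value is identically zero —
passes its surplus energy to the symbiont rather than withholding it.  This
is what produces the post-reproductive proliferation of the symbiont (it
converges on the sustainable ceiling `N/α`); with the opposite tie-break the
symbiont would be abandoned after the last reproduction, which contradicts
the reported dynamics of post-reproductive hosts.

**Verification.**  On tiny fixtures whose dynamics are closed on the state
grid (`α = β = 1` makes the next density equal the integer allocation;
`μ = 0` with integer `ω`, `N`, actions keeps reserves on the lattice;
reproduction only at the horizon, because its proportional drain maps any
lattice off itself) the solver agrees with a grid-free exhaustive recursion
over the action tree to machine precision.

**Periodicity.**  The converged policy repeats with the 4-step reproductive
period.  Repetition is exact at ≥ 98% of grid states for `8 ≤ t ≤ 28`;
isolated knife-edge states flip by one action step because backward
convergence of the value function is asymptotic, and the deviation grows in
the last few cycles before the horizon.  Tests assert the verified form
(≥ 97% exact, deviations ≤ one action step of 0.1 in the interior) rather
than blanket equality.

## Forward simulation

Cohorts cover the integer initial grid `{1..20}²` with 10 replicates per
state (4000 hosts); `E = 0` and `W = 0` are excluded as absorbing.  Each
host iterates the dynamics under a strategy; `B` accrues at the end of the
step, then survival to `t+1` is a Bernoulli draw with probability `S`
(consistent with `H = B + S·V`, where `B` is unconditional).  Lifetime
fitnesses are `V_H = Σ B` and `V_S = Σ W_rep` over the steps lived.  A
deterministic mode skips the draws so every host reaches the horizon; it is
used for trajectory statistics, where the policy itself is deterministic and
survivorship would only thin the sample.  Off-grid policy lookups use the
same bilinear interpolation as the solver, clamped to `[0, N]`.

A single root seed spawns one PCG64 stream per host (via `SeedSequence`), so
a host's draws do not depend on the cohort size.

Strategies: interpolated optimal policy; imperfect implementation
(`u ~ U(u* − 1, u* + 1)` clamped to `[0, N]`); fixed `u = 3`; proportional
`u = 0.3W` (which makes density decay geometrically at factor 0.9 when no
reproduction intervenes); and the policy solved with the symbiont objective
`B = W_rep`.  Perturbation experiments reset each surviving host's state to
its own `t = 1` values at the start of the given steps (default 7, 24, 39),
before metabolism.  Reconvergence after a reset takes about two reproductive
cycles — the same ~7 steps the initial state range needs to collapse.

## Plateau statistic and sensitivity analysis

The plateau density is the mean of `W` over all (surviving host, step)
observations of the reproductive phase of life, `t ≥ repro_first`.  This
full-cycle mean sits between the oscillation extremes (base case ≈ 5.85 and
≈ 6.56, plateau ≈ 6.4), which is how the reported plateau values relate to
the reported cycle extremes; a mean over only the reproduction steps would
instead track the pre-reproduction peak.

The sensitivity module sweeps ten parameters (`T, E_crit, W_crit, N, μ, ω,
α, β, λ, γ`) by Latin hypercube sampling over their admissible ranges
(state bounds stay fixed at 20), runs the full solve-then-simulate pipeline
per sample with stochastic survival, and correlates each parameter with the
plateau by Pearson's r (two-sided p, t distribution, n − 2 df).  The sample
count defaults to 400.  Samples where no host survives to the first
scheduled reproduction have no plateau and are excluded listwise.  Because
the ranges are individually viable but jointly often lethal, typically only
~20% of samples are viable; with that effective sample size the strongly
correlated parameters (`α`, `N`, `β`) are reliably significant, while the
weak negative correlations of `μ` and `ω` carry correct signs but limited
power.  Sweeps default to 2 replicates per initial state for speed; the
analyses reported by the acceptance tests use the full 10.

## Scenario variants

* **Symbiont-optimal** — the solver maximizes `B = W_rep`; simulation still
  accounts host fitness as `E_rep · W_rep`.
* **Non-essential symbiont** — `W_crit = 0`; the survival density factor is
  shifted, `1 − e^{−s(W''+2)}`, so a symbiont-free host can survive; the
  fitness of a reproductive event is `0.5 E_rep W_rep + 5`.  Whether the
  `+5` offset accrues every step or only at reproduction is not determined
  by the model description; here it accrues at reproduction only, because
  `B` is the fitness of offspring production and a per-step constant makes
  bare longevity dominate the objective, driving the optimal density *up*
  (plateau ≈ 7.5) instead of down.  Even under the reproduction-only
  reading the optimal plateau is ≈ 6.0, well above the reported ≈ 3.8; only
  a fully density-independent survival factor would reproduce that value
  (≈ 3.2, oscillating ≈ 1.9–5.1).  The implementation keeps the stated
  shifted-factor survival and the discrepancy stands as a known limitation.
* **Temporary benefit** — for `t ≥ 8` survival depends on reserves alone.
  The symbiont is then maintained only for transmission: run down after each
  reproduction and rebuilt just before the next.  The post-reproduction
  baseline (mean density at the step after a reproductive event, converged
  cycles) is ≈ 3.8.  The within-cycle *minimum* is lower (≈ 2.7) because
  with a fine action grid the optimal policy defers the rebuild to the last
  step before reproduction, which is cheaper in maintenance.
* **Post-reproductive host** — the last scheduled reproduction is capped at
  `t = 32`; afterwards the indifferent host allocates its surplus (see
  tie-breaking) and the symbiont proliferates to the sustainable ceiling.

## What the simulations do and do not show

The cohort generator covers every possible initial state, not an empirical
state distribution; deterministic-survival trajectories show the policy's
regulation dynamics free of survivorship thinning, while all fitness
comparisons use stochastic survival.  Real host-symbiont systems have
stochastic feeding, mechanistic (immune/digestive) symbiont removal,
multiple symbiont populations and non-linear density costs — all outside
this framework, so quantitative levels are model statements, not predictions
for any particular organism.

## Statistical comparison of strategies

Host and symbiont fitness vectors (4000 hosts per strategy, stochastic
survival, independent seeds per cohort) are compared by a tie-corrected
Kruskal-Wallis test and pairwise two-sided Mann-Whitney tests, at the 5%
level.  Both raw and Holm-adjusted pairwise matrices are reported;
significance letters are the maximal cliques of the
not-significantly-different graph on the adjusted matrix.  Exact H values
are seed-dependent and are not asserted anywhere — only significance and
ordering.  In this implementation the symbiont-optimal policy yields
measurably lower host fitness (≈ −13%) and higher symbiont fitness
(≈ +17%) than the host-optimal policy, differences a rank test on 4000
hosts detects; the two policies differ at ~37% of grid states at the 0.1
action resolution (falling to ~25% with integer actions, where the host-
fitness difference stops being detectable).

## Problem sizes

Default analyses use the full problem sizes throughout: 21 × 21 × 81
state-action grid over 50 steps for the solver, 4000-host cohorts, 400-point
sweeps.  The only deliberately reduced setting is the sweep's per-sample
cohort (2 replicates by default, 10 in the reported analyses).
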
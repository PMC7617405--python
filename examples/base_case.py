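"""Base case: solve for the optimal allocation policy and simulate a cohort.

Solves the host's energy-allocation problem by backward induction, then
forward-simulates 10 hosts from every initial state on the 20x20 grid
(4000 hosts) with deterministic survival, and prints the emergent
symbiont-density statistics.
"""

import numpy as np

from symdens import ModelParams, StrategySpec, backward_induction, simulate_cohort

params = ModelParams()
solution = backward_induction(params)
cohort = simulate_cohort(
    StrategySpec(kind="optimal", policy=solution),
    params,
    replicates=10,
    seed=1,
    deterministic=True,
)

W = cohort.W
mean_w = np.nanmean(W, axis=0)
mean_u = np.nanmean(cohort.u[:, :-1], axis=0)
w8 = W[:, 7]

print(f"hosts simulated:                      {cohort.n_hosts}")
print(f"density range at t=1:                 {np.ptp(cohort.W0):.1f}")
print(f"density range at t=8 (first repro):   {np.nanmax(w8) - np.nanmin(w8):.2f}")
print(f"plateau density (mean W, t>=8):       {np.nanmean(W[:, 7:]):.2f}")
print(f"converged cycle trough/peak (t 20-44): {mean_w[19:44].min():.2f} / {mean_w[19:44].max():.2f}")
print(f"allocation cycle trough/peak (t>=8):  {np.nanmin(mean_u[7:44]):.2f} / {np.nanmax(mean_u[7:44]):.2f}")
print()
print("The initial 19-unit spread of symbiont densities collapses to ~2 units")
print("by the first reproduction; thereafter density oscillates with the")
print("4-step reproductive cycle around a constant plateau.")
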
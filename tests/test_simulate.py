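"""Cohort-simulator tests: strategies, accounting, perturbations, seeds."""

import numpy as np
import pytest

from symdens import (
    HostState,
    ModelParams,
    PerturbationSpec,
    ScenarioConfig,
    StrategySpec,
    cohort_summary,
    decide_allocation,
    simulate_cohort,
    simulate_host,
    simulate_perturbed_cohort,
)


def test_fixed_strategy_ignores_state():
    s = StrategySpec(kind="fixed", fixed_u=3.0)
    for E, W, t in [(1, 1, 1), (20, 20, 30)]:
        assert decide_allocation(s, HostState(E, W, t)) == 3.0


def test_proportional_strategy_scales_with_density():
    s = StrategySpec(kind="proportional", prop_factor=0.3)
    assert decide_allocation(s, HostState(10.0, 10.0, 5)) == pytest.approx(3.0)
    # clamped at the dietary income
    params = ModelParams()
    assert decide_allocation(s, HostState(10.0, params.W_max + 0, 5)) <= params.N


def test_imperfect_strategy_stays_within_noise_band(base_solution):
    s = StrategySpec(kind="imperfect", policy=base_solution)
    rng = np.random.default_rng(0)
    for _ in range(50):
        state = HostState(E=12.0, W=6.0, t=10)
        u0 = float(base_solution.allocation(state.E, state.W, state.t))
        u = decide_allocation(s, state, rng=rng)
        assert max(0.0, u0 - 1) - 1e-12 <= u <= min(8.0, u0 + 1) + 1e-12


def test_policy_strategy_requires_policy():
    with pytest.raises(ValueError):
        StrategySpec(kind="optimal")


def test_proportional_decay_is_geometric_without_reproduction():
    """u = 0.3 W with defaults gives W(t+1) = 0.9 W(t) exactly."""
    params = ModelParams(T=20, repro_first=21)  # schedule empty
    rec = simulate_host(
        20.0, 10.0, StrategySpec(kind="proportional"), params, deterministic=True
    )
    W = rec["W"]
    np.testing.assert_allclose(W, 10.0 * 0.9 ** np.arange(20), rtol=1e-12)


def test_cohort_counts():
    params = ModelParams(T=5, repro_first=21)
    c = simulate_cohort(
        StrategySpec(kind="fixed"), params, replicates=1,
        initial_states=([1.0, 2.0], [1.0, 2.0]), deterministic=True,
    )
    assert c.n_hosts == 2
    c = simulate_cohort(StrategySpec(kind="fixed"), params, replicates=2, seed=0)
    assert c.n_hosts == 2 * 20 * 20


def test_default_cohort_is_4000_hosts(base_cohort_det):
    assert base_cohort_det.n_hosts == 4000


def test_seed_determinism(base_solution):
    params = ModelParams(T=15)
    spec = StrategySpec(kind="imperfect", policy=base_solution)
    a = simulate_cohort(spec, params, replicates=1, seed=7)
    b = simulate_cohort(spec, params, replicates=1, seed=7)
    np.testing.assert_array_equal(a.W, b.W)
    np.testing.assert_array_equal(a.V_H, b.V_H)
    c = simulate_cohort(spec, params, replicates=1, seed=8)
    assert not np.array_equal(a.V_H, c.V_H)


def test_fitness_accounting_identities(strategy_cohorts):
    """V_H and V_S are the sums of B and W_rep over the steps lived."""
    for cohort in strategy_cohorts.values():
        vh = np.nansum(np.where(cohort.alive, np.nan_to_num(cohort.B), 0.0), axis=1)
        vs = np.nansum(np.where(cohort.alive, np.nan_to_num(cohort.W_rep), 0.0), axis=1)
        np.testing.assert_allclose(cohort.V_H, vh, rtol=1e-12)
        np.testing.assert_allclose(cohort.V_S, vs, rtol=1e-12)


def test_host_without_symbiont_earns_nothing():
    params = ModelParams(T=10)
    rec = simulate_host(10.0, 0.0, StrategySpec(kind="fixed"), params, seed=3)
    assert np.all((rec["W"] == 0) | np.isnan(rec["W"]))
    assert rec["V_H"] == 0.0 and rec["V_S"] == 0.0
    # base-case survival is zero without symbionts: death after the first step
    assert rec["alive"].sum() == 1


def test_no_transmission_zero_fitness(base_params):
    from symdens import backward_induction

    params = ModelParams(T=12, gamma=0.0)
    sol = backward_induction(params)
    c = simulate_cohort(
        StrategySpec(kind="optimal", policy=sol), params, replicates=1, seed=0,
        deterministic=True,
    )
    assert np.all(c.V_H == 0.0) and np.all(c.V_S == 0.0)


def test_empty_perturbation_is_noop(base_params, base_solution):
    spec = StrategySpec(kind="optimal", policy=base_solution)
    kw = dict(replicates=1, seed=5, deterministic=True)
    plain = simulate_cohort(spec, base_params, **kw)
    pert = simulate_perturbed_cohort(spec, PerturbationSpec(times=()), base_params, **kw)
    np.testing.assert_array_equal(plain.W, pert.W)


def test_perturbation_outside_horizon_rejected(base_params, base_solution):
    spec = StrategySpec(kind="optimal", policy=base_solution)
    with pytest.raises(ValueError):
        simulate_perturbed_cohort(spec, PerturbationSpec(times=(99,)), base_params)


def test_perturbed_cohort_reconverges(base_params, base_solution):
    """A reset to the t = 1 state is absorbed within the following cycle."""
    spec = StrategySpec(kind="optimal", policy=base_solution)
    kw = dict(replicates=1, seed=5, deterministic=True)
    plain = simulate_cohort(spec, base_params, **kw)
    pert = simulate_perturbed_cohort(spec, PerturbationSpec(times=(24,)), base_params, **kw)
    # at the perturbation step states are back at their t = 1 values
    np.testing.assert_array_equal(pert.W[:, 23], pert.W0)
    # reconvergence mirrors the initial collapse: two cycles suffice
    assert abs(np.nanmean(pert.W[:, 31]) - np.nanmean(plain.W[:, 31])) < 0.3
    assert np.nanmax(pert.W[:, 31]) - np.nanmin(pert.W[:, 31]) < 1.0
    assert abs(np.nanmean(pert.W[:, 35]) - np.nanmean(plain.W[:, 35])) < 0.15


def test_initial_density_range_collapses_by_first_reproduction(base_cohort_det):
    W8 = base_cohort_det.W[:, 7]
    assert np.nanmax(W8) - np.nanmin(W8) < 4.0  # from an initial range of 19


def test_cohort_summary_consistency(base_cohort_det):
    df = cohort_summary(base_cohort_det)
    assert len(df) == 50
    row = df[df.t == 8].iloc[0]
    assert row.min_W <= row.mean_W <= row.max_W
    assert row.frac_alive == 1.0  # deterministic mode
    assert "V_H_mean" in df.attrs and df.attrs["V_H_sd"] >= 0.0
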
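"""Unit and property tests of the within-step dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symdens import (
    HostState,
    ModelParams,
    ScenarioConfig,
    immediate_fitness,
    metabolic_expenditure,
    reproduction_event,
    reserve_transition,
    step,
    step_arrays,
    survival_probability,
    symbiont_transition,
)

BASE = ModelParams()
SC = ScenarioConfig()


@pytest.mark.parametrize(
    "E, mu, omega, expected",
    [
        (10.0, 0.2, 2.0, 6.0),
        (0.0, 0.2, 2.0, -2.0),  # negative intermediate is allowed
        (7.0, 0.0, 0.0, 7.0),
    ],
)
def test_metabolic_expenditure(E, mu, omega, expected):
    params = ModelParams(mu=mu, omega=omega)
    assert metabolic_expenditure(E, params) == pytest.approx(expected)


def test_reproduction_on_scheduled_step_with_sufficient_state():
    E2, W1, E_rep, W_rep, rep = reproduction_event(10.0, 8.0, 8, BASE, SC)
    assert bool(rep)
    assert (E2, W1, E_rep, W_rep) == pytest.approx((7.0, 6.4, 3.0, 1.6))


@pytest.mark.parametrize(
    "E_prime, W, t",
    [
        (10.0, 8.0, 7),  # not a scheduled step
        (5.0, 10.0, 8),  # reserves below threshold
        (10.0, 5.0, 8),  # density below threshold
    ],
)
def test_reproduction_gates(E_prime, W, t):
    E2, W1, E_rep, W_rep, rep = reproduction_event(E_prime, W, t, BASE, SC)
    assert not bool(rep)
    assert (E2, W1, E_rep, W_rep) == pytest.approx((E_prime, W, 0.0, 0.0))


def test_non_essential_reproduction_ignores_density_threshold():
    sc = ScenarioConfig(variant="non_essential")
    *_, rep = reproduction_event(10.0, 0.0, 8, BASE, sc)
    assert bool(rep)


@pytest.mark.parametrize(
    "W_prime, u, expected",
    [
        (4.0, 0.0, 3.0),  # zero allocation: exactly a 25% reduction
        (0.0, 8.0, 0.0),  # extinction is absorbing
        (1.0, 8.0, 4.75),
    ],
)
def test_symbiont_transition(W_prime, u, expected):
    assert symbiont_transition(W_prime, u, BASE) == pytest.approx(expected)


@pytest.mark.parametrize(
    "E_dprime, u, expected",
    [
        (7.0, 3.0, 12.0),
        (5.0, 8.0, 5.0),  # all income allocated
        (14.0, 0.0, 20.0),  # clamped from 22
    ],
)
def test_reserve_transition(E_dprime, u, expected):
    assert reserve_transition(E_dprime, u, BASE) == pytest.approx(expected)


@pytest.mark.parametrize("fn", [symbiont_transition, reserve_transition])
@pytest.mark.parametrize("u", [-0.5, 8.5])
def test_infeasible_allocation_rejected(fn, u):
    with pytest.raises(ValueError):
        fn(5.0, u, BASE)


def test_survival_base_case():
    s = survival_probability(10.0, 10.0, 5, BASE, SC)
    assert s == pytest.approx((1 - math.exp(-3)) ** 2)
    assert survival_probability(10.0, 0.0, 5, BASE, SC) == 0.0


def test_survival_temporary_benefit_after_maturation():
    sc = ScenarioConfig(variant="temporary_benefit")
    assert survival_probability(10.0, 0.0, 9, BASE, sc) == pytest.approx(1 - math.exp(-3))
    # before maturation the density factor still applies
    assert survival_probability(10.0, 0.0, 7, BASE, sc) == 0.0


def test_survival_non_essential_density_offset():
    sc = ScenarioConfig(variant="non_essential")
    s = survival_probability(10.0, 0.0, 5, BASE, sc)
    assert s == pytest.approx((1 - math.exp(-3)) * (1 - math.exp(-0.6)))


@given(
    E=st.floats(-50, 50),
    W=st.floats(-50, 50),
    t=st.integers(1, 50),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_survival_bounded_for_any_input(E, W, t):
    for variant in ("base", "non_essential", "temporary_benefit"):
        s = survival_probability(E, W, t, BASE, ScenarioConfig(variant=variant))
        assert 0.0 <= s <= 1.0


def test_immediate_fitness():
    assert immediate_fitness(3.0, 1.6, SC) == pytest.approx(4.8)
    assert immediate_fitness(0.0, 0.0, SC) == 0.0
    sc = ScenarioConfig(variant="symbiont_optimal")
    assert immediate_fitness(3.0, 1.6, sc) == pytest.approx(1.6)
    assert immediate_fitness(3.0, 1.6, sc, objective="host") == pytest.approx(4.8)


def test_immediate_fitness_non_essential_offset_only_at_reproduction():
    sc = ScenarioConfig(variant="non_essential")
    assert immediate_fitness(3.0, 1.6, sc, reproduced=True) == pytest.approx(
        0.5 * 3.0 * 1.6 + 5.0
    )
    assert immediate_fitness(0.0, 0.0, sc, reproduced=False) == 0.0


def test_step_chains_all_events():
    out = step(HostState(E=10.0, W=8.0, t=8), 3.0, BASE, SC)
    assert out.E_prime == pytest.approx(6.0)
    assert bool(out.reproduced)
    assert out.E_rep == pytest.approx(1.8)
    assert out.E_dprime == pytest.approx(4.2)
    assert out.W_rep == pytest.approx(1.6)
    assert out.W_prime == pytest.approx(6.4)
    assert out.W_dprime == pytest.approx(6.3)
    assert out.E_tprime == pytest.approx(9.2)
    assert out.B == pytest.approx(2.88)
    assert 0.0 <= out.S <= 1.0


def test_step_rejects_dead_host():
    with pytest.raises(ValueError):
        step(HostState(E=10.0, W=8.0, t=5, alive=False), 3.0, BASE, SC)


@given(
    E=st.floats(0, 20),
    W=st.floats(0.01, 20),
    t=st.integers(1, 49),
    u=st.floats(0, 8),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_energy_conservation_without_clamping(E, W, t, u):
    out = step_arrays(E, W, t, u, BASE, SC)
    raw_next = float(out.E_dprime) + BASE.N - u
    if 0.0 <= raw_next <= BASE.E_max:  # clamp did not trigger
        delta = float(out.E_tprime) - E
        assert delta == pytest.approx(BASE.N - u - float(out.E_exp) - float(out.E_rep))


@given(W=st.floats(0.01, 20), k=st.integers(1, 10))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_zero_allocation_geometric_decay(W, k):
    """With u = 0 and no reproduction, W decays by exactly (1 - alpha*beta) per step."""
    w = W
    for _ in range(k):
        w = symbiont_transition(w, 0.0, BASE)
    assert w == pytest.approx(W * 0.75**k)


@given(W_prime=st.floats(16.001, 40), u=st.floats(0, 8))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_decline_ceiling_above_sustainable_density(W_prime, u):
    """Above N/alpha = 16 no admissible allocation can sustain the density."""
    params = ModelParams(W_max=40)
    assert symbiont_transition(W_prime, u, params) < W_prime


def test_extinction_absorbing():
    w = 0.0
    for u in (0.0, 4.0, 8.0):
        w = symbiont_transition(w, u, BASE)
        assert w == 0.0
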
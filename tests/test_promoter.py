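"""Promoter occupancy functions, decay fluxes, and the production curve."""

import math

import numpy as np
import pytest

from clockwave.equilibrium import EquilibriumState, solve_dimer_equilibrium
from clockwave.params import ParameterSet, ScenarioConfig
from clockwave.promoter import (clock_decay_flux, clock_production_curve,
                                clock_promoter_activity, signal_promoter_activity)

SC1 = ScenarioConfig.from_name("I")
SC2 = ScenarioConfig.from_name("III")


def enumeration_oracle(R, A, q, k_r, c_r, k_a, c_a, n_sites):
    """Boltzmann-weighted enumeration of all promoter states.

    States: RNAP bound (with or without activator, repressor sites empty)
    transcribe; otherwise the activator site and each of the n repressor
    sites fill independently, with cooperativity c_r between two
    simultaneously bound repressor dimers.
    """
    transcribing = q + q * c_a * k_a * A
    silent = 0.0
    for a in (0, 1):
        wa = (k_a * A) ** a
        for r in range(n_sites + 1):
            wr = math.comb(n_sites, r) * (k_r * R) ** r
            if r == 2:
                wr *= c_r
            silent += wa * wr
    return transcribing / (transcribing + silent)


@pytest.mark.parametrize("n_sites", [1, 2])
def test_state_enumeration_oracle_agreement(n_sites):
    rng = np.random.default_rng(3)
    sc = ScenarioConfig.from_name("I" if n_sites == 1 else "III")
    for _ in range(100):
        ps = ParameterSet(
            q=10 ** rng.uniform(-1.5, 0.5), k_r=10 ** rng.uniform(-2, 0),
            c_r=rng.uniform(1, 100), k_a=10 ** rng.uniform(-6, -4),
            c_a=rng.uniform(1, 50),
        )
        R, A = rng.uniform(0, 500), rng.uniform(0, 2000)
        got = clock_promoter_activity(R, A, ps, sc)
        want = enumeration_oracle(R, A, ps.q, ps.k_r, ps.c_r, ps.k_a, ps.c_a, n_sites)
        assert got == pytest.approx(want, rel=1e-12)


def test_empty_promoter_limit():
    ps = ParameterSet(q=0.7)
    assert clock_promoter_activity(0.0, 0.0, ps, SC2) == pytest.approx(0.7 / 1.7)
    assert signal_promoter_activity(0.0, ps) == pytest.approx(0.7 / 1.7)


def test_full_repression_limit_monotone():
    ps = ParameterSet()
    vals = [clock_promoter_activity(R, 100.0, ps, SC2) for R in (0, 10, 1e3, 1e6, 1e9)]
    assert all(a > b for a, b in zip(vals, vals[1:]))
    assert vals[-1] < 1e-9


def test_single_site_hand_value():
    # q=0.5, k_r=0.1, R=10, A=0: 0.5 / (0.5 + (1 + 1)) = 0.2
    ps = ParameterSet(q=0.5, k_r=0.1)
    assert clock_promoter_activity(10.0, 0.0, ps, SC1) == pytest.approx(0.2)


def test_signal_promoter_hand_value():
    # q=1, k_r=0.1, R=40: 1 / (1 + 1 + 4) = 1/6
    ps = ParameterSet(q=1.0, k_r=0.1)
    assert signal_promoter_activity(40.0, ps) == pytest.approx(1.0 / 6.0)
    assert signal_promoter_activity(40.0, ps, q=2.0) == pytest.approx(2.0 / 7.0)


def test_two_sites_without_cooperativity_square_factor():
    ps = ParameterSet(c_r=1.0)
    rng = np.random.default_rng(4)
    for R in rng.uniform(0, 300, 20):
        f2 = clock_promoter_activity(R, 0.0, ps, SC2)
        x = ps.k_r * R
        expect = ps.q / (ps.q + (1 + x) ** 2)
        assert f2 == pytest.approx(expect, rel=1e-12)


def test_monotonicity_in_repressor_and_activator():
    rng = np.random.default_rng(5)
    ps = ParameterSet(c_a=25.0)
    for _ in range(50):
        R, A = rng.uniform(0, 400), rng.uniform(0, 2000)
        h = 1e-3
        down = clock_promoter_activity(R + h, A, ps, SC2) - clock_promoter_activity(R, A, ps, SC2)
        up = clock_promoter_activity(R, A + h, ps, SC2) - clock_promoter_activity(R, A, ps, SC2)
        assert down < 0
        assert up > 0  # c_a > 1 makes the activator activating
        assert 0.0 < clock_promoter_activity(R, A, ps, SC2) < 1.0


def test_linear_decay_identity_with_equal_rates():
    # scenarios II/IV collapse the flux to delta_p * total clock protein
    ps = ParameterSet(delta_p=0.35).with_scenario("IV")
    eq = solve_dimer_equilibrium(800.0, 300.0, ps)
    flux = clock_decay_flux(eq, ps)
    assert flux == pytest.approx(ps.delta_p * 800.0, rel=1e-12)


def test_monomer_only_decay_is_sublinear():
    ps = ParameterSet(delta_p=0.35).with_scenario("III")
    eq = solve_dimer_equilibrium(800.0, 300.0, ps)
    assert eq.hh > 0 and eq.pg > 0
    assert clock_decay_flux(eq, ps) < ps.delta_p * 800.0


def test_decay_flux_hand_value():
    ps = ParameterSet(delta_p=0.3).with_scenario("III")
    eq = EquilibriumState(p=10.0, g=0.0, hh=5.0, gg=0.0, pg=20.0)
    assert clock_decay_flux(eq, ps) == pytest.approx(3.0)


def test_production_curve_limits_and_ordering():
    ps = ParameterSet(q=1.0, k_r=0.05, c_r=10.0, K_hh=100.0)
    grid = np.linspace(0.0, 600.0, 40)
    c2 = clock_production_curve(grid, G=0.0, A=0.0, params=ps, scenario=SC2)
    c1 = clock_production_curve(grid, G=0.0, A=0.0, params=ps, scenario=SC1)
    # empty-promoter value at P = 0
    assert c2[0] == pytest.approx(ps.kappa_m * ps.q / (ps.q + 1.0))
    # monotone non-increasing, and two sites repress at least as hard
    assert np.all(np.diff(c2) <= 1e-12)
    assert np.all(c2[1:] <= c1[1:] + 1e-12)


def test_production_curve_spot_value_composes_verified_ops():
    ps = ParameterSet(q=1.0, k_r=0.05, c_r=10.0, K_hh=100.0)
    (val,) = clock_production_curve([200.0], G=0.0, A=0.0, params=ps, scenario=SC2)
    eq = solve_dimer_equilibrium(200.0, 0.0, ps)
    assert val == pytest.approx(ps.kappa_m * clock_promoter_activity(eq.hh, 0.0, ps, SC2))
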
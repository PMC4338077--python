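"""Group payoffs under the majority-signal quorum rule and bimorphic fitness.

The brute-force oracle re-derives the expected fitness by enumerating
every possible draw of co-players explicitly, independently of the
hypergeometric-weight implementation.
"""

import itertools
import math

import numpy as np
import pytest

from quorumsignal import (
    GameParams,
    base_payoff,
    bimorphic_fitness,
    expected_focal_payoff,
    fitness_profiles,
    focal_state_payoff,
    majority_signal,
    parse_label,
    signal_flip,
)
from quorumsignal.payoffs import TIE

FIG1 = dict(Z=100, N=9, M=5, c=0.5, c_S=0.2, F=10.0, gamma=5.0)


# ---------------------------------------------------------------- majority

@pytest.mark.parametrize(
    "ones, N, expected",
    [(5, 9, 1), (0, 9, 0), (9, 18, TIE), (4, 9, 0), (10, 18, 1), (2, 4, TIE)],
)
def test_majority_signal(ones, N, expected):
    assert majority_signal(ones, N) == expected


def test_majority_signal_rejects_out_of_range():
    with pytest.raises(ValueError):
        majority_signal(10, 9)
    with pytest.raises(ValueError):
        majority_signal(-1, 9)


# ---------------------------------------------------------------- base payoff

def test_base_payoff_defector_at_threshold():
    p = GameParams(**FIG1, lam=0.5)
    # 5 cooperators exactly meet M=5: theta(0) = 1, defector shares F*k*c/N
    assert base_payoff(False, 5, "alpha", p) == pytest.approx(25 / 9)
    assert base_payoff(True, 5, "alpha", p) == pytest.approx(25 / 9 - 0.5)


def test_base_payoff_loner_variant():
    p = GameParams(**FIG1, lam=0.5, shirker_role="loner")
    # cooperator against loners: F*c*theta(k-M) - c = 5 - 0.5
    assert base_payoff(True, 5, "alpha", p) == pytest.approx(4.5)
    # loners always get exactly zero, in both states
    for k in range(p.N + 1):
        assert base_payoff(False, k, "alpha", p) == 0.0
        assert base_payoff(False, k, "beta", p) == 0.0


def test_base_payoff_state_beta_kills_benefit():
    p = GameParams(**FIG1, lam=0.5)
    for k in range(1, p.N + 1):
        assert base_payoff(True, k, "beta", p) == pytest.approx(-p.c)
        assert base_payoff(False, k, "beta", p) == 0.0


def test_base_payoff_below_threshold_is_zero_for_defector():
    p = GameParams(**FIG1, lam=0.5)
    assert base_payoff(False, 4, "alpha", p) == 0.0


def test_base_payoff_input_errors():
    p = GameParams(**FIG1, lam=0.5)
    with pytest.raises(ValueError):
        base_payoff(False, p.N + 1, "alpha", p)
    with pytest.raises(ValueError):
        base_payoff(True, 0, "alpha", p)


def test_cooperator_pays_exactly_c_more_than_defector():
    # Pi_C(k) = Pi_D(k) - c for every k >= 1 and both states (defector role)
    p = GameParams(**FIG1, lam=0.5)
    for state in ("alpha", "beta"):
        for k in range(1, p.N + 1):
            assert base_payoff(True, k, state, p) == pytest.approx(
                base_payoff(False, k, state, p) - p.c
            )


# ------------------------------------------------------------- group payoff

def test_all_signalers_cooperate_under_alpha():
    p = GameParams(**FIG1, lam=0.5)
    g = parse_label("(10|01)")
    # all 9 emit 1, majority 1, all cooperate: 10*9*0.5/9 - 0.5 - 0.2
    assert focal_state_payoff(g, g, 9, 0, "alpha", p) == pytest.approx(4.3)
    # under beta nobody signals, majority 0, A0 = 0: no action, no cost
    assert focal_state_payoff(g, g, 9, 0, "beta", p) == 0.0


def test_inert_strategy_scores_zero():
    p = GameParams(**FIG1, lam=0.5)
    g = parse_label("(00|00)")
    assert focal_state_payoff(g, g, 9, 0, "alpha", p) == 0.0


def test_signal_cost_charged_even_when_action_is_shirk():
    p = GameParams(**FIG1, lam=0.5)
    g = parse_label("(10|00)")  # signals under alpha but never cooperates
    assert focal_state_payoff(g, g, 9, 0, "alpha", p) == pytest.approx(-p.c_S)


def test_tie_averages_both_majority_readings():
    p = GameParams(Z=100, N=4, M=2, c=0.5, c_S=0.2, F=10.0, lam=0.5, gamma=5.0)
    focal = parse_label("(10|01)")  # emits 1 under alpha, cooperates on majority 1
    other = parse_label("(00|11)")  # silent, always cooperates
    # 2 of 4 emit signal 1 -> exact tie. Reading 1: all 4 cooperate (k=4).
    # Reading 0: only the two (00|11) cooperate (k=2 >= M).
    pay1 = p.F * 4 * p.c / p.N - p.c
    pay0 = 0.0 + p.F * 2 * p.c / p.N  # focal shirks, still shares as defector
    expected = 0.5 * (pay1 + pay0) - p.c_S
    assert focal_state_payoff(focal, other, 2, 2, "alpha", p) == pytest.approx(expected)


def test_group_composition_validation():
    p = GameParams(**FIG1, lam=0.5)
    g = parse_label("(10|01)")
    with pytest.raises(ValueError):
        focal_state_payoff(g, g, 0, 9, "alpha", p)
    with pytest.raises(ValueError):
        focal_state_payoff(g, g, 5, 5, "alpha", p)


def test_state_mixture():
    g = parse_label("(10|01)")
    p = GameParams(**FIG1, lam=0.5)
    assert expected_focal_payoff(g, g, 9, 0, p) == pytest.approx(0.5 * 4.3 + 0.5 * 0.0)
    p1 = p.replace(lam=1.0)
    assert expected_focal_payoff(g, g, 9, 0, p1) == pytest.approx(
        focal_state_payoff(g, g, 9, 0, "alpha", p1)
    )
    p0 = p.replace(lam=0.0)
    assert expected_focal_payoff(g, g, 9, 0, p0) == pytest.approx(
        focal_state_payoff(g, g, 9, 0, "beta", p0)
    )


# --------------------------------------------------------- bimorphic fitness

def _oracle_group_payoff(focal, members, state, p):
    """Independent first-principles group play (averaging exact ties)."""
    N = len(members)
    ones = sum(m.sigma_alpha if state == "alpha" else m.sigma_beta for m in members)
    readings = [1] if 2 * ones > N else [0] if 2 * ones < N else [0, 1]
    total = 0.0
    for maj in readings:
        acts = [(m.a1 if maj else m.a0) for m in members]
        k = sum(acts)
        mine = acts[0]
        quorum = k >= p.M
        if p.shirker_role == "loner":
            pay = (p.F * p.c * quorum - p.c if mine else 0.0) if state == "alpha" else (
                -p.c if mine else 0.0
            )
        else:
            benefit = (p.F * k * p.c / p.N * quorum) if state == "alpha" else 0.0
            pay = benefit - p.c if mine else benefit
        total += pay
    pay = total / len(readings)
    if (focal.sigma_alpha if state == "alpha" else focal.sigma_beta) == 1:
        pay -= p.c_S
    return pay


@pytest.mark.parametrize("role", ["defector", "loner"])
def test_bimorphic_fitness_matches_exhaustive_enumeration(role):
    p = GameParams(Z=20, N=5, M=3, c=0.5, c_S=0.2, F=10.0, lam=0.7, gamma=1.0,
                   shirker_role=role)
    U, V = parse_label("(10|01)"), parse_label("(00|00)")
    k = 10
    for focal, others_pool in [
        (U, [U] * (k - 1) + [V] * (p.Z - k)),
        (V, [U] * k + [V] * (p.Z - k - 1)),
    ]:
        total = 0.0
        n_draws = 0
        for co in itertools.combinations(range(p.Z - 1), p.N - 1):
            members = [focal] + [others_pool[i] for i in co]
            pay = p.lam * _oracle_group_payoff(focal, members, "alpha", p)
            pay += (1 - p.lam) * _oracle_group_payoff(focal, members, "beta", p)
            total += pay
            n_draws += 1
        assert n_draws == math.comb(p.Z - 1, p.N - 1)
        prof = bimorphic_fitness(U, V, k, p)
        got = prof.omega_U if focal is U else prof.omega_V
        assert got == pytest.approx(total / n_draws, rel=1e-12)


def test_group_equals_population_collapses_hypergeometric():
    p = GameParams(Z=6, N=6, M=3, c=0.5, c_S=0.2, F=10.0, lam=0.6, gamma=1.0)
    U, V = parse_label("(10|01)"), parse_label("(00|11)")
    for k in range(1, p.Z):
        prof = bimorphic_fitness(U, V, k, p)
        assert prof.omega_U == pytest.approx(expected_focal_payoff(U, V, k, p.Z - k, p))
        assert prof.omega_V == pytest.approx(expected_focal_payoff(V, U, p.Z - k, k, p))


def test_bimorphic_fitness_rejects_boundary_counts():
    p = GameParams(**FIG1, lam=0.5)
    U, V = parse_label("(10|01)"), parse_label("(00|00)")
    for k in (0, p.Z):
        with pytest.raises(ValueError):
            bimorphic_fitness(U, V, k, p)


# ----------------------------------------------------------------- symmetries

def test_fitness_ignores_beta_signal_when_nature_is_always_alpha(full_space):
    p = GameParams(**FIG1, lam=1.0)
    U, V = parse_label("(10|01)"), parse_label("(00|11)")
    flip = lambda g: g.__class__(g.sigma_alpha, 1 - g.sigma_beta, g.a0, g.a1)
    a = fitness_profiles(U, V, p)
    b = fitness_profiles(flip(U), flip(V), p)
    np.testing.assert_allclose(a[0], b[0], rtol=1e-14)
    np.testing.assert_allclose(a[1], b[1], rtol=1e-14)


def test_costless_signals_make_the_two_systems_equivalent():
    p = GameParams(Z=40, N=7, M=4, c=0.5, c_S=0.0, F=10.0, lam=0.6, gamma=2.0)
    U, V = parse_label("(10|01)"), parse_label("(00|10)")
    a = fitness_profiles(U, V, p)
    b = fitness_profiles(signal_flip(U), signal_flip(V), p)
    np.testing.assert_allclose(a[0], b[0], rtol=1e-14)
    np.testing.assert_allclose(a[1], b[1], rtol=1e-14)
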
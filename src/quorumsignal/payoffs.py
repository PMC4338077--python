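"""Group payoffs and expected fitness in a bimorphic population.

Each group of ``N`` individuals plays a threshold public goods game whose
benefit depends on the state of Nature.  Under state alpha, ``k``
cooperators produce a per-beneficiary benefit ``F*k*c/N`` once ``k >= M``
(Heaviside convention: exactly meeting the threshold pays); under state
beta the benefit factor is zero, so cooperation is pure cost.  Members
first emit their genotype's signal for the realized state, then everyone
acts on the majority signal in the group (ties are a fair coin flip).
Shirkers are either defectors (share the benefit) or loners (get zero).

Expected fitness in a well-mixed population of ``Z`` individuals with two
strategies present follows from hypergeometric sampling of the ``N - 1``
co-players of a focal individual.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import comb

from .params import GameParams, LONER
from .strategies import Strategy

__all__ = [
    "majority_signal",
    "base_payoff",
    "focal_state_payoff",
    "expected_focal_payoff",
    "bimorphic_fitness",
    "fitness_profiles",
    "pair_payoff_table",
    "FitnessProfile",
    "TIE",
]

#: Sentinel returned by :func:`majority_signal` when the group splits evenly.
TIE = "tie"

ALPHA = "alpha"
BETA = "beta"


def majority_signal(ones: int, N: int):
    """Majority signal in a group where ``ones`` of ``N`` members emit signal 1.

    Returns 1 for a strict majority of signal-1 emitters, 0 for a strict
    minority, and :data:`TIE` for an exact split (possible only for even N).
    """
    if not 0 <= ones <= N:
        raise ValueError(f"ones must lie in [0, {N}], got {ones}")
    if 2 * ones > N:
        return 1
    if 2 * ones < N:
        return 0
    return TIE


def base_payoff(cooperates: bool, k: int, state: str, p: GameParams) -> float:
    """Game payoff of one group member, before any signaling cost.

    Parameters
    ----------
    cooperates : bool
        Whether the focal member cooperates.
    k : int
        Total number of cooperators in the group (including the focal
        member if it cooperates).
    state : str
        Realized state of Nature, ``"alpha"`` or ``"beta"``.
    """
    if not 0 <= k <= p.N:
        raise ValueError(f"cooperator count k must lie in [0, {p.N}], got {k}")
    if cooperates and k < 1:
        raise ValueError("a cooperating focal implies k >= 1")
    F = p.F if state == ALPHA else 0.0
    quorum = 1.0 if k >= p.M else 0.0  # theta(k - M), theta(0) = 1
    if p.shirker_role == LONER:
        if cooperates:
            return F * p.c * quorum - p.c
        return 0.0
    benefit = F * k * p.c / p.N * quorum
    return benefit - p.c if cooperates else benefit


def focal_state_payoff(
    focal: Strategy,
    other: Strategy,
    n_focal: int,
    n_other: int,
    state: str,
    p: GameParams,
) -> float:
    """Expected payoff of a focal individual in one group, for a given state.

    The group holds ``n_focal`` members of the focal's genotype (including
    the focal itself) and ``n_other`` members of the other genotype.  All
    members emit their state-dependent signal, act on the majority signal
    (an exact tie averages the two readings, i.e. the expectation over the
    coin flip), and the focal pays the signaling cost ``c_S`` whenever its
    own emitted signal is 1.
    """
    if n_focal < 1 or n_other < 0 or n_focal + n_other != p.N:
        raise ValueError(
            f"invalid group composition ({n_focal}, {n_other}) for N={p.N}"
        )
    sig_f = focal.signal(state)
    sig_o = other.signal(state)
    ones = n_focal * sig_f + n_other * sig_o
    maj = majority_signal(ones, p.N)
    readings = (0, 1) if maj == TIE else (maj,)
    total = 0.0
    for m in readings:
        act_f = focal.action(m)
        act_o = other.action(m)
        k = n_focal * act_f + n_other * act_o
        total += base_payoff(act_f == 1, k, state, p)
    payoff = total / len(readings)
    if sig_f == 1:
        payoff -= p.c_S
    return payoff


def expected_focal_payoff(
    focal: Strategy, other: Strategy, n_focal: int, n_other: int, p: GameParams
) -> float:
    """State-averaged group payoff: lambda * Pi^alpha + (1 - lambda) * Pi^beta."""
    pay = 0.0
    if p.lam > 0.0:
        pay += p.lam * focal_state_payoff(focal, other, n_focal, n_other, ALPHA, p)
    if p.lam < 1.0:
        pay += (1.0 - p.lam) * focal_state_payoff(focal, other, n_focal, n_other, BETA, p)
    return pay


def pair_payoff_table(focal: Strategy, other: Strategy, p: GameParams) -> np.ndarray:
    """Expected payoff of a ``focal``-type individual by co-player composition.

    Entry ``m`` is the state-averaged payoff when ``m`` of the focal's
    ``N - 1`` co-players share its genotype (group composition
    ``(m + 1, N - 1 - m)``).  Length ``N``.
    """
    return np.array(
        [expected_focal_payoff(focal, other, m + 1, p.N - 1 - m, p) for m in range(p.N)]
    )


@dataclass(frozen=True)
class FitnessProfile:
    """Expected payoffs of both types when ``k`` of ``Z`` individuals are type U."""

    k: int
    omega_U: float
    omega_V: float


@lru_cache(maxsize=4096)
def fitness_profiles(U: Strategy, V: Strategy, p: GameParams):
    """Expected fitness of U- and V-individuals for every mixed composition.

    Returns ``(omega_U, omega_V)``: arrays of length ``Z - 1`` whose entry
    ``k - 1`` gives the expected payoff of a U (resp. V) individual when
    the population holds ``k`` U-strategists and ``Z - k`` V-strategists,
    for ``k = 1 .. Z - 1``.  Groups of size N are sampled without
    replacement from the other ``Z - 1`` individuals, so the number of
    same-type co-players of a focal individual is hypergeometric.
    """
    Z, N = p.Z, p.N
    pi_U = pair_payoff_table(U, V, p)
    pi_V = pair_payoff_table(V, U, p)
    k = np.arange(1, Z)[:, None]          # U count, column vector
    m = np.arange(N)[None, :]             # same-type co-players of the focal
    denom = comb(Z - 1, N - 1)
    # focal U: m U-co-players from k-1 other Us, N-1-m from Z-k Vs
    w_U = comb(k - 1, m) * comb(Z - k, N - 1 - m) / denom
    # focal V: m V-co-players from Z-k-1 other Vs, N-1-m from k Us
    w_V = comb(Z - k - 1, m) * comb(k, N - 1 - m) / denom
    omega_U = w_U @ pi_U
    omega_V = w_V @ pi_V
    omega_U.setflags(write=False)
    omega_V.setflags(write=False)
    return omega_U, omega_V


def bimorphic_fitness(U: Strategy, V: Strategy, k: int, p: GameParams) -> FitnessProfile:
    """Expected fitness of U and V individuals at a single composition ``k``.

    ``k`` is the number of U-strategists, ``1 <= k <= Z - 1``.
    """
    if not 1 <= k <= p.Z - 1:
        raise ValueError(f"k must lie in [1, {p.Z - 1}], got {k}")
    omega_U, omega_V = fitness_profiles(U, V, p)
    return FitnessProfile(k=k, omega_U=float(omega_U[k - 1]), omega_V=float(omega_V[k - 1]))
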
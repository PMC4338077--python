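"""Fermi pairwise-comparison dynamics and single-mutant fixation probabilities.

At each birth-death step two random individuals are paired and the first
imitates the second with the Fermi probability ``[1 + exp(-gamma*dOmega)]^-1``.
For a bimorphic population this yields a one-dimensional birth-death chain
over the mutant count ``k`` whose absorption probability (fixation of a
single mutant) has the standard closed form

    rho = [ sum_{i=0}^{Z-1} prod_{j=1}^{i} phi_j ]^-1,
    phi_j = T-(j)/T+(j) = exp(-gamma * (Omega_U(j) - Omega_V(j))).

The sum is evaluated in the log domain (cumulative sums of ``-gamma*dOmega``
followed by log-sum-exp) so strong selection does not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logsumexp

from .params import GameParams
from .payoffs import fitness_profiles
from .strategies import Strategy

__all__ = [
    "fermi_probability",
    "transition_rates",
    "fixation_probability",
    "TransitionRates",
    "FixationResult",
]


def fermi_probability(delta_omega: float, gamma: float) -> float:
    """Imitation probability ``[1 + exp(-gamma * delta_omega)]^-1``.

    ``delta_omega`` is the fitness advantage of the imitated individual
    over the imitating one.  Stable for arbitrarily large ``|gamma*delta|``.
    """
    if gamma < 0:
        raise ValueError(f"gamma must be non-negative, got {gamma}")
    return float(expit(gamma * delta_omega))


@dataclass(frozen=True)
class TransitionRates:
    """One-step probabilities of the mutant count moving up or down."""

    k: int
    t_plus: float
    t_minus: float


def transition_rates(U: Strategy, V: Strategy, k: int, p: GameParams) -> TransitionRates:
    """Probabilities T+/-(k) that the number of U-strategists changes by one.

    ``T+-(k) = (k/Z) * ((Z-k)/(Z-1)) * [1 + exp(-+ gamma*(Omega_U - Omega_V))]^-1``;
    both rates vanish at the absorbing boundaries k = 0 and k = Z.
    """
    if not 0 <= k <= p.Z:
        raise ValueError(f"k must lie in [0, {p.Z}], got {k}")
    if k == 0 or k == p.Z:
        return TransitionRates(k=k, t_plus=0.0, t_minus=0.0)
    omega_U, omega_V = fitness_profiles(U, V, p)
    delta = omega_U[k - 1] - omega_V[k - 1]
    prefactor = (k / p.Z) * ((p.Z - k) / (p.Z - 1))
    return TransitionRates(
        k=k,
        t_plus=prefactor * fermi_probability(delta, p.gamma),
        t_minus=prefactor * fermi_probability(-delta, p.gamma),
    )


@dataclass(frozen=True)
class FixationResult:
    """Fixation probability of one ``invader`` mutant among Z-1 ``resident``s."""

    invader: Strategy
    resident: Strategy
    rho: float
    neutral_rho: float


def _log_rho_from_delta(gamma: float, delta: np.ndarray) -> float:
    """log of rho given the fitness differences dOmega(j), j = 1..Z-1."""
    # partial products prod_{j<=i} phi_j in the log domain; i = 0 term is 1
    log_phi_cumsum = np.concatenate(([0.0], np.cumsum(-gamma * delta)))
    return -float(logsumexp(log_phi_cumsum))


def fixation_probability(invader: Strategy, resident: Strategy, p: GameParams) -> FixationResult:
    """Closed-form fixation probability of a single invader mutant.

    The neutral reference is 1/Z; selection favors the invasion whenever
    ``rho > 1/Z``.
    """
    if invader == resident:
        raise ValueError("invader and resident must be distinct strategies")
    omega_U, omega_V = fitness_profiles(invader, resident, p)
    rho = float(np.exp(_log_rho_from_delta(p.gamma, omega_U - omega_V)))
    return FixationResult(
        invader=invader, resident=resident, rho=rho, neutral_rho=1.0 / p.Z
    )
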
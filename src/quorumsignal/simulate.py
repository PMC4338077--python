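"""Stochastic birth-death simulation with mutation.

An explicit agent-based implementation of the same dynamics the analytic
modules treat in the small-mutation limit: at every step a random focal
individual imitates another random individual with the Fermi probability,
and with probability ``mu`` the updated individual's strategy is replaced
by one drawn uniformly from the strategy space (so a mutation event
overrides the imitation outcome for that step).  This simulator is the
independent check on the embedded-chain analytics and the only route to
appreciable mutation rates.

Two exact accelerations keep long runs affordable without changing the
process distribution: (i) while the population is monomorphic, imitation
is a no-op, so the dwell time until the next mutation event is drawn
directly from its geometric law; (ii) fixation-probability trials follow
the embedded jump chain over the mutant count (self-loops of the
birth-death chain do not affect which boundary absorbs the walk).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit

from .params import GameParams
from .payoffs import TIE, base_payoff, fitness_profiles, majority_signal
from .strategies import Strategy, StrategySpace, enumerate_strategies

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "FixationEstimate",
    "run_simulation",
    "estimate_fixation",
]

EXACT_BIMORPHIC = "exact_bimorphic"
SAMPLED_GROUPS = "sampled_groups"

_BLOCK = 8192  # batched RNG draws for the per-step loop


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one simulation run.

    ``fitness_mode`` controls fitness evaluation when more than two
    strategies coexist: ``"exact_bimorphic"`` falls back to sampled groups
    only in that (rare, small-mu) regime, while ``"sampled_groups"``
    always estimates fitness from ``n_group_samples`` random groups.
    With at most two strategies present the exact hypergeometric
    expectation is used under ``"exact_bimorphic"``.
    """

    p: GameParams
    mu: float = 0.0
    steps: int = 100_000
    burn_in: int = 0
    seed: int = 0
    fitness_mode: str = EXACT_BIMORPHIC
    n_group_samples: int = 50
    reduced: bool = False
    init_label: Optional[str] = None  # monomorphic start; None = random strategy
    thin: int = 0  # record counts every `thin` steps; 0 disables

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must lie in [0, 1], got {self.mu}")
        if not 0 <= self.burn_in < self.steps:
            raise ValueError("burn_in must satisfy 0 <= burn_in < steps")
        if self.fitness_mode not in (EXACT_BIMORPHIC, SAMPLED_GROUPS):
            raise ValueError(f"unknown fitness_mode {self.fitness_mode!r}")
        if self.n_group_samples < 1:
            raise ValueError("n_group_samples must be >= 1")


@dataclass(frozen=True)
class SimulationResult:
    """Time-averaged output of one run (fractions over retained steps)."""

    config: SimulationConfig
    space: StrategySpace
    time_averaged_frequencies: dict[str, float]
    monomorphic_occupancy: dict[str, float]
    trajectory_summary: Optional[list[tuple[int, list[int]]]] = field(default=None, repr=False)

    def monomorphic_fraction(self) -> float:
        return sum(self.monomorphic_occupancy.values())

    def to_dict(self) -> dict:
        return {
            "params": self.config.p.to_dict(),
            "mu": self.config.mu,
            "steps": self.config.steps,
            "burn_in": self.config.burn_in,
            "seed": self.config.seed,
            "fitness_mode": self.config.fitness_mode,
            "reduced": self.config.reduced,
            "time_averaged_frequencies": self.time_averaged_frequencies,
            "monomorphic_occupancy": self.monomorphic_occupancy,
        }


def _group_payoff(
    focal: Strategy, others: list[Strategy], state: str, p: GameParams, rng: np.random.Generator
) -> float:
    """Payoff of ``focal`` in one realized group; ties flip an actual coin."""
    members = [focal] + others
    ones = sum(g.signal(state) for g in members)
    maj = majority_signal(ones, p.N)
    if maj == TIE:
        maj = int(rng.integers(2))
    k = sum(g.action(maj) for g in members)
    pay = base_payoff(focal.action(maj) == 1, k, state, p)
    if focal.signal(state) == 1:
        pay -= p.c_S
    return pay


def _sampled_fitness(
    idx: int,
    pop: np.ndarray,
    strategies: list[Strategy],
    p: GameParams,
    rng: np.random.Generator,
    n_samples: int,
) -> float:
    """Mean payoff over sampled groups (focal plus N-1 distinct others)."""
    Z = len(pop)
    others_pool = np.concatenate([np.arange(idx), np.arange(idx + 1, Z)])
    focal = strategies[pop[idx]]
    total = 0.0
    for _ in range(n_samples):
        co = rng.choice(others_pool, size=p.N - 1, replace=False)
        others = [strategies[pop[c]] for c in co]
        pay = 0.0
        if p.lam > 0.0:
            pay += p.lam * _group_payoff(focal, others, "alpha", p, rng)
        if p.lam < 1.0:
            pay += (1.0 - p.lam) * _group_payoff(focal, others, "beta", p, rng)
        total += pay
    return total / n_samples


def run_simulation(cfg: SimulationConfig) -> SimulationResult:
    """Run the birth-death process and return time-averaged occupancies.

    Fully reproducible: identical ``cfg`` (including ``seed``) gives
    bit-identical results.  The population size is conserved throughout.
    """
    p = cfg.p
    Z = p.Z
    rng = np.random.default_rng(cfg.seed)
    space = enumerate_strategies(reduced=cfg.reduced)
    strategies = list(space)
    n_S = space.n_S

    if cfg.init_label is not None:
        start = space.index(cfg.init_label)
    else:
        start = int(rng.integers(n_S))
    pop = np.full(Z, start, dtype=np.int64)
    counts = np.zeros(n_S, dtype=np.int64)
    counts[start] = Z

    freq_acc = np.zeros(n_S)
    mono_acc = np.zeros(n_S)
    retained = 0
    trajectory: Optional[list[tuple[int, list[int]]]] = [] if cfg.thin else None
    next_record = cfg.thin

    def accumulate(n_steps: int, t: int) -> int:
        """Credit the current state for steps t .. t+n_steps-1; return new t."""
        nonlocal retained, next_record
        lo = max(t, cfg.burn_in)
        hi = t + n_steps
        if hi > lo:
            w = hi - lo
            freq_acc[:] += w * counts / Z
            if counts.max() == Z:
                mono_acc[int(np.argmax(counts))] += w
            retained += w
        if trajectory is not None:
            while next_record <= hi:
                trajectory.append((next_record, counts.tolist()))
                next_record += cfg.thin
        return hi

    # batched randoms for the per-step polymorphic loop
    buf_i = buf_j = buf_uf = buf_um = None
    buf_pos = _BLOCK

    def draw_step():
        nonlocal buf_i, buf_j, buf_uf, buf_um, buf_pos
        if buf_pos >= _BLOCK:
            buf_i = rng.integers(0, Z, _BLOCK)
            buf_j = rng.integers(0, Z - 1, _BLOCK)
            buf_uf = rng.random(_BLOCK)
            buf_um = rng.random(_BLOCK)
            buf_pos = 0
        i = int(buf_i[buf_pos])
        j = int(buf_j[buf_pos])
        if j >= i:
            j += 1
        uf = buf_uf[buf_pos]
        um = buf_um[buf_pos]
        buf_pos += 1
        return i, j, uf, um

    t = 0
    while t < cfg.steps:
        present = np.flatnonzero(counts)
        if present.size == 1:
            # monomorphic: imitation is a no-op, jump to the next mutation
            if cfg.mu == 0.0:
                t = accumulate(cfg.steps - t, t)
                break
            dwell = int(rng.geometric(cfg.mu))
            if t + dwell > cfg.steps:
                t = accumulate(cfg.steps - t, t)
                break
            if dwell > 1:
                t = accumulate(dwell - 1, t)
            i = int(rng.integers(Z))
            new = int(rng.integers(n_S))
            counts[pop[i]] -= 1
            pop[i] = new
            counts[new] += 1
            t = accumulate(1, t)
        else:
            i, j, uf, um = draw_step()
            si, sj = int(pop[i]), int(pop[j])
            if um < cfg.mu:
                new = int(rng.integers(n_S))
                counts[si] -= 1
                pop[i] = new
                counts[new] += 1
            elif si != sj:
                if present.size == 2 and cfg.fitness_mode == EXACT_BIMORPHIC:
                    a, b = int(present[0]), int(present[1])
                    om_a, om_b = fitness_profiles(strategies[a], strategies[b], p)
                    k = int(counts[a])
                    omega = {a: om_a[k - 1], b: om_b[k - 1]}
                    w_i, w_j = omega[si], omega[sj]
                else:
                    w_i = _sampled_fitness(i, pop, strategies, p, rng, cfg.n_group_samples)
                    w_j = _sampled_fitness(j, pop, strategies, p, rng, cfg.n_group_samples)
                if uf < expit(p.gamma * (w_j - w_i)):
                    counts[si] -= 1
                    pop[i] = sj
                    counts[sj] += 1
            t = accumulate(1, t)

    freqs = freq_acc / retained
    mono = mono_acc / retained
    return SimulationResult(
        config=cfg,
        space=space,
        time_averaged_frequencies={g.label: float(f) for g, f in zip(space, freqs)},
        monomorphic_occupancy={g.label: float(m) for g, m in zip(space, mono)},
        trajectory_summary=trajectory,
    )


@dataclass(frozen=True)
class FixationEstimate:
    """Empirical fixation probability with its binomial standard error."""

    invader: Strategy
    resident: Strategy
    rho_hat: float
    std_error: float
    n_trials: int
    n_fixed: int


def estimate_fixation(
    cfg: SimulationConfig, invader: Strategy, resident: Strategy, n_trials: int
) -> FixationEstimate:
    """Estimate the fixation probability of a single mutant by simulation.

    Each trial starts with one invader among ``Z - 1`` residents and runs
    the mutation-free process to absorption.  Trials follow the embedded
    jump chain over the mutant count: steps on which the count does not
    change are skipped, which leaves the absorption probability untouched
    (at interior count ``k`` the next change is +1 with probability
    ``T+(k) / (T+(k) + T-(k))``).
    """
    if invader == resident:
        raise ValueError("invader and resident must be distinct strategies")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    p = cfg.p
    Z = p.Z
    rng = np.random.default_rng(cfg.seed)
    omega_U, omega_V = fitness_profiles(invader, resident, p)
    # P(next change is up | change) at k = 1..Z-1
    p_up = expit(p.gamma * (omega_U - omega_V))

    state = np.ones(n_trials, dtype=np.int64)
    fixed = 0
    while state.size:
        u = rng.random(state.size)
        state = np.where(u < p_up[state - 1], state + 1, state - 1)
        fixed += int(np.sum(state == Z))
        state = state[(state > 0) & (state < Z)]
    rho_hat = fixed / n_trials
    se = float(np.sqrt(rho_hat * (1.0 - rho_hat) / n_trials))
    return FixationEstimate(
        invader=invader,
        resident=resident,
        rho_hat=rho_hat,
        std_error=se,
        n_trials=n_trials,
        n_fixed=fixed,
    )
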
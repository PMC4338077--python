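"""Small-mutation-limit embedded Markov chain over monomorphic states.

When mutations are rare the population is monomorphic almost all the time:
each new mutant either dies out or fixes before the next mutation arrives.
Evolution then reduces to a Markov chain whose states are the monomorphic
configurations (one per strategy) and whose off-diagonal transition
probabilities are ``eta * rho_{V,U}``, with ``rho_{V,U}`` the fixation
probability of a single U mutant in a resident V population and
``eta = 1/(n_S - 1)`` the probability that the mutant is of type U.  The
stationary distribution of this chain gives the long-run fraction of time
spent in each monomorphic state (the "prevalence" of each strategy).

A strategy is *evolutionarily robust* (ERS) when every possible single
mutant fixes with probability strictly below the neutral value 1/Z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .fixation import fixation_probability
from .params import GameParams
from .strategies import Strategy, StrategySpace, parse_label

__all__ = [
    "EmbeddedChain",
    "InvasionGraph",
    "DegenerateChainError",
    "fixation_matrix",
    "build_chain",
    "stationary_distribution",
    "ers_set",
    "stability_variants",
    "invasion_graph",
    "restrict_chain",
]

STABILITY_CRITERIA = ("ers", "ers_plus_fitness", "counter_invasion")

# comparisons against the neutral fixation probability 1/Z use a relative
# band so that exactly-neutral pairs (computed in the log domain, hence
# rounded at ~1e-16) classify as neutral rather than as marginal winners
# or losers
_NEUTRAL_RTOL = 1e-12


class DegenerateChainError(RuntimeError):
    """Raised when the stationary distribution is not unique."""


def fixation_matrix(space: StrategySpace, p: GameParams) -> np.ndarray:
    """Pairwise fixation probabilities ``rho[i, j] = rho_{i -> j}``.

    Row ``i`` is the resident strategy, column ``j`` the invading mutant;
    the diagonal is NaN (a strategy cannot invade itself).
    """
    n = space.n_S
    rho = np.full((n, n), np.nan)
    for i, resident in enumerate(space):
        for j, invader in enumerate(space):
            if i != j:
                rho[i, j] = fixation_probability(invader, resident, p).rho
    return rho


@dataclass(frozen=True)
class EmbeddedChain:
    """Transition matrix of the small-mutation embedded chain.

    ``T[i, j] = eta * rho[i, j]`` off the diagonal, with the diagonal
    completing each row to one; ``rho`` keeps the raw pairwise fixation
    probabilities so the chain can be restricted to strategy subsets
    without recomputation.
    """

    space: StrategySpace
    params: GameParams
    rho: np.ndarray = field(repr=False)
    T: np.ndarray = field(repr=False)

    @property
    def eta(self) -> float:
        return 1.0 / (self.space.n_S - 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.T, index=self.space.labels, columns=self.space.labels)


def _assemble(space: StrategySpace, p: GameParams, rho: np.ndarray) -> EmbeddedChain:
    n = space.n_S
    if np.any((rho[~np.eye(n, dtype=bool)] < 0) | (rho[~np.eye(n, dtype=bool)] > 1)):
        raise RuntimeError("fixation probabilities outside [0, 1]")
    eta = 1.0 / (n - 1)
    T = eta * np.where(np.eye(n, dtype=bool), 0.0, rho)
    diag = 1.0 - T.sum(axis=1)
    if np.any(diag < -1e-12) or np.any(diag > 1 + 1e-12):
        raise RuntimeError("diagonal entries of the embedded chain left [0, 1]")
    T[np.eye(n, dtype=bool)] = np.clip(diag, 0.0, 1.0)
    return EmbeddedChain(space=space, params=p, rho=rho, T=T)


def build_chain(space: StrategySpace, p: GameParams) -> EmbeddedChain:
    """Build the embedded chain from all pairwise fixation probabilities."""
    return _assemble(space, p, fixation_matrix(space, p))


def stationary_distribution(chain: EmbeddedChain) -> np.ndarray:
    """Stationary distribution ``pi`` of the embedded chain (``pi T = pi``).

    Solved as a linear system with the normalization constraint appended,
    which is deterministic.  Uniqueness requires a single closed
    communicating class of the transition graph (off-diagonal entries
    that are exactly zero are absent edges); a chain with several closed
    classes raises :class:`DegenerateChainError` naming them.  Strong
    selection routinely produces metastable chains (second eigenvalue
    extremely close to one); those remain irreducible and are solved
    normally.
    """
    T = chain.T
    n = T.shape[0]
    mask = np.where(np.eye(n, dtype=bool), 0.0, T)
    g = nx.from_numpy_array((mask > 0.0).astype(int), create_using=nx.DiGraph)
    cond = nx.condensation(g)
    closed = [c for c in cond.nodes if cond.out_degree(c) == 0]
    if len(closed) != 1:
        members = [sorted(chain.space[i].label for i in cond.nodes[c]["members"]) for c in closed]
        raise DegenerateChainError(
            f"stationary distribution is not unique: {len(closed)} closed "
            f"communicating classes {members}"
        )
    A = np.vstack([T.T - np.eye(n), np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def ers_set(space: StrategySpace, p: GameParams, rho: np.ndarray | None = None) -> set[Strategy]:
    """Strategies into which every single mutant fixes with probability < 1/Z.

    The inequality is strict: a neutral mutant (``rho`` equal to 1/Z up to
    the rounding band) denies robustness, so no strategy is robust at
    gamma = 0.
    """
    if rho is None:
        rho = fixation_matrix(space, p)
    neutral = 1.0 / p.Z
    out = set()
    for i, s in enumerate(space):
        row = np.delete(rho[i], i)
        if np.all(row < neutral * (1.0 - _NEUTRAL_RTOL)):
            out.add(s)
    return out


def stability_variants(
    space: StrategySpace,
    p: GameParams,
    criterion: str,
    rho: np.ndarray | None = None,
) -> set[Strategy]:
    """Robust strategies under one of three stability notions.

    ``"ers"``
        Every mutant fixes with probability strictly below 1/Z.
    ``"ers_plus_fitness"``
        ERS plus the classical finite-population stability condition that
        a single mutant of any other strategy has lower fitness than the
        residents; always a subset of the ERS set.
    ``"counter_invasion"``
        Every mutant that invades above neutrality (rho_{A,B} > 1/Z) is
        counter-invaded with a larger probability (rho_{B,A} > rho_{A,B}).
    """
    if criterion not in STABILITY_CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; expected one of {STABILITY_CRITERIA}")
    if rho is None:
        rho = fixation_matrix(space, p)
    neutral = 1.0 / p.Z
    if criterion == "ers":
        return ers_set(space, p, rho)
    if criterion == "ers_plus_fitness":
        from .payoffs import bimorphic_fitness

        robust = ers_set(space, p, rho)
        out = set()
        for a in robust:
            ok = True
            for b in space:
                if b == a:
                    continue
                prof = bimorphic_fitness(b, a, 1, p)  # one B mutant among As
                if not prof.omega_U < prof.omega_V:
                    ok = False
                    break
            if ok:
                out.add(a)
        return out
    # counter_invasion
    out = set()
    for i, a in enumerate(space):
        ok = True
        for j, b in enumerate(space):
            if i == j:
                continue
            if rho[i, j] > neutral * (1.0 + _NEUTRAL_RTOL) and not rho[j, i] > rho[i, j]:
                ok = False
                break
        if ok:
            out.add(a)
    return out


@dataclass(frozen=True)
class InvasionGraph:
    """Directed graph of selection-favored transitions between strategies.

    An edge V -> U means a single U mutant fixes in a V population with
    probability above the neutral threshold 1/Z.  Sink nodes (no outgoing
    edge under the strict > test) host no advantageous mutant.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, float], ...]  # (from, to, rho)
    neutral_threshold: float

    def successors(self, label: str) -> set[str]:
        return {v for u, v, _ in self.edges if u == label}

    def sinks(self) -> set[str]:
        has_out = {u for u, _, _ in self.edges}
        return {n for n in self.nodes if n not in has_out}

    def has_edge(self, u: str, v: str) -> bool:
        return any(a == u and b == v for a, b, _ in self.edges)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(neutral_threshold=self.neutral_threshold)
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges, weight="rho")
        return g

    def to_dot(self) -> str:
        lines = ["digraph invasion {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for u, v, r in self.edges:
            lines.append(f'  "{u}" -> "{v}" [label="{r:.4g}"];')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"from": u, "to": v, "rho": r, "neutral_threshold": self.neutral_threshold}
                for u, v, r in self.edges
            ],
            columns=["from", "to", "rho", "neutral_threshold"],
        )


def invasion_graph(
    space: StrategySpace, p: GameParams, rho: np.ndarray | None = None
) -> InvasionGraph:
    """Build the invasion graph: edges where fixation beats neutral drift."""
    if rho is None:
        rho = fixation_matrix(space, p)
    neutral = 1.0 / p.Z
    edges = []
    for i, resident in enumerate(space):
        for j, invader in enumerate(space):
            if i != j and rho[i, j] > neutral * (1.0 + _NEUTRAL_RTOL):
                edges.append((resident.label, invader.label, float(rho[i, j])))
    return InvasionGraph(
        nodes=tuple(space.labels), edges=tuple(edges), neutral_threshold=neutral
    )


def restrict_chain(chain: EmbeddedChain, subset) -> EmbeddedChain:
    """Embedded chain over a strategy subset, reusing the pairwise rho values.

    The per-mutant factor is renormalized to ``eta = 1/(|subset| - 1)``.
    ``subset`` may hold labels or :class:`Strategy` objects; order follows
    the parent space.
    """
    wanted = set()
    for s in subset:
        g = parse_label(s) if isinstance(s, str) else s
        if g not in chain.space:
            raise ValueError(f"strategy {g.label} not in the chain's space")
        wanted.add(g)
    if len(wanted) < 2:
        raise ValueError("subset must contain at least 2 strategies")
    idx = [i for i, g in enumerate(chain.space) if g in wanted]
    sub_space = StrategySpace(
        members=tuple(chain.space[i] for i in idx), reduced=chain.space.reduced
    )
    sub_rho = chain.rho[np.ix_(idx, idx)]
    return _assemble(sub_space, chain.params, sub_rho)
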
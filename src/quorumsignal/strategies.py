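"""Strategy genotypes for the quorum-signaling game.

A strategy is a 4-bit genotype ``(sigma_alpha sigma_beta | A0 A1)``: the
signal (0 or 1) emitted under each state of Nature (alpha/beta), and the
action taken (1 = cooperate, 0 = shirk) under each possible majority group
signal.  Emitting signal 1 is costly; signal 0 is free (the "no signal"
convention).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterator

__all__ = ["Strategy", "StrategySpace", "enumerate_strategies", "parse_label", "signal_flip"]

_LABEL_RE = re.compile(r"^\(([01])([01])\|([01])([01])\)$")


@dataclass(frozen=True, order=True)
class Strategy:
    """One quorum-sensing genotype.

    Parameters
    ----------
    sigma_alpha, sigma_beta : int
        Signal (0 or 1) emitted when Nature chooses state alpha / beta.
    a0, a1 : int
        Action (1 = cooperate, 0 = shirk) when the majority group signal
        is 0 / 1.
    """

    sigma_alpha: int
    sigma_beta: int
    a0: int
    a1: int

    def __post_init__(self) -> None:
        for name in ("sigma_alpha", "sigma_beta", "a0", "a1"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1, got {v!r}")

    @property
    def label(self) -> str:
        """Canonical string form, e.g. ``(10|01)``."""
        return f"({self.sigma_alpha}{self.sigma_beta}|{self.a0}{self.a1})"

    def signal(self, state: str) -> int:
        """Signal emitted under state ``"alpha"`` or ``"beta"``."""
        if state == "alpha":
            return self.sigma_alpha
        if state == "beta":
            return self.sigma_beta
        raise ValueError(f"state must be 'alpha' or 'beta', got {state!r}")

    def action(self, majority_signal: int) -> int:
        """Action taken given the majority group signal (0 or 1)."""
        return self.a1 if majority_signal == 1 else self.a0

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_label(label: str) -> Strategy:
    """Parse a canonical strategy label like ``"(10|01)"``.

    Raises
    ------
    ValueError
        If the label is not of the form ``(dd|dd)`` with binary digits.
    """
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise ValueError(f"malformed strategy label: {label!r} (expected '(dd|dd)' with d in 0/1)")
    sa, sb, a0, a1 = (int(g) for g in m.groups())
    return Strategy(sa, sb, a0, a1)


def signal_flip(g: Strategy) -> Strategy:
    """Relabel the two signals: flip both emitted signals and swap the actions.

    This is the symmetry that maps the costly-signal system (10|01) onto
    the "secret handshake" system (01|10).  It is an involution, and when
    signaling is free (c_S = 0) it leaves all payoffs unchanged.
    """
    return Strategy(1 - g.sigma_alpha, 1 - g.sigma_beta, g.a1, g.a0)


@dataclass(frozen=True)
class StrategySpace:
    """An ordered collection of strategies (the state space of the chain)."""

    members: tuple[Strategy, ...]
    reduced: bool = False
    _index: dict[Strategy, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError("strategy space contains duplicates")
        object.__setattr__(self, "_index", {g: i for i, g in enumerate(self.members)})

    @property
    def n_S(self) -> int:
        return len(self.members)

    @property
    def labels(self) -> list[str]:
        return [g.label for g in self.members]

    def index(self, g: Strategy | str) -> int:
        if isinstance(g, str):
            g = parse_label(g)
        return self._index[g]

    def __iter__(self) -> Iterator[Strategy]:
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, g: object) -> bool:
        return g in self._index

    def __getitem__(self, i: int) -> Strategy:
        return self.members[i]


def enumerate_strategies(reduced: bool = False) -> StrategySpace:
    """Enumerate the strategy space in lexicographic order.

    The full space has all 2^4 = 16 genotypes.  The reduced space keeps
    only genotypes that always shirk in the absence of signals (A0 = 0),
    i.e. populations constrained to achieve quorum solely in the presence
    of the costly signal: 8 genotypes.
    """
    members = tuple(
        Strategy(sa, sb, a0, a1)
        for sa, sb, a0, a1 in itertools.product((0, 1), repeat=4)
        if not (reduced and a0 != 0)
    )
    return StrategySpace(members=members, reduced=reduced)
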
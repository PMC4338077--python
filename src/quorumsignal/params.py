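"""Model parameters for the N-person threshold public goods game with signaling."""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Any, Mapping

__all__ = ["GameParams", "DEFECTOR", "LONER"]

DEFECTOR = "defector"
LONER = "loner"

# keys accepted in config mappings; "lambda" is the external spelling of lam
_CONFIG_KEYS = {
    "Z": "Z", "N": "N", "M": "M", "c": "c", "c_S": "c_S", "cs": "c_S",
    "F": "F", "lambda": "lam", "lam": "lam", "gamma": "gamma",
    "shirker_role": "shirker_role",
}


@dataclass(frozen=True)
class GameParams:
    """Parameters of the quorum-signaling collective-action game.

    Attributes
    ----------
    Z : int
        Population size (>= 2).
    N : int
        Group size, 2 <= N <= Z.
    M : int
        Coordination threshold: at least M cooperators in a group are
        required to produce any benefit (1 <= M <= N).
    c : float
        Cost of cooperating (> 0).
    c_S : float
        Cost of emitting signal 1 (>= 0); signal 0 is free.
    F : float
        Enhancement factor of the public good (>= 0); each cooperator adds
        F*c/N to every beneficiary's payoff once the quorum is met.
    lam : float
        Probability that Nature chooses state alpha (the state in which
        collective action produces a benefit); in [0, 1].
    gamma : float
        Intensity of selection in the pairwise-comparison (Fermi) update
        (>= 0; 0 is neutral drift).
    shirker_role : str
        "defector" (shirkers share the benefit) or "loner" (shirkers
        neither pay nor benefit).
    """

    Z: int = 100
    N: int = 9
    M: int = 5
    c: float = 0.5
    c_S: float = 0.2
    F: float = 10.0
    lam: float = 0.5
    gamma: float = 5.0
    shirker_role: str = DEFECTOR

    def __post_init__(self) -> None:
        if not (isinstance(self.Z, int) and self.Z >= 2):
            raise ValueError(f"Z must be an integer >= 2, got {self.Z!r}")
        if not (isinstance(self.N, int) and 2 <= self.N <= self.Z):
            raise ValueError(f"N must satisfy 2 <= N <= Z, got N={self.N!r}, Z={self.Z}")
        if not (isinstance(self.M, int) and 1 <= self.M <= self.N):
            raise ValueError(f"M must satisfy 1 <= M <= N, got M={self.M!r}, N={self.N}")
        if not self.c > 0:
            raise ValueError(f"c must be positive, got {self.c!r}")
        if self.c_S < 0:
            raise ValueError(f"c_S must be non-negative, got {self.c_S!r}")
        if self.F < 0:
            raise ValueError(f"F must be non-negative, got {self.F!r}")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lam must lie in [0, 1], got {self.lam!r}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be non-negative, got {self.gamma!r}")
        if self.shirker_role not in (DEFECTOR, LONER):
            raise ValueError(
                f"shirker_role must be '{DEFECTOR}' or '{LONER}', got {self.shirker_role!r}"
            )

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any], **overrides: Any) -> "GameParams":
        """Build parameters from a config mapping (keys as in config files).

        ``lambda`` and ``lam`` are both accepted for the state-alpha
        probability; ``cs`` is an alias for ``c_S``.  Unknown keys raise.
        """
        kwargs: dict[str, Any] = {}
        for key, value in mapping.items():
            if key not in _CONFIG_KEYS:
                raise ValueError(f"unknown parameter key {key!r}")
            field = _CONFIG_KEYS[key]
            if field in ("Z", "N", "M"):
                value = int(value)
            elif field != "shirker_role":
                value = float(value)
            kwargs[field] = value
        kwargs.update(overrides)
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        """Serializable form, with the external key ``lambda``."""
        d = asdict(self)
        d["lambda"] = d.pop("lam")
        return d

    def replace(self, **changes: Any) -> "GameParams":
        return replace(self, **changes)
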
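"""Parameter sweeps over the embedded-chain analysis.

A sweep evaluates one or two parameter axes on a grid, building a fresh
embedded chain at every grid point, and reports requested observables in
a tidy long-format table.  Supported observables:

``prevalence_of:<label>``
    Stationary mass of one strategy, e.g. ``prevalence_of:(10|01)``.
``ers_flag:<label>``
    1.0 if the strategy is evolutionarily robust at that point, else 0.0.
``signaling_prevalence``
    Combined stationary mass of the two signaling systems (10|01) and
    (01|10).
``stationary_full``
    One row per strategy with its stationary mass.

Grid points whose parameters are invalid (e.g. M > N) produce rows with
an ``error`` entry and the sweep continues.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import pandas as pd

from .chain import build_chain, ers_set, stationary_distribution
from .params import GameParams, _CONFIG_KEYS
from .strategies import enumerate_strategies, parse_label

__all__ = ["SweepSpec", "run_sweep"]

SIGNALING_LABELS = ("(10|01)", "(01|10)")


@dataclass(frozen=True)
class SweepSpec:
    """Specification of a sweep: axes, fixed parameters, observables."""

    axes: dict[str, tuple]            # parameter name -> value grid (1 or 2 axes)
    fixed: GameParams = field(default_factory=GameParams)
    outputs: tuple[str, ...] = ("signaling_prevalence",)
    reduced: bool = False

    def __post_init__(self) -> None:
        if not 1 <= len(self.axes) <= 2:
            raise ValueError("a sweep needs one or two axes")
        for name, grid in self.axes.items():
            if name not in _CONFIG_KEYS:
                raise ValueError(f"unknown sweep axis {name!r}")
            if len(grid) == 0:
                raise ValueError(f"axis {name!r} has an empty grid")
        for obs in self.outputs:
            _parse_observable(obs)  # validates

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "SweepSpec":
        axes = {str(k): tuple(v) for k, v in dict(mapping["axes"]).items()}
        fixed = GameParams.from_mapping(mapping.get("fixed", {}))
        outputs = tuple(mapping.get("outputs", ("signaling_prevalence",)))
        return cls(axes=axes, fixed=fixed, outputs=outputs,
                   reduced=bool(mapping.get("reduced", False)))


def _parse_observable(obs: str) -> tuple[str, str | None]:
    if obs in ("signaling_prevalence", "stationary_full"):
        return obs, None
    for prefix in ("prevalence_of:", "ers_flag:"):
        if obs.startswith(prefix):
            label = obs[len(prefix):].strip()
            parse_label(label)
            return prefix[:-1], label
    raise ValueError(f"unknown observable {obs!r}")


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Evaluate the sweep; one row per grid point per observable (per strategy
    for ``stationary_full``).  Deterministic and order-independent: each grid
    point is computed from a fresh embedded chain."""
    space = enumerate_strategies(reduced=spec.reduced)
    axis_names = list(spec.axes)
    rows: list[dict[str, Any]] = []
    for values in itertools.product(*(spec.axes[a] for a in axis_names)):
        point = dict(zip(axis_names, values))
        base = dict(point)
        try:
            p = GameParams.from_mapping(point, **_non_axis_fields(spec.fixed, axis_names))
        except (ValueError, TypeError) as exc:
            for obs in spec.outputs:
                rows.append({**base, "observable": obs, "strategy": None,
                             "value": float("nan"), "error": str(exc)})
            continue
        chain = build_chain(space, p)
        pi = stationary_distribution(chain)
        mass = {g.label: float(x) for g, x in zip(space, pi)}
        robust = None
        for obs in spec.outputs:
            kind, label = _parse_observable(obs)
            if kind == "signaling_prevalence":
                value = sum(mass.get(lbl, 0.0) for lbl in SIGNALING_LABELS)
                rows.append({**base, "observable": obs, "strategy": None,
                             "value": value, "error": None})
            elif kind == "prevalence_of":
                rows.append({**base, "observable": obs, "strategy": label,
                             "value": mass.get(label, 0.0), "error": None})
            elif kind == "ers_flag":
                if robust is None:
                    robust = {g.label for g in ers_set(space, p, chain.rho)}
                rows.append({**base, "observable": obs, "strategy": label,
                             "value": float(label in robust), "error": None})
            else:  # stationary_full
                for lbl in space.labels:
                    rows.append({**base, "observable": obs, "strategy": lbl,
                                 "value": mass[lbl], "error": None})
    return pd.DataFrame(rows, columns=[*axis_names, "observable", "strategy", "value", "error"])


def _non_axis_fields(fixed: GameParams, axis_names: Sequence[str]) -> dict[str, Any]:
    axis_fields = {_CONFIG_KEYS[a] for a in axis_names}
    d = {
        "Z": fixed.Z, "N": fixed.N, "M": fixed.M, "c": fixed.c, "c_S": fixed.c_S,
        "F": fixed.F, "lam": fixed.lam, "gamma": fixed.gamma,
        "shirker_role": fixed.shirker_role,
    }
    return {k: v for k, v in d.items() if k not in axis_fields}
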
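"""Hyperparameter search space for the recurrent anomaly classifier.

The optimizer works on unconstrained real vectors; this module defines the
box it searches (mixed continuous/integer bounds) and the decoding of a
position vector into concrete training parameters.  The space is a fixed
7-vector — learning rate, dropout, epochs, layer count, and one neuron-count
slot per possible recurrent layer (up to 3) — so that every swarm agent has
the same dimension even though the decoded architectures differ in depth.
Neuron slots beyond the decoded layer count are carried but ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ParameterSpec",
    "SearchSpace",
    "HyperparameterSet",
    "default_space",
    "decode",
    "clip_to_bounds",
]


@dataclass(frozen=True)
class ParameterSpec:
    """Bounds and kind of one tunable dimension."""

    name: str
    lower: float
    upper: float
    kind: str = "continuous"  # "continuous" or "integer"

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "integer"):
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        if not self.lower < self.upper:
            raise ValueError(
                f"{self.name}: lower bound {self.lower} must be < upper {self.upper}"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class SearchSpace:
    """Ordered collection of parameter specs; dimension D = len(specs)."""

    specs: tuple[ParameterSpec, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names in search space")

    @property
    def dimension(self) -> int:
        return len(self.specs)

    @property
    def lower(self) -> np.ndarray:
        return np.array([s.lower for s in self.specs], dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.array([s.upper for s in self.specs], dtype=float)

    @property
    def widths(self) -> np.ndarray:
        return self.upper - self.lower

    def spec(self, name: str) -> ParameterSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass(frozen=True)
class HyperparameterSet:
    """Decoded, concrete training parameters for one candidate network.

    learning_rate : gradient step size, in [0.0001, 0.01]
    dropout       : fraction of hidden units dropped during training, [0.05, 0.2]
    epochs        : training epoch budget, [30, 60]
    num_layers    : recurrent layer count, [1, 3]
    neurons       : hidden units per layer (len == num_layers), each in [8, 15]
    """

    learning_rate: float
    dropout: float
    epochs: int
    num_layers: int
    neurons: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.neurons) != self.num_layers:
            raise ValueError(
                f"neurons list length {len(self.neurons)} != num_layers {self.num_layers}"
            )


# Standard ranges for the heart-rate tuning task: lighter networks are
# favoured, so depth tops out at 3 and widths at the window length (15).
_DEFAULT_SPECS = (
    ParameterSpec("learning_rate", 1e-4, 1e-2, "continuous"),
    ParameterSpec("dropout", 0.05, 0.2, "continuous"),
    ParameterSpec("epochs", 30, 60, "integer"),
    ParameterSpec("num_layers", 1, 3, "integer"),
    ParameterSpec("neurons_1", 8, 15, "integer"),
    ParameterSpec("neurons_2", 8, 15, "integer"),
    ParameterSpec("neurons_3", 8, 15, "integer"),
)


def default_space(overrides: dict | None = None) -> SearchSpace:
    """The standard 7-dimensional tuning space.

    ``overrides`` maps parameter names to ``{"lower": .., "upper": ..}``
    dicts (as loaded from an experiment config file) replacing the default
    bounds of individual dimensions.
    """
    specs = []
    for s in _DEFAULT_SPECS:
        if overrides and s.name in overrides:
            o = overrides[s.name]
            s = ParameterSpec(
                s.name,
                float(o.get("lower", s.lower)),
                float(o.get("upper", s.upper)),
                o.get("kind", s.kind),
            )
        specs.append(s)
    return SearchSpace(tuple(specs))


def clip_to_bounds(position: Sequence[float], space: SearchSpace) -> np.ndarray:
    """Coerce each component into its spec's [lower, upper] box."""
    pos = np.asarray(position, dtype=float)
    if pos.shape != (space.dimension,):
        raise ValueError(
            f"position has shape {pos.shape}, expected ({space.dimension},)"
        )
    return np.clip(pos, space.lower, space.upper)


def decode(position: Sequence[float], space: SearchSpace) -> HyperparameterSet:
    """Map a real-valued position to a concrete hyperparameter set.

    Integer dimensions are rounded to the nearest whole number; only the
    first ``num_layers`` neuron slots are read.  The position is clipped to
    the box first, so decode never fails on any real vector of the right
    length.
    """
    pos = clip_to_bounds(position, space)
    values: dict[str, float] = {}
    for s, x in zip(space.specs, pos):
        values[s.name] = float(np.rint(x)) if s.kind == "integer" else float(x)
    num_layers = int(values["num_layers"])
    neurons = tuple(
        int(values[f"neurons_{i + 1}"]) for i in range(num_layers)
    )
    return HyperparameterSet(
        learning_rate=values["learning_rate"],
        dropout=values["dropout"],
        epochs=int(values["epochs"]),
        num_layers=num_layers,
        neurons=neurons,
    )
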
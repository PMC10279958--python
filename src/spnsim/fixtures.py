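"""Small reference systems with known behaviour, for tests and oracles.

``tiny_grid`` is a real 1x2 segment polarity model (66 species) that keeps
integration-based tests fast; ``toy_decay`` and ``toy_bistable`` are 1-D
systems with closed-form attractors used as independent oracles for the
dynamics and multistability machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network import build_model
from .params import default_table

__all__ = ["make_fixtures", "ToyModel"]


@dataclass
class ToyModel:
    """Minimal model protocol: ``n_species`` plus an ``rhs(t, y)``."""

    name: str
    n_species: int
    _f: callable
    species_names: list = field(default_factory=list)
    n_cells: int = 1

    def __post_init__(self):
        if not self.species_names:
            self.species_names = [f"x{i}_0_{i}" for i in range(self.n_species)]

    def rhs(self, t, y):
        return self._f(t, np.asarray(y, dtype=float))


def make_fixtures(kind: str, seed: int = 0):
    """Return (model, expectations) for one fixture kind."""
    if kind == "tiny_grid":
        model = build_model(1, 2, default_table())
        return model, {"n_species": 66, "n_parameters": 53, "n_sampled": 48}
    if kind == "toy_decay":
        model = ToyModel("toy_decay", 1, lambda t, y: -y)
        return model, {
            "solution": lambda t, x0=1.0: x0 * math.exp(-t),
            "half_life": math.log(2.0),
            "attractors": [np.array([0.0])],
        }
    if kind == "toy_bistable":
        model = ToyModel(
            "toy_bistable", 1, lambda t, y: y * (1.0 - y) * (y - 0.3)
        )
        return model, {
            "attractors": [np.array([0.0]), np.array([1.0])],
            "separatrix": 0.3,
            "basin_examples": {0.1: 0.0, 0.9: 1.0},
        }
    if kind == "toy_oscillator":
        def f(t, y):
            return np.array([-y[1], y[0]])

        model = ToyModel("toy_oscillator", 2, f)
        return model, {"converges": False}
    raise ValueError(f"unknown fixture kind {kind!r}")
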
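"""Parameter registry for the segment polarity network model.

The model has exactly 53 named global parameters shared across cells, of
which 48 are sampled in the robustness screen and 5 are fixed.  The sampled
set comprises:

* 13 half-lives ``H_*`` (one per dynamic species class), range [5, 100] time
  units;
* 11 regulator pairs ``kappa_*`` / ``nu_*`` (half-saturation constants in
  [1e-3, 1] normalized units, cooperativity exponents in [1, 10]);
* the wg-promoter weights ``alpha_CIwg`` and ``alpha_WGwg``, the maximum CI
  cleavage rate ``C_CI``, the PTC-HH association rate ``k_PTCHH``, the WG
  exocytosis/endocytosis rates ``r_ExoWG``/``r_EndoWG``, the cross-cell WG
  membrane exchange rate ``r_MxferWG``, the four lateral (side-to-side)
  membrane diffusion rates ``r_LMxfer{WG,PTC,HH,PH}``, all in [1e-3, 1e3] per
  time unit;
* the concentration scale factors ``PTC_0`` and ``HH_0``, range [1, 1000].

All sampling is log-uniform.  The 5 fixed parameters are the basal ci inducer
``B_ci`` (=1), the shared maximum transcription and translation scales
``V_max`` and ``P_trans`` (=1; transcription and translation velocities are
normalized so steady levels stay in [0, 1]), and the cross-cell membrane
exchange rates ``r_MxferPTC`` and ``r_MxferHH`` (=0: unlike secreted
Wingless, Patched and membrane-tethered Hedgehog do not hop between cells).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = ["Parameter", "ParameterTable", "default_table", "N_PARAMS", "N_SAMPLED"]

N_PARAMS = 53
N_SAMPLED = 48


@dataclass
class Parameter:
    name: str
    value: float
    range_lo: float | None = None
    range_hi: float | None = None
    scale: str = "log"
    sampled: bool = False
    category: str = "rate"

    def __post_init__(self):
        if self.sampled:
            if self.range_lo is None or self.range_hi is None:
                raise ValueError(f"sampled parameter {self.name} needs a range")
            if not (0 < self.range_lo < self.range_hi):
                raise ValueError(
                    f"invalid range [{self.range_lo}, {self.range_hi}] for {self.name}"
                )
            if not (self.range_lo <= self.value <= self.range_hi):
                raise ValueError(
                    f"default value {self.value} of {self.name} outside its range"
                )


class ParameterTable:
    """Ordered registry of named parameters with sampling metadata.

    The row order defines the parameter-vector layout used by the compiled
    right-hand side and by every CSV/JSON export.
    """

    def __init__(self, rows: list[Parameter]):
        names = [r.name for r in rows]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")
        self.rows = list(rows)
        self.index = {r.name: i for i, r in enumerate(self.rows)}

    def __len__(self) -> int:
        return len(self.rows)

    def __contains__(self, name: str) -> bool:
        return name in self.index

    def __getitem__(self, name: str) -> Parameter:
        return self.rows[self.index[name]]

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rows]

    @property
    def sampled_names(self) -> list[str]:
        return [r.name for r in self.rows if r.sampled]

    @property
    def n_sampled(self) -> int:
        return sum(r.sampled for r in self.rows)

    def values(self) -> np.ndarray:
        """Default parameter vector in registry order."""
        return np.array([r.value for r in self.rows], dtype=float)

    def vector_from_sampled(self, sampled_values: np.ndarray) -> np.ndarray:
        """Full 53-vector from a 48-vector of sampled values (fixed rows kept)."""
        sampled_values = np.asarray(sampled_values, dtype=float)
        if sampled_values.shape != (self.n_sampled,):
            raise ValueError(
                f"expected {self.n_sampled} sampled values, got {sampled_values.shape}"
            )
        vec = self.values()
        j = 0
        for i, row in enumerate(self.rows):
            if row.sampled:
                vec[i] = sampled_values[j]
                j += 1
        return vec

    def sampled_from_vector(self, vector: np.ndarray) -> np.ndarray:
        vector = np.asarray(vector, dtype=float)
        return vector[[i for i, r in enumerate(self.rows) if r.sampled]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.rows])

    # -- configuration round-trip ------------------------------------------------
    def to_config(self) -> dict:
        return {"parameters": [asdict(r) for r in self.rows]}

    @classmethod
    def from_config(cls, cfg: dict) -> "ParameterTable":
        try:
            rows = [Parameter(**row) for row in cfg["parameters"]]
        except (KeyError, TypeError) as exc:
            raise ValueError(f"malformed parameter configuration: {exc}") from exc
        return cls(rows)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_config(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ParameterTable":
        with open(path) as fh:
            return cls.from_config(json.load(fh))


def _geomid(lo: float, hi: float) -> float:
    return math.sqrt(lo * hi)


#: regulator pairs in registry order: (target gene <- regulator) edges
REGULATOR_PAIRS = [
    "WGen",   # en induction by neighbour-membrane Wingless (EWG_T)
    "CNen",   # en repression by CN
    "CIwg",   # wg induction by full-length CI
    "CNwg",   # wg repression by CN
    "WGwg",   # wg auto-activation by intracellular Wingless
    "CIptc",  # ptc induction by CI
    "CNptc",  # ptc repression by CN
    "ENci",   # ci repression by Engrailed
    "PTCCI",  # CI cleavage promotion by free Patched (PTC_T)
    "ENhh",   # hh induction by Engrailed
    "CNhh",   # hh repression by CN
]

HALF_LIFE_NAMES = [
    "H_en", "H_EN", "H_wg", "H_IWG", "H_EWG", "H_ptc", "H_PTC",
    "H_ci", "H_CI", "H_CN", "H_hh", "H_HH", "H_PH",
]

RATE_NAMES = [
    "alpha_CIwg", "alpha_WGwg", "C_CI", "k_PTCHH",
    "r_ExoWG", "r_EndoWG", "r_MxferWG",
    "r_LMxferWG", "r_LMxferPTC", "r_LMxferHH", "r_LMxferPH",
]


def default_table() -> ParameterTable:
    """The default 53-parameter registry (48 sampled, 5 fixed).

    Default values sit at the geometric midpoint of each sampling range.
    """
    rows: list[Parameter] = []
    for name in HALF_LIFE_NAMES:
        rows.append(Parameter(name, _geomid(5, 100), 5, 100, "log", True, "half_life"))
    for pair in REGULATOR_PAIRS:
        rows.append(Parameter(f"kappa_{pair}", _geomid(1e-3, 1), 1e-3, 1, "log", True, "kappa"))
        rows.append(Parameter(f"nu_{pair}", _geomid(1, 10), 1, 10, "log", True, "nu"))
    for name in RATE_NAMES:
        rows.append(Parameter(name, _geomid(1e-3, 1e3), 1e-3, 1e3, "log", True, "rate"))
    rows.append(Parameter("PTC_0", _geomid(1, 1000), 1, 1000, "log", True, "scale_factor"))
    rows.append(Parameter("HH_0", _geomid(1, 1000), 1, 1000, "log", True, "scale_factor"))
    # fixed
    rows.append(Parameter("B_ci", 1.0, sampled=False, category="rate"))
    rows.append(Parameter("V_max", 1.0, sampled=False, category="rate"))
    rows.append(Parameter("P_trans", 1.0, sampled=False, category="rate"))
    rows.append(Parameter("r_MxferPTC", 0.0, sampled=False, category="rate"))
    rows.append(Parameter("r_MxferHH", 0.0, sampled=False, category="rate"))
    table = ParameterTable(rows)
    assert len(table) == N_PARAMS and table.n_sampled == N_SAMPLED
    return table
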
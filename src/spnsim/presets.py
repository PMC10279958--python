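"""Initial-condition presets and the target stripe pattern.

The wild-type segment polarity pattern on the four-cell parasegment repeat
(cells numbered 1..4, parasegment boundary between cells 2 and 3) is:
wingless on in cell 2, engrailed and hedgehog on in cell 3, patched on in
cells 2 and 4 (the cells flanking the hedgehog source).

Preset starting patterns mirror the published screen conditions.  Their
verbal range classes are mapped to fixed values: "<20%" -> 0.15,
"20%-60%" -> 0.4, "60%-100%" -> 0.9.  A preset assigns the class value to
the named gene's mRNA and to its cognate proteins in the same cell
(membrane pools split evenly over the six sides); every other species
starts at the low class value.  CN starts low and PH starts low/6
everywhere.  The exact vectors used by the original screen were published
only in deposited model files; these reconstructions are documented in
docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel as K
from .network import SPECIES_PER_CELL

__all__ = ["PatternTarget", "ICPreset", "PRESETS", "default_target", "LOW", "MID", "HIGH"]

LOW, MID, HIGH = 0.15, 0.4, 0.9

GENES = ("en", "wg", "ptc", "ci", "hh")
#: protein species fed by each gene: (cytosolic offsets, membrane block offsets)
_GENE_PRODUCTS = {
    "en": ([K.S_EN], []),
    "wg": ([K.S_IWG], [K.S_EWG]),
    "ptc": ([], [K.S_PTC]),
    "ci": ([K.S_CI], []),
    "hh": ([], [K.S_HH]),
}


@dataclass(frozen=True)
class PatternTarget:
    """On/off cell sets (1-based, within the 4-cell repeat) per scored mRNA."""

    on: dict
    off: dict

    def __post_init__(self):
        for gene in self.on:
            if not self.on[gene] or not self.off[gene]:
                raise ValueError(f"empty on/off set for {gene}")
            if self.on[gene] & self.off[gene]:
                raise ValueError(f"on/off sets overlap for {gene}")

    def shifted(self, k: int, n_cols: int = 4) -> "PatternTarget":
        """Target with all cell labels cyclically shifted by ``k`` columns."""

        def sh(cells):
            return {((c - 1 + k) % n_cols) + 1 for c in cells}

        return PatternTarget(
            on={g: sh(s) for g, s in self.on.items()},
            off={g: sh(s) for g, s in self.off.items()},
        )


def default_target() -> PatternTarget:
    """The scored stripe pattern.

    wg must be expressed in cell 2 only; en and hh in cell 3 only; ptc in
    both cells flanking the hedgehog source (2 and 4) and silenced in the
    engrailed cell (3).  Patched expression in cell 1 is left unconstrained:
    in the embryo ptc is repressed only in engrailed territory, and the
    anterior cell of the repeat expresses it broadly.
    """
    return PatternTarget(
        on={"wg": {2}, "ptc": {2, 4}, "en": {3}, "hh": {3}},
        off={"wg": {1, 3, 4}, "ptc": {3}, "en": {1, 2, 4}, "hh": {1, 2, 4}},
    )


@dataclass(frozen=True)
class ICPreset:
    """Named initial-condition builder over the grid.

    ``levels`` maps gene -> per-cell class values on the 4-cell repeat
    (index 0 = cell 1); unlisted genes are LOW everywhere.
    """

    name: str
    levels: dict = field(default_factory=dict)

    def level(self, gene: str, cell1: int) -> float:
        per_cell = self.levels.get(gene)
        if per_cell is None:
            return LOW
        return per_cell[(cell1 - 1) % len(per_cell)]

    def build(self, model) -> np.ndarray:
        """State vector over the model's grid (pattern tiled along columns)."""
        n_cols = model.topology.n_cols if model.topology is not None else 1
        x0 = np.empty(model.n_species)
        for c in range(model.n_cells):
            col = c % n_cols if model.topology is None else model.topology.cell_id(c)[1]
            cell1 = (col % 4) + 1
            b = c * SPECIES_PER_CELL
            block = np.full(SPECIES_PER_CELL, LOW)
            for j in range(6):  # membrane pools default LOW/6
                for off in (K.S_EWG, K.S_PTC, K.S_HH, K.S_PH):
                    block[off + j] = LOW / 6.0
            for gi, gene in enumerate(GENES):
                v = self.level(gene, cell1)
                block[gi] = v
                cyto, membr = _GENE_PRODUCTS[gene]
                for off in cyto:
                    block[off] = v
                for off in membr:
                    block[off : off + 6] = v / 6.0
            block[K.S_CN] = LOW
            x0[b : b + SPECIES_PER_CELL] = block
        return x0

    def shifted(self, k: int) -> "ICPreset":
        """Preset with the 4-cell pattern cyclically shifted by ``k`` columns."""
        return ICPreset(
            name=f"{self.name}_shift{k}",
            levels={g: tuple(np.roll(v, k)) for g, v in self.levels.items()},
        )


_BAND_412 = (HIGH, HIGH, LOW, HIGH)  # 3-cell band covering cells 4, 1, 2


PRESETS = {
    "crisp": ICPreset("crisp", {
        "wg": (LOW, HIGH, LOW, LOW),
        "en": (LOW, LOW, HIGH, LOW),
    }),
    "degraded": ICPreset("degraded", {
        "wg": (MID, HIGH, MID, LOW),
        "en": (LOW, MID, HIGH, MID),
    }),
    "crisp_ubq_ci_ptc": ICPreset("crisp_ubq_ci_ptc", {
        "wg": (LOW, HIGH, LOW, LOW),
        "en": (LOW, LOW, HIGH, LOW),
        "ci": (MID, MID, MID, MID),
        "ptc": (MID, MID, MID, MID),
    }),
    "ci_band_wg_posterior": ICPreset("ci_band_wg_posterior", {
        "ci": _BAND_412,
        "wg": (LOW, HIGH, LOW, LOW),
    }),
    "ptc_band_en_anterior": ICPreset("ptc_band_en_anterior", {
        "ptc": _BAND_412,
        "en": (LOW, LOW, HIGH, LOW),
    }),
    "ptc_band_ci_out_of_phase": ICPreset("ptc_band_ci_out_of_phase", {
        "ptc": _BAND_412,
        "ci": (LOW, HIGH, HIGH, HIGH),
    }),
    "close_to_target": ICPreset("close_to_target", {
        "wg": (LOW, HIGH, LOW, LOW),
        "en": (LOW, LOW, HIGH, LOW),
        "hh": (LOW, LOW, HIGH, LOW),
        "ptc": (LOW, HIGH, LOW, HIGH),
        "ci": (HIGH, HIGH, LOW, HIGH),
    }),
}
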
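"""Assembly of the full segment polarity network model on a cell grid.

Per cell the model tracks 33 dynamic species: the five mRNAs (en, wg, ptc,
ci, hh), four cytosolic proteins (EN, IWG = intracellular Wingless, CI, CN)
and four membrane proteins in six per-side pools each (EWG_j = membrane
Wingless, PTC_j, HH_j, PH_j = Patched-Hedgehog complex).  A 1x4 grid has 132
dynamic species.  All 53 parameters are global (shared across cells).

Regulatory wiring (transcription uses the guarded inducer-repressor law,
decay is first order with rate ln2/H):

1.  en  <- induced by EWG_T (Wingless on the six apposed neighbour
    membranes), repressed by CN.
2.  wg  <- saturating composite of CI activation gated by CN repression plus
    IWG auto-activation, weighted by alpha_CIwg / alpha_WGwg.
3.  ptc <- induced by CI, repressed by CN.
4.  ci  <- constitutive (basal inducer B_ci), repressed by EN.
5.  hh  <- induced by EN, repressed by CN.
6.  Proteins translate from their mRNA on the same half-life time scale;
    membrane proteins split translation evenly over the six sides.
7.  IWG exchanges with each EWG_j (exocytosis r_ExoWG/6 per side, endocytosis
    r_EndoWG); membrane pools diffuse to the two adjacent sides
    (r_LMxfer{WG,PTC,HH,PH}); EWG additionally exchanges with the apposed
    neighbour pool (r_MxferWG).
8.  CI is cleaved to CN at rate C_CI * CI * phi(PTC_T); free Patched binds
    apposed Hedgehog into PH with the normalized-scale fluxes
    dPTC_j = -HH_0*k*PTC_j*HH_j', dHH_j' = -PTC_0*k*PTC_j*HH_j',
    dPH_j = +HH_0*k*PTC_j*HH_j'.

Derived (non-dynamic) totals per cell: PTC_T and PH_T are within-cell pool
sums; EWG_T sums the six apposed neighbour EWG pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel as K
from .expr import Expr, Max, Num, Sym
from .hexlattice import make_grid
from .kinetics import GuardConfig, LN2
from .params import ParameterTable, default_table

__all__ = [
    "ModelSpec",
    "Reaction",
    "build_model",
    "build_single_cell",
    "compile_rhs",
    "SPECIES_PER_CELL",
    "MRNAS",
    "MEMBRANE_PROTEINS",
]

SPECIES_PER_CELL = K.N_PER_CELL
MRNAS = ("en", "wg", "ptc", "ci", "hh")
CYTO_PROTEINS = ("EN", "IWG", "CI", "CN")
MEMBRANE_PROTEINS = ("EWG", "PTC", "HH", "PH")

#: per-cell species short names in state-vector order
CELL_SPECIES = list(MRNAS) + list(CYTO_PROTEINS) + [
    f"{prot}{side}" for prot in MEMBRANE_PROTEINS for side in range(1, 7)
]

_MRNA_OFFSET = {g: i for i, g in enumerate(MRNAS)}
_MEMBRANE_OFFSET = {"EWG": K.S_EWG, "PTC": K.S_PTC, "HH": K.S_HH, "PH": K.S_PH}

#: boundary species required by the single-cell model: apposed neighbour pools
BOUNDARY_KEYS = [f"{prot}{side}" for prot in ("EWG", "PTC", "HH") for side in range(1, 7)]


@dataclass
class Reaction:
    """One elementary process: stoichiometry plus a rate-law expression."""

    rid: str
    #: list of (species id, stoichiometry); negative consumes, positive produces
    stoich: list
    rate: Expr
    #: species/total ids read by the rate law but not converted
    modifiers: list = field(default_factory=list)


class ModelSpec:
    """Assembled model: topology, registries and the compiled ODE right-hand side."""

    def __init__(self, topology, params, guard, boundary=None):
        self.topology = topology
        self.params = params
        self.guard = guard
        self.param_vector = params.values()
        self.n_cells = topology.n_cells if topology is not None else 1
        self.n_species = self.n_cells * SPECIES_PER_CELL
        #: -1 entries mark fixed-boundary sides (single-cell model)
        if topology is not None:
            self.neighbor = topology.neighbor_cell.astype(np.int64)
        else:
            self.neighbor = -np.ones((1, 6), dtype=np.int64)
        if boundary is None:
            self.b_ewg = np.zeros(6)
            self.b_ptc = np.zeros(6)
            self.b_hh = np.zeros(6)
            self.boundary = None
        else:
            missing = [k for k in BOUNDARY_KEYS if k not in boundary]
            if missing:
                raise ValueError(f"boundary map missing species: {missing}")
            self.boundary = dict(boundary)
            self.b_ewg = np.array([boundary[f"EWG{j}"] for j in range(1, 7)], float)
            self.b_ptc = np.array([boundary[f"PTC{j}"] for j in range(1, 7)], float)
            self.b_hh = np.array([boundary[f"HH{j}"] for j in range(1, 7)], float)
        self.species_names = self._species_names()
        self._species_index = {n: i for i, n in enumerate(self.species_names)}
        self.totals = _build_totals(self)
        self.reactions = _build_reactions(self)

    # -- naming -----------------------------------------------------------------
    def _cell_label(self, c: int) -> str:
        if self.topology is None:
            return "0_0"
        r, col = self.topology.cell_id(c)
        return f"{r}_{col}"

    def _species_names(self) -> list:
        out = []
        for c in range(self.n_cells):
            lab = self._cell_label(c)
            out.extend(f"{s}_{lab}" for s in CELL_SPECIES)
        return out

    def species_index(self, name: str) -> int:
        """Flat state index of a cell-qualified species id like ``EWG5_0_1``."""
        try:
            return self._species_index[name]
        except KeyError:
            raise KeyError(f"unknown species {name!r}") from None

    def mrna_index(self, gene: str, cell: int) -> int:
        return cell * SPECIES_PER_CELL + _MRNA_OFFSET[gene]

    # -- evaluation ---------------------------------------------------------------
    def rhs_for(self, param_vector: np.ndarray):
        """Compiled RHS ``f(t, y)`` for an arbitrary full parameter vector."""
        p = np.ascontiguousarray(param_vector, dtype=float)
        if p.shape != (len(self.params),):
            raise ValueError(f"parameter vector must have length {len(self.params)}")
        neigh = self.neighbor
        b_ewg, b_ptc, b_hh = self.b_ewg, self.b_ptc, self.b_hh
        guard = bool(self.guard.enabled)
        eps = float(self.guard.epsilon)
        n = self.n_species
        kernel = K.rhs_kernel

        def rhs(t, y):
            y = np.asarray(y, dtype=float)
            if y.shape != (n,):
                raise ValueError(f"state vector must have length {n}")
            dy = np.empty(n)
            kernel(y, dy, p, neigh, b_ewg, b_ptc, b_hh, guard, eps)
            return dy

        return rhs

    def odeint_pair(self, param_vector: np.ndarray):
        """Low-overhead ``(f(y, t), jac(y, t), bad_flag)`` triple for odeint.

        ``f`` reuses one output buffer and records non-finite derivative
        counts in ``bad_flag[0]`` instead of raising; ``jac`` is the analytic
        Jacobian.  Intended for the inner loops of screens and censuses.
        """
        p = np.ascontiguousarray(param_vector, dtype=float)
        if p.shape != (len(self.params),):
            raise ValueError(f"parameter vector must have length {len(self.params)}")
        neigh = self.neighbor
        b_ewg, b_ptc, b_hh = self.b_ewg, self.b_ptc, self.b_hh
        guard = bool(self.guard.enabled)
        eps = float(self.guard.epsilon)
        n = self.n_species
        dy = np.empty(n)
        J = np.empty((n, n))
        bad_flag = np.zeros(1, dtype=np.int64)
        kernel, jkernel = K.rhs_kernel, K.jac_kernel

        def f(y, t):
            bad = kernel(y, dy, p, neigh, b_ewg, b_ptc, b_hh, guard, eps)
            if bad:
                bad_flag[0] += bad
                raise FloatingPointError("non-finite derivative")
            return dy

        def jac(y, t):
            jkernel(y, J, p, neigh, b_ewg, b_ptc, b_hh, guard, eps)
            return J

        return f, jac, bad_flag

    def rhs(self, t, y):
        """RHS at the table's default parameter values."""
        return self.rhs_for(self.param_vector)(t, y)

    def eval_totals(self, y: np.ndarray) -> dict:
        """Derived per-cell totals EWG_T, PTC_T, PH_T at state ``y``."""
        env = {n: y[i] for i, n in enumerate(self.species_names)}
        return {name: expr.ev(env) for name, expr in self.totals.items()}

    def rhs_from_reactions(self, y: np.ndarray) -> np.ndarray:
        """Reference RHS computed by summing the reaction registry.

        Slow path; exists as an independent cross-check of the compiled
        kernel and as the semantic ground truth for SBML export.
        """
        y = np.asarray(y, dtype=float)
        env = {r.name: float(v) for r, v in zip(self.params.rows, self.param_vector)}
        env.update({n: y[i] for i, n in enumerate(self.species_names)})
        for name, expr in self.totals.items():
            env[name] = expr.ev(env)
        dy = np.zeros(self.n_species)
        for rxn in self.reactions:
            v = rxn.rate.ev(env)
            for sid, st in rxn.stoich:
                dy[self._species_index[sid]] += st * v
        return dy

    def summary(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "n_species": self.n_species,
            "n_parameters": len(self.params),
            "n_sampled": self.params.n_sampled,
            "n_reactions": len(self.reactions),
            "guard": {"enabled": self.guard.enabled, "epsilon": self.guard.epsilon},
        }


# -- rate-law expression builders -------------------------------------------------

def _g(model: ModelSpec, x: Expr) -> Expr:
    """Guard a state-dependent base: max(eps, x)."""
    if model.guard.enabled:
        return Max(Num(model.guard.epsilon), x)
    return x


def _phi(model, x: Expr, kappa: str, nu: str) -> Expr:
    xk = _g(model, x) ** Sym(nu)
    return xk / (Sym(kappa) ** Sym(nu) + xk)


def _psi(model, x: Expr, kappa: str, nu: str) -> Expr:
    return _g(model, 1.0 - _phi(model, x, kappa, nu))


def _tir(model, ind: Expr, rep: Expr, pair_i: str, pair_r: str) -> Expr:
    ibar = _g(model, ind * _psi(model, rep, f"kappa_{pair_r}", f"nu_{pair_r}"))
    num = ibar ** Sym(f"nu_{pair_i}")
    return num / (Sym(f"kappa_{pair_i}") ** Sym(f"nu_{pair_i}") + num)


def _build_totals(model: ModelSpec) -> dict:
    totals = {}
    for c in range(model.n_cells):
        lab = model._cell_label(c)
        ptc_sum: Expr = Sym(f"PTC1_{lab}")
        ph_sum: Expr = Sym(f"PH1_{lab}")
        for j in range(2, 7):
            ptc_sum = ptc_sum + Sym(f"PTC{j}_{lab}")
            ph_sum = ph_sum + Sym(f"PH{j}_{lab}")
        ewg_t: Expr | None = None
        for j in range(6):
            nb = int(model.neighbor[c, j])
            js = (j + 3) % 6
            if nb >= 0:
                term: Expr = Sym(f"EWG{js + 1}_{model._cell_label(nb)}")
            else:
                term = Num(float(model.b_ewg[j]))
            ewg_t = term if ewg_t is None else ewg_t + term
        totals[f"PTC_T_{lab}"] = ptc_sum
        totals[f"PH_T_{lab}"] = ph_sum
        totals[f"EWG_T_{lab}"] = ewg_t
    return totals


def _neighbor_pool(model, c: int, j: int, prot: str):
    """(expression, modifier id or None) for the pool apposed to (cell c, side j)."""
    nb = int(model.neighbor[c, j])
    js = (j + 3) % 6
    if nb >= 0:
        sid = f"{prot}{js + 1}_{model._cell_label(nb)}"
        return Sym(sid), sid
    b = {"EWG": model.b_ewg, "PTC": model.b_ptc, "HH": model.b_hh}[prot]
    return Num(float(b[j])), None


def _build_reactions(model: ModelSpec) -> list:
    rxns: list[Reaction] = []
    add = rxns.append

    for c in range(model.n_cells):
        lab = model._cell_label(c)

        def S(name):
            return f"{name}_{lab}"

        en, wg, ptc, ci, hh = (Sym(S(g)) for g in MRNAS)
        EN, IWG, CI, CN = (Sym(S(pn)) for pn in CYTO_PROTEINS)
        ewg_T, ptc_T = Sym(f"EWG_T_{lab}"), Sym(f"PTC_T_{lab}")

        # transcription + mRNA decay; V_X = V_max * ln2/H_X
        tx = {
            "en": _tir(model, ewg_T, CN, "WGen", "CNen"),
            "ptc": _tir(model, CI, CN, "CIptc", "CNptc"),
            "hh": _tir(model, EN, CN, "ENhh", "CNhh"),
            "ci": Sym("B_ci") * _psi(model, EN, "kappa_ENci", "nu_ENci"),
        }
        w_ci = Sym("alpha_CIwg") * _phi(model, CI, "kappa_CIwg", "nu_CIwg") \
            * _psi(model, CN, "kappa_CNwg", "nu_CNwg")
        w_wg = Sym("alpha_WGwg") * _phi(model, IWG, "kappa_WGwg", "nu_WGwg")
        tx["wg"] = (w_ci + w_wg) / (1.0 + w_ci + w_wg)
        tx_mod = {
            "en": [f"EWG_T_{lab}", S("CN")],
            "wg": [S("CI"), S("CN"), S("IWG")],
            "ptc": [S("CI"), S("CN")],
            "ci": [S("EN")],
            "hh": [S("EN"), S("CN")],
        }
        h_mrna = {"en": "H_en", "wg": "H_wg", "ptc": "H_ptc", "ci": "H_ci", "hh": "H_hh"}
        for gene in MRNAS:
            rate = Num(LN2) / Sym(h_mrna[gene]) * Sym("V_max") * tx[gene]
            add(Reaction(f"tx_{gene}_{lab}", [(S(gene), +1)], rate, tx_mod[gene]))
            add(Reaction(
                f"deg_{gene}_{lab}", [(S(gene), -1)],
                Num(LN2) / Sym(h_mrna[gene]) * Sym(S(gene)),
            ))

        # translation + decay of cytosolic proteins
        for prot, mrna, H in (("EN", "en", "H_EN"), ("IWG", "wg", "H_IWG"),
                              ("CI", "ci", "H_CI")):
            add(Reaction(
                f"tl_{prot}_{lab}", [(S(prot), +1)],
                Num(LN2) / Sym(H) * Sym("P_trans") * Sym(S(mrna)), [S(mrna)],
            ))
            add(Reaction(f"deg_{prot}_{lab}", [(S(prot), -1)],
                         Num(LN2) / Sym(H) * Sym(S(prot))))
        # CI cleavage to CN, promoted by free Patched
        add(Reaction(
            f"cleave_CI_{lab}", [(S("CI"), -1), (S("CN"), +1)],
            Sym("C_CI") * CI * _phi(model, ptc_T, "kappa_PTCCI", "nu_PTCCI"),
            [f"PTC_T_{lab}"],
        ))
        add(Reaction(f"deg_CN_{lab}", [(S("CN"), -1)],
                     Num(LN2) / Sym("H_CN") * CN))

        for j in range(1, 7):
            # WG membrane exchange
            add(Reaction(
                f"exo_WG{j}_{lab}", [(S("IWG"), -1), (S(f"EWG{j}"), +1)],
                Sym("r_ExoWG") / 6.0 * IWG,
            ))
            add(Reaction(
                f"endo_WG{j}_{lab}", [(S(f"EWG{j}"), -1), (S("IWG"), +1)],
                Sym("r_EndoWG") * Sym(S(f"EWG{j}")),
            ))
            # membrane translation (even split over sides) and decay
            add(Reaction(
                f"tl_PTC{j}_{lab}", [(S(f"PTC{j}"), +1)],
                Num(LN2) / Sym("H_PTC") * Sym("P_trans") * ptc / 6.0, [S("ptc")],
            ))
            add(Reaction(
                f"tl_HH{j}_{lab}", [(S(f"HH{j}"), +1)],
                Num(LN2) / Sym("H_HH") * Sym("P_trans") * hh / 6.0, [S("hh")],
            ))
            for prot, H in (("EWG", "H_EWG"), ("PTC", "H_PTC"),
                            ("HH", "H_HH"), ("PH", "H_PH")):
                add(Reaction(
                    f"deg_{prot}{j}_{lab}", [(S(f"{prot}{j}"), -1)],
                    Num(LN2) / Sym(H) * Sym(S(f"{prot}{j}")),
                ))
            # lateral (side-to-side) diffusion, one reversible reaction per edge
            jn = (j % 6) + 1
            for prot, r in (("EWG", "r_LMxferWG"), ("PTC", "r_LMxferPTC"),
                            ("HH", "r_LMxferHH"), ("PH", "r_LMxferPH")):
                add(Reaction(
                    f"lat_{prot}{j}_{jn}_{lab}",
                    [(S(f"{prot}{j}"), -1), (S(f"{prot}{jn}"), +1)],
                    Sym(r) * (Sym(S(f"{prot}{j}")) - Sym(S(f"{prot}{jn}"))),
                ))

        for j0 in range(6):
            j = j0 + 1
            # PTC + apposed HH -> PH; unequal normalized-scale fluxes are
            # encoded as paired reactions sharing the bimolecular law
            hh_nb, hh_mod = _neighbor_pool(model, c, j0, "HH")
            ptc_nb, ptc_mod = _neighbor_pool(model, c, j0, "PTC")
            add(Reaction(
                f"bind_PH{j}_{lab}",
                [(S(f"PTC{j}"), -1), (S(f"PH{j}"), +1)],
                Sym("HH_0") * Sym("k_PTCHH") * Sym(S(f"PTC{j}")) * hh_nb,
                [hh_mod] if hh_mod else [],
            ))
            add(Reaction(
                f"loss_HH{j}_{lab}",
                [(S(f"HH{j}"), -1)],
                Sym("PTC_0") * Sym("k_PTCHH") * ptc_nb * Sym(S(f"HH{j}")),
                [ptc_mod] if ptc_mod else [],
            ))
            # cross-cell membrane exchange (active for WG; PTC/HH rates are 0)
            nb = int(model.neighbor[c, j0])
            js0 = (j0 + 3) % 6
            for prot, r in (("EWG", "r_MxferWG"), ("PTC", "r_MxferPTC"),
                            ("HH", "r_MxferHH")):
                pool_nb, mod = _neighbor_pool(model, c, j0, prot)
                if nb >= 0 and (nb, js0) < (c, j0):
                    continue  # reversible pair already emitted from the other cell
                if nb >= 0:
                    stoich = [(S(f"{prot}{j}"), +1),
                              (f"{prot}{js0 + 1}_{model._cell_label(nb)}", -1)]
                else:
                    stoich = [(S(f"{prot}{j}"), +1)]
                add(Reaction(
                    f"xfer_{prot}{j}_{lab}", stoich,
                    Sym(r) * (pool_nb - Sym(S(f"{prot}{j}"))),
                ))
    return rxns


def build_model(
    n_rows: int,
    n_cols: int,
    params: ParameterTable | None = None,
    guard: GuardConfig | None = None,
) -> ModelSpec:
    """Assemble the grid model; see the module docstring for the wiring."""
    params = params if params is not None else default_table()
    guard = guard if guard is not None else GuardConfig()
    _check_params(params)
    topo = make_grid(n_rows, n_cols)
    return ModelSpec(topo, params, guard)


def build_single_cell(
    params: ParameterTable | None = None,
    boundary_values: dict | None = None,
    guard: GuardConfig | None = None,
) -> ModelSpec:
    """Single cell with the cross-cell inputs held at fixed concentrations.

    ``boundary_values`` must provide, for every side j in 1..6, the apposed
    neighbour pools ``EWGj``, ``PTCj`` and ``HHj``.
    """
    params = params if params is not None else default_table()
    guard = guard if guard is not None else GuardConfig()
    _check_params(params)
    if boundary_values is None:
        raise ValueError("single-cell model requires a boundary_values map")
    return ModelSpec(None, params, guard, boundary=boundary_values)


def _check_params(params: ParameterTable) -> None:
    ref = default_table()
    missing = [n for n in ref.names if n not in params]
    if missing:
        raise ValueError(f"parameter table missing required parameters: {missing}")
    if params.names != ref.names:
        raise ValueError("parameter table must follow the registry order")


def compile_rhs(model: ModelSpec):
    """RHS ``f(t, y)`` at the model's default parameter values."""
    return model.rhs_for(model.param_vector)
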
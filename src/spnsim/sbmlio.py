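"""SBML Level 3 Version 1 export and import.

The exported document carries the full reaction network, not just the
differential equations: one compartment per cell, cell-qualified species ids
(``EWG5_0_1`` for the side-5 membrane Wingless pool of cell row 0, column 1),
all 53 global parameters, the derived totals (EWG_T, PTC_T, PH_T) as
assignment rules, and every reaction with its complete kinetic law in
content MathML.  The guard ``max(eps, x)`` is encoded as piecewise, since
L3V1 MathML has no ``max`` operator; an unguarded model exports plain power
terms.

The writer and reader are implemented directly on the standard library XML
tools.  Validation is structural (unique identifiers, resolvable references,
supported MathML subset); the operative correctness check is the round-trip
oracle: import(export(M)) must reproduce the right-hand side of M.
"""

from __future__ import annotations

import hashlib
import json
import math
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np

from .expr import Add, Div, Expr, Max, Mul, Num, Pow, Sub, Sym
from .kinetics import GuardConfig
from .network import ModelSpec, Reaction, build_model
from .params import Parameter, ParameterTable, default_table

__all__ = ["ExportBundle", "export_sbml", "import_sbml", "ImportedModel", "SbmlError"]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


class SbmlError(ValueError):
    pass


@dataclass
class ExportBundle:
    """Paths + contents of one export: SBML document and simulation sidecar."""

    sbml_path: str
    sidecar_path: str
    sidecar: dict
    n_species: int
    n_reactions: int


# ---------------------------------------------------------------------------
# MathML writing
# ---------------------------------------------------------------------------

def _cn(parent, value: float) -> None:
    txt = repr(float(value))
    if "e" in txt or "E" in txt:
        mant, expo = re.split("[eE]", txt)
        el = ET.SubElement(parent, f"{{{MATHML_NS}}}cn", {"type": "e-notation"})
        el.text = mant
        sep = ET.SubElement(el, f"{{{MATHML_NS}}}sep")
        sep.tail = expo
    else:
        el = ET.SubElement(parent, f"{{{MATHML_NS}}}cn")
        el.text = txt


_OPTAG = {Add: "plus", Mul: "times", Sub: "minus", Div: "divide", Pow: "power"}


def _emit(parent, expr: Expr) -> None:
    if isinstance(expr, Num):
        _cn(parent, expr.value)
    elif isinstance(expr, Sym):
        ci = ET.SubElement(parent, f"{{{MATHML_NS}}}ci")
        ci.text = expr.name
    elif isinstance(expr, Max):
        # max(a, b) with a the guard floor: piecewise(b if b >= a else a)
        pw = ET.SubElement(parent, f"{{{MATHML_NS}}}piecewise")
        piece = ET.SubElement(pw, f"{{{MATHML_NS}}}piece")
        _emit(piece, expr.b)
        cond = ET.SubElement(piece, f"{{{MATHML_NS}}}apply")
        ET.SubElement(cond, f"{{{MATHML_NS}}}geq")
        _emit(cond, expr.b)
        _emit(cond, expr.a)
        other = ET.SubElement(pw, f"{{{MATHML_NS}}}otherwise")
        _emit(other, expr.a)
    else:
        ap = ET.SubElement(parent, f"{{{MATHML_NS}}}apply")
        ET.SubElement(ap, f"{{{MATHML_NS}}}{_OPTAG[type(expr)]}")
        _emit(ap, expr.a)
        _emit(ap, expr.b)


def _math_element(expr: Expr) -> ET.Element:
    math_el = ET.Element(f"{{{MATHML_NS}}}math")
    _emit(math_el, expr)
    return math_el


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_sbml(
    model: ModelSpec,
    path: str,
    x0: np.ndarray | None = None,
    seed: int | None = None,
    t_end: float = 1100.0,
    dt_out: float = 5.0,
    atol: float = 1e-13,
    rtol: float = 1e-8,
) -> ExportBundle:
    """Write the model as SBML L3V1 plus a JSON simulation sidecar.

    The sidecar records the standard time course (end time 1100, sampled
    every 5 time units, LSODA tolerances) and provenance, so the full
    simulation experiment is reconstructible from the pair of files.
    """
    if x0 is None:
        x0 = np.zeros(model.n_species)
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (model.n_species,):
        raise ValueError("x0 length does not match the model")

    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    root = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "1"})
    n_rows = model.topology.n_rows if model.topology is not None else 1
    n_cols = model.topology.n_cols if model.topology is not None else 1
    mdl = ET.SubElement(root, f"{{{SBML_NS}}}model", {
        "id": f"segment_polarity_network_{n_rows}x{n_cols}",
        "name": f"Segment polarity network, {n_rows}x{n_cols} hexagonal cell grid",
    })

    comps = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfCompartments")
    for c in range(model.n_cells):
        lab = model._cell_label(c)
        ET.SubElement(comps, f"{{{SBML_NS}}}compartment", {
            "id": f"cell_{lab}", "size": "1", "spatialDimensions": "3",
            "constant": "true",
        })

    sps = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfSpecies")
    for i, name in enumerate(model.species_names):
        lab = name.rsplit("_", 2)
        ET.SubElement(sps, f"{{{SBML_NS}}}species", {
            "id": name, "compartment": f"cell_{lab[1]}_{lab[2]}",
            "initialConcentration": repr(float(x0[i])),
            "hasOnlySubstanceUnits": "false", "boundaryCondition": "false",
            "constant": "false",
        })

    pars = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfParameters")
    for row, val in zip(model.params.rows, model.param_vector):
        ET.SubElement(pars, f"{{{SBML_NS}}}parameter", {
            "id": row.name, "value": repr(float(val)), "constant": "true",
        })
    for total in model.totals:
        ET.SubElement(pars, f"{{{SBML_NS}}}parameter", {
            "id": total, "value": "0", "constant": "false",
        })

    rules = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfRules")
    for total, expr in model.totals.items():
        rule = ET.SubElement(rules, f"{{{SBML_NS}}}assignmentRule", {"variable": total})
        rule.append(_math_element(expr))

    rxns = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfReactions")
    for rxn in model.reactions:
        r = ET.SubElement(rxns, f"{{{SBML_NS}}}reaction", {
            "id": rxn.rid, "reversible": "false", "fast": "false",
        })
        reactants = [(s, st) for s, st in rxn.stoich if st < 0]
        products = [(s, st) for s, st in rxn.stoich if st > 0]
        if reactants:
            lo = ET.SubElement(r, f"{{{SBML_NS}}}listOfReactants")
            for s, st in reactants:
                ET.SubElement(lo, f"{{{SBML_NS}}}speciesReference", {
                    "species": s, "stoichiometry": repr(float(-st)),
                    "constant": "true",
                })
        if products:
            lo = ET.SubElement(r, f"{{{SBML_NS}}}listOfProducts")
            for s, st in products:
                ET.SubElement(lo, f"{{{SBML_NS}}}speciesReference", {
                    "species": s, "stoichiometry": repr(float(st)),
                    "constant": "true",
                })
        mods = [m for m in rxn.modifiers if m in model._species_index]
        if mods:
            lo = ET.SubElement(r, f"{{{SBML_NS}}}listOfModifiers")
            for m in mods:
                ET.SubElement(lo, f"{{{SBML_NS}}}modifierSpeciesReference",
                              {"species": m})
        kl = ET.SubElement(r, f"{{{SBML_NS}}}kineticLaw")
        kl.append(_math_element(rxn.rate))

    _validate_tree(mdl, model)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="unicode")

    cfg = model.params.to_config()
    sidecar = {
        "simulation": {
            "t_end": t_end, "dt_out": dt_out, "algorithm": "LSODA",
            "atol": atol, "rtol": rtol,
        },
        "provenance": {
            "tool": "spnsim",
            "version": getattr(__import__("spnsim"), "__version__", "0"),
            "seed": seed,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg, sort_keys=True).encode()
            ).hexdigest(),
            "guard": {"enabled": model.guard.enabled, "epsilon": model.guard.epsilon},
        },
    }
    sidecar_path = str(path) + ".sim.json"
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return ExportBundle(str(path), sidecar_path, sidecar,
                        model.n_species, len(model.reactions))


def _validate_tree(mdl: ET.Element, model: ModelSpec) -> None:
    """Structural validation of the document before writing."""
    ids = [el.get("id") for el in mdl.iter() if el.get("id")]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SbmlError(f"duplicate identifiers in document: {dupes[:5]}")
    species = {el.get("id") for el in mdl.find(f"{{{SBML_NS}}}listOfSpecies")}
    if len(species) != model.n_species:
        raise SbmlError("species list incomplete")
    for ref in mdl.iter(f"{{{SBML_NS}}}speciesReference"):
        if ref.get("species") not in species:
            raise SbmlError(f"unresolved species reference {ref.get('species')}")


# ---------------------------------------------------------------------------
# import
# ---------------------------------------------------------------------------

def _parse_cn(el: ET.Element) -> float:
    if el.get("type") == "e-notation":
        sep = el.find(f"{{{MATHML_NS}}}sep")
        return float(f"{el.text.strip()}e{sep.tail.strip()}")
    return float(el.text.strip())


def _parse_math(el: ET.Element) -> Expr:
    tag = el.tag.split("}")[-1]
    if tag == "math":
        kids = list(el)
        if len(kids) != 1:
            raise SbmlError("math element must have exactly one child")
        return _parse_math(kids[0])
    if tag == "cn":
        return Num(_parse_cn(el))
    if tag == "ci":
        return Sym(el.text.strip())
    if tag == "piecewise":
        pieces = el.findall(f"{{{MATHML_NS}}}piece")
        other = el.find(f"{{{MATHML_NS}}}otherwise")
        if len(pieces) != 1 or other is None:
            raise SbmlError("unsupported piecewise (need one piece + otherwise)")
        val, cond = list(pieces[0])
        ops = list(cond)
        if cond.tag.split("}")[-1] != "apply" or ops[0].tag.split("}")[-1] != "geq":
            raise SbmlError("unsupported piecewise condition (expected geq)")
        floor = _parse_math(list(other)[0])
        # pattern: piecewise(x if x >= eps else eps) == max(eps, x)
        return Max(floor, _parse_math(val))
    if tag == "apply":
        kids = list(el)
        op = kids[0].tag.split("}")[-1]
        args = [_parse_math(k) for k in kids[1:]]
        if op == "plus":
            out = args[0]
            for a in args[1:]:
                out = Add(out, a)
            return out
        if op == "times":
            out = args[0]
            for a in args[1:]:
                out = Mul(out, a)
            return out
        if op == "minus":
            if len(args) == 1:
                return Sub(Num(0.0), args[0])
            return Sub(args[0], args[1])
        if op == "divide":
            return Div(args[0], args[1])
        if op == "power":
            return Pow(args[0], args[1])
        raise SbmlError(f"unsupported MathML operator <{op}>")
    raise SbmlError(f"unsupported MathML element <{tag}>")


@dataclass
class ImportedModel:
    """Model reconstructed from an SBML document.

    ``rhs`` evaluates the document semantics directly (assignment rules,
    then reaction fluxes times stoichiometry); ``to_modelspec`` rebuilds a
    native :class:`ModelSpec` when the document follows this package's
    conventions, verifying right-hand-side agreement at random states.
    """

    species_names: list
    initial: np.ndarray
    parameters: dict
    rules: dict
    reactions: list
    compartments: list
    guard: GuardConfig
    sidecar: dict | None = None
    _index: dict = field(default_factory=dict)

    def __post_init__(self):
        self._index = {n: i for i, n in enumerate(self.species_names)}

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    def rhs(self, t, y) -> np.ndarray:
        env = dict(self.parameters)
        env.update({n: y[i] for i, n in enumerate(self.species_names)})
        for name, expr in self.rules.items():
            env[name] = expr.ev(env)
        dy = np.zeros(self.n_species)
        for rxn in self.reactions:
            v = rxn.rate.ev(env)
            for sid, st in rxn.stoich:
                dy[self._index[sid]] += st * v
        return dy

    def to_modelspec(self, check_states: int = 20, tol: float = 1e-9,
                     seed: int = 0) -> ModelSpec:
        ref = default_table()
        missing = [r.name for r in ref.rows if r.name not in self.parameters]
        if missing:
            raise SbmlError(f"document lacks registry parameters: {missing[:5]}")
        rows = []
        for r in ref.rows:
            rows.append(Parameter(r.name, self.parameters[r.name], r.range_lo,
                                  r.range_hi, r.scale, False, r.category))
        cells = sorted(
            tuple(int(x) for x in c.split("_")[1:]) for c in self.compartments
        )
        n_rows = max(r for r, _ in cells) + 1
        n_cols = max(c for _, c in cells) + 1
        model = build_model(n_rows, n_cols, ParameterTable(rows), self.guard)
        if model.species_names != self.species_names:
            raise SbmlError("species layout does not follow package conventions")
        rng = np.random.default_rng(seed)
        f = model.rhs_for(model.param_vector)
        for _ in range(check_states):
            y = rng.uniform(0.0, 1.0, model.n_species)
            a, b = f(0.0, y), self.rhs(0.0, y)
            denom = np.maximum(np.abs(a), 1e-30)
            if np.max(np.abs(a - b) / denom) > tol:
                raise SbmlError("imported document disagrees with native kinetics")
        return model


def import_sbml(path: str) -> ImportedModel:
    """Read an SBML L3 file with full kinetic laws."""
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise SbmlError(f"malformed SBML document: {exc}") from exc
    root = tree.getroot()
    mdl = root.find(f"{{{SBML_NS}}}model")
    if mdl is None:
        raise SbmlError("no <model> element (is this an SBML L3 file?)")

    compartments = [el.get("id") for el in
                    mdl.findall(f"{{{SBML_NS}}}listOfCompartments/{{{SBML_NS}}}compartment")]
    species_names, initial = [], []
    for el in mdl.findall(f"{{{SBML_NS}}}listOfSpecies/{{{SBML_NS}}}species"):
        species_names.append(el.get("id"))
        initial.append(float(el.get("initialConcentration", "0")))
    parameters, rule_targets = {}, set()
    for el in mdl.findall(f"{{{SBML_NS}}}listOfParameters/{{{SBML_NS}}}parameter"):
        parameters[el.get("id")] = float(el.get("value", "nan"))
    rules = {}
    for el in mdl.findall(f"{{{SBML_NS}}}listOfRules/{{{SBML_NS}}}assignmentRule"):
        target = el.get("variable")
        rules[target] = _parse_math(el.find(f"{{{MATHML_NS}}}math"))
        rule_targets.add(target)

    eps_seen, guard_seen = [], False
    reactions = []
    for el in mdl.findall(f"{{{SBML_NS}}}listOfReactions/{{{SBML_NS}}}reaction"):
        stoich = []
        for ref in el.findall(f"{{{SBML_NS}}}listOfReactants/{{{SBML_NS}}}speciesReference"):
            stoich.append((ref.get("species"), -float(ref.get("stoichiometry", "1"))))
        for ref in el.findall(f"{{{SBML_NS}}}listOfProducts/{{{SBML_NS}}}speciesReference"):
            stoich.append((ref.get("species"), float(ref.get("stoichiometry", "1"))))
        kl = el.find(f"{{{SBML_NS}}}kineticLaw")
        if kl is None:
            raise SbmlError(f"reaction {el.get('id')} has no kinetic law")
        rate = _parse_math(kl.find(f"{{{MATHML_NS}}}math"))
        mods = [m.get("species") for m in
                el.findall(f"{{{SBML_NS}}}listOfModifiers/{{{SBML_NS}}}modifierSpeciesReference")]
        reactions.append(Reaction(el.get("id"), stoich, rate, mods))
        for node in _iter_max(rate):
            guard_seen = True
            if isinstance(node.a, Num):
                eps_seen.append(node.a.value)

    known = set(species_names) | set(parameters) | rule_targets
    for rxn in reactions:
        unresolved = rxn.rate.symbols() - known
        if unresolved:
            raise SbmlError(
                f"reaction {rxn.rid} references unknown symbols {sorted(unresolved)[:5]}"
            )
    guard = GuardConfig(epsilon=min(eps_seen) if eps_seen else 1e-80,
                        enabled=guard_seen)
    sidecar = None
    try:
        with open(str(path) + ".sim.json") as fh:
            sidecar = json.load(fh)
    except (OSError, json.JSONDecodeError):
        pass
    return ImportedModel(species_names, np.array(initial), parameters, rules,
                         reactions, compartments, guard, sidecar)


def _iter_max(expr: Expr):
    if isinstance(expr, Max):
        yield expr
    for attr in ("a", "b"):
        child = getattr(expr, attr, None)
        if isinstance(child, Expr):
            yield from _iter_max(child)
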
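"""Read, write and summarise genome-scale models.

Two formats are supported:

* a **tabular TSV dialect** with one row per reaction (columns ``id``,
  ``name``, ``equation``, ``lower_bound``, ``upper_bound``, ``subsystem``,
  ``gpr``), mirroring the reaction-list spreadsheets that GSMM supplements
  ship as.  Equation strings use ``metId[compartment]`` tokens joined by
  ``+``, with `` => `` (irreversible) or `` <=> `` (reversible) separating
  substrates from products.  The arrow is display-only; reversibility is
  carried by the bounds.
* **SBML Level 3 + fbc v2** (flux bounds, gene-product associations and the
  active objective), via python-libsbml.

The tabular reader accepts a column-mapping so externally produced sheets can
be ingested after renaming alone.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import pandas as pd

from .model import (
    EXTRACELLULAR,
    GPR,
    GPRParseError,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    parse_gpr,
)

__all__ = [
    "read_model",
    "write_model",
    "read_tabular",
    "write_tabular",
    "read_sbml",
    "write_sbml",
    "parse_equation",
    "format_equation",
    "summarize_subsystems",
    "EquationParseError",
    "TABULAR_COLUMNS",
]


class EquationParseError(ValueError):
    pass


TABULAR_COLUMNS = {
    "id": "id",
    "name": "name",
    "equation": "equation",
    "lower_bound": "lower_bound",
    "upper_bound": "upper_bound",
    "subsystem": "subsystem",
    "gpr": "gpr",
}

_TOKEN_RE = re.compile(r"^(?:(?P<coef>[0-9.eE+-]+)\s+)?(?P<met>[^\s\[\]]+)\[(?P<comp>[^\[\]]+)\]$")


def parse_equation(equation: str, reaction_id: str = "?") -> Tuple[Dict[str, float], Dict[str, str]]:
    """Parse an equation string into (stoichiometry, metabolite->compartment).

    Reactants get negative coefficients.  Either side may be empty (exchange
    and sink reactions).
    """
    for arrow in ("<=>", "=>", "<->", "->"):
        if arrow in equation:
            left, right = equation.split(arrow, 1)
            break
    else:
        raise EquationParseError(
            f"reaction {reaction_id!r}: no reaction arrow in equation {equation!r}"
        )
    stoich: Dict[str, float] = {}
    comps: Dict[str, str] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in re.split(r"\s+\+\s+", side):
            term = term.strip()
            if not term:
                continue
            m = _TOKEN_RE.match(term)
            if m is None:
                raise EquationParseError(
                    f"reaction {reaction_id!r}: cannot parse term {term!r}"
                )
            try:
                coef = float(m.group("coef")) if m.group("coef") else 1.0
            except ValueError as exc:
                raise EquationParseError(
                    f"reaction {reaction_id!r}: bad coefficient in {term!r}"
                ) from exc
            met = m.group("met")
            stoich[met] = stoich.get(met, 0.0) + sign * coef
            comps[met] = m.group("comp")

    add_side(left, -1.0)
    add_side(right, +1.0)
    stoich = {k: v for k, v in stoich.items() if v != 0.0}
    if not stoich:
        raise EquationParseError(f"reaction {reaction_id!r}: empty equation")
    return stoich, comps


def _fmt_num(x: float) -> str:
    return format(float(x), ".10g")


def format_equation(reaction: Reaction, model: MetabolicModel) -> str:
    comp = {m.id: m.compartment for m in model.metabolites}

    def side(items: List[Tuple[str, float]]) -> str:
        parts = []
        for met_id, coef in items:
            tok = f"{met_id}[{comp[met_id]}]"
            if abs(coef) != 1.0:
                tok = f"{_fmt_num(abs(coef))} {tok}"
            parts.append(tok)
        return " + ".join(parts)

    items = sorted(reaction.stoichiometry.items())
    lhs = [(m, c) for m, c in items if c < 0]
    rhs = [(m, c) for m, c in items if c > 0]
    arrow = "<=>" if reaction.reversible else "=>"
    return f"{side(lhs)} {arrow} {side(rhs)}".strip()


# ---------------------------------------------------------------------------
# Tabular dialect
# ---------------------------------------------------------------------------

def write_tabular(model: MetabolicModel, path: Union[str, Path]) -> None:
    model.validate()
    path = Path(path)
    lines = []
    meta = {
        "id": model.id,
        "objective_id": model.objective_id,
        "dha_exchange_id": model.dha_exchange_id,
        "genes": sorted(model.genes),
    }
    lines.append("#%% " + json.dumps(meta, sort_keys=True))
    for m in model.metabolites:
        lines.append(
            "#met\t" + "\t".join([m.id, m.name, m.compartment, m.formula or ""])
        )
    lines.append("\t".join(TABULAR_COLUMNS))
    for r in model.reactions:
        gpr = r.gpr.to_string() if r.gpr is not None else ""
        lines.append(
            "\t".join(
                [
                    r.id,
                    r.name,
                    format_equation(r, model),
                    _fmt_num(r.lower_bound),
                    _fmt_num(r.upper_bound),
                    r.subsystem,
                    gpr,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def read_tabular(
    path: Union[str, Path],
    column_map: Optional[Dict[str, str]] = None,
) -> MetabolicModel:
    """Read the tabular dialect.  *column_map* maps the standard column names
    (keys of :data:`TABULAR_COLUMNS`) to the names used in the file."""
    path = Path(path)
    colmap = dict(TABULAR_COLUMNS)
    if column_map:
        colmap.update(column_map)

    meta: Dict[str, object] = {}
    met_rows: List[List[str]] = []
    body: List[str] = []
    for line in path.read_text().splitlines():
        if line.startswith("#%%"):
            meta = json.loads(line[3:])
        elif line.startswith("#met\t"):
            met_rows.append(line.split("\t")[1:])
        elif line.startswith("#") or not line.strip():
            continue
        else:
            body.append(line)
    if not body:
        raise EquationParseError(f"{path}: no reaction table found")

    header = body[0].split("\t")
    idx = {}
    for std, col in colmap.items():
        if col in header:
            idx[std] = header.index(col)
    for required in ("id", "equation"):
        if required not in idx:
            raise EquationParseError(
                f"{path}: missing required column {colmap[required]!r}"
            )

    metabolites: Dict[str, Metabolite] = {}
    for row in met_rows:
        mid, name, comp = row[0], row[1], row[2]
        formula = row[3] or None if len(row) > 3 else None
        metabolites[mid] = Metabolite(mid, name, comp, formula)

    reactions: List[Reaction] = []
    genes = set(meta.get("genes", []))
    for line in body[1:]:
        row = line.split("\t")

        def get(std: str, default: str = "") -> str:
            i = idx.get(std)
            return row[i].strip() if i is not None and i < len(row) else default

        rid = get("id")
        stoich, comps = parse_equation(get("equation"), rid)
        for met_id, comp in comps.items():
            if met_id not in metabolites:
                metabolites[met_id] = Metabolite(met_id, met_id, comp)
            elif metabolites[met_id].compartment != comp:
                raise ModelValidationError(
                    f"reaction {rid!r}: metabolite {met_id!r} tagged [{comp}] but "
                    f"declared in compartment [{metabolites[met_id].compartment}]"
                )
        try:
            lb = float(get("lower_bound", "0") or 0.0)
            ub = float(get("upper_bound", "1000") or 1000.0)
        except ValueError as exc:
            raise EquationParseError(f"reaction {rid!r}: bad bounds") from exc
        gpr_str = get("gpr")
        gpr = parse_gpr(gpr_str) if gpr_str else None
        if gpr is not None:
            genes |= gpr.genes()
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                subsystem=get("subsystem"),
                gpr=gpr,
                name=get("name") or rid,
            )
        )

    model = MetabolicModel(
        id=str(meta.get("id", path.stem)),
        metabolites=list(metabolites.values()),
        reactions=reactions,
        genes=sorted(genes),
        objective_id=meta.get("objective_id"),
        dha_exchange_id=meta.get("dha_exchange_id"),
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# SBML L3 + fbc v2
# ---------------------------------------------------------------------------

def _sbml_safe(sid: str) -> str:
    out = re.sub(r"[^A-Za-z0-9_]", "_", sid)
    if not re.match(r"[A-Za-z_]", out):
        out = "x" + out
    return out


def write_sbml(model: MetabolicModel, path: Union[str, Path]) -> None:
    import libsbml

    model.validate()
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sbml_safe(model.id))
    sm.setName(model.id)
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(False)
    if model.dha_exchange_id is not None:
        sm.appendNotes(
            "<body xmlns='http://www.w3.org/1999/xhtml'><p>"
            f"dha_exchange_id: {model.dha_exchange_id}</p></body>"
        )

    for comp_id in sorted({m.compartment for m in model.metabolites}):
        comp = sm.createCompartment()
        comp.setId(_sbml_safe(comp_id))
        comp.setConstant(True)

    for m in model.metabolites:
        sp = sm.createSpecies()
        sp.setId("M_" + _sbml_safe(m.id))
        sp.setName(m.name)
        sp.setCompartment(_sbml_safe(m.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        if m.formula:
            sp.getPlugin("fbc").setChemicalFormula(m.formula)

    def add_param(pid: str, value: float) -> str:
        p = sm.createParameter()
        p.setId(pid)
        p.setValue(float(value))
        p.setConstant(True)
        return pid

    gene_done = set()
    for g in sorted(model.genes):
        gp = mplug.createGeneProduct()
        gp.setId("G_" + _sbml_safe(g))
        gp.setLabel(g)
        gene_done.add(g)

    for r in model.reactions:
        rx = sm.createReaction()
        rid = "R_" + _sbml_safe(r.id)
        rx.setId(rid)
        rx.setName(r.name)
        rx.setFast(False)
        rx.setReversible(r.reversible)
        if r.subsystem:
            rx.appendNotes(
                "<body xmlns='http://www.w3.org/1999/xhtml'><p>"
                f"subsystem: {r.subsystem}</p></body>"
            )
        for met_id, coef in sorted(r.stoichiometry.items()):
            ref = rx.createReactant() if coef < 0 else rx.createProduct()
            ref.setSpecies("M_" + _sbml_safe(met_id))
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(add_param(rid + "_lb", r.lower_bound))
        rplug.setUpperFluxBound(add_param(rid + "_ub", r.upper_bound))
        if r.gpr is not None and not r.gpr.is_empty:
            gpa = rplug.createGeneProductAssociation()
            infix = r.gpr.to_string()
            for g in sorted(r.gpr.genes(), key=len, reverse=True):
                infix = re.sub(
                    r"(?<![\w])" + re.escape(g) + r"(?![\w])",
                    "G_" + _sbml_safe(g),
                    infix,
                )
            gpa.setAssociation(infix, True, False)

    obj = mplug.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    mplug.setActiveObjectiveId("obj")
    if model.objective_id is not None:
        fo = obj.createFluxObjective()
        fo.setReaction("R_" + _sbml_safe(model.objective_id))
        fo.setCoefficient(1.0)

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


def read_sbml(path: Union[str, Path]) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ModelValidationError(
            f"{path}: SBML parse error: "
            + doc.getErrorLog().toString()
        )
    sm = doc.getModel()
    if sm is None:
        raise ModelValidationError(f"{path}: no model element")
    mplug = sm.getPlugin("fbc")

    def strip(prefix: str, sid: str) -> str:
        return sid[len(prefix):] if sid.startswith(prefix) else sid

    metabolites = []
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        formula = None
        spf = sp.getPlugin("fbc")
        if spf is not None and spf.isSetChemicalFormula():
            formula = spf.getChemicalFormula()
        metabolites.append(
            Metabolite(
                id=strip("M_", sp.getId()),
                name=sp.getName() or strip("M_", sp.getId()),
                compartment=sp.getCompartment(),
                formula=formula,
            )
        )

    gene_by_sid: Dict[str, str] = {}
    genes: List[str] = []
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            label = gp.getLabel() or strip("G_", gp.getId())
            gene_by_sid[gp.getId()] = label
            genes.append(label)

    def notes_field(node, key: str) -> Optional[str]:
        if not node.isSetNotes():
            return None
        text = node.getNotesString()
        m = re.search(re.escape(key) + r":\s*([^<\n]+)", text)
        return m.group(1).strip() if m else None

    reactions = []
    for i in range(sm.getNumReactions()):
        rx = sm.getReaction(i)
        rid = strip("R_", rx.getId())
        stoich: Dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            met = strip("M_", ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            met = strip("M_", ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0.0}
        rplug = rx.getPlugin("fbc")
        lb, ub = -1000.0, 1000.0
        if rplug is not None:
            plb = sm.getParameter(rplug.getLowerFluxBound())
            pub = sm.getParameter(rplug.getUpperFluxBound())
            if plb is not None:
                lb = plb.getValue()
            if pub is not None:
                ub = pub.getValue()
        gpr = None
        if rplug is not None and rplug.isSetGeneProductAssociation():
            assoc = rplug.getGeneProductAssociation().getAssociation()
            infix = libsbml.FbcAssociation.toInfix(assoc) if assoc else ""
            for sid, label in sorted(gene_by_sid.items(), key=lambda kv: -len(kv[0])):
                infix = re.sub(r"(?<![\w])" + re.escape(sid) + r"(?![\w])", label, infix)
            if infix.strip():
                gpr = parse_gpr(infix)
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                subsystem=notes_field(rx, "subsystem") or "",
                gpr=gpr,
                name=rx.getName() or rid,
            )
        )

    objective_id = None
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getObjective(mplug.getActiveObjectiveId()) or mplug.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective_id = strip("R_", obj.getFluxObjective(0).getReaction())

    model = MetabolicModel(
        id=sm.getName() or sm.getId() or Path(path).stem,
        metabolites=metabolites,
        reactions=reactions,
        genes=sorted(set(genes)),
        objective_id=objective_id,
        dha_exchange_id=notes_field(sm, "dha_exchange_id"),
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Dispatch + summaries
# ---------------------------------------------------------------------------

def _infer_format(path: Union[str, Path], fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml"
    return "tabular"


def read_model(
    path: Union[str, Path],
    format: Optional[str] = None,
    column_map: Optional[Dict[str, str]] = None,
) -> MetabolicModel:
    fmt = _infer_format(path, format)
    if fmt == "sbml":
        return read_sbml(path)
    if fmt == "tabular":
        return read_tabular(path, column_map=column_map)
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path: Union[str, Path], format: Optional[str] = None) -> None:
    fmt = _infer_format(path, format)
    if fmt == "sbml":
        write_sbml(model, path)
    elif fmt == "tabular":
        write_tabular(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")


def load_summary(model: MetabolicModel) -> str:
    """Load summary as a JSON string (reaction/metabolite/gene counts)."""
    return json.dumps(model.summary(), indent=2, sort_keys=True)


def summarize_subsystems(model: MetabolicModel) -> pd.DataFrame:
    """Per-subsystem reaction counts and percentages (each reaction counted
    once; percentages sum to 100 up to rounding)."""
    labels = [r.subsystem or "unassigned" for r in model.reactions]
    counts = pd.Series(labels).value_counts()
    df = pd.DataFrame(
        {
            "subsystem": counts.index,
            "n_reactions": counts.values,
        }
    )
    df["percent"] = 100.0 * df["n_reactions"] / len(model.reactions)
    return df.reset_index(drop=True)
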
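"""Core in-memory representation of a genome-scale metabolic model.

A model is a stoichiometric matrix S (m metabolites x n reactions) together
with flux bounds, boolean gene-protein-reaction (GPR) rules, subsystem labels
and a biomass objective.  Exchange reactions are pseudo-reactions that move a
single extracellular metabolite across the system boundary; by convention a
negative exchange flux is uptake and a positive one is secretion.  All fluxes
are in mmol/gDW/h (the biomass flux is the specific growth rate in /h).
"""

from __future__ import annotations

import copy as _copy
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import sparse

__all__ = [
    "Metabolite",
    "Reaction",
    "GPR",
    "MetabolicModel",
    "parse_gpr",
    "models_equal",
    "ModelValidationError",
    "GPRParseError",
    "EXTRACELLULAR",
]

#: compartment tag used to recognise exchange reactions
EXTRACELLULAR = "e"


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


class GPRParseError(ValueError):
    """Raised for malformed gene-protein-reaction rule strings."""


# ---------------------------------------------------------------------------
# GPR boolean expressions
# ---------------------------------------------------------------------------

class _Node:
    def evaluate(self, knocked: Set[str]) -> bool:  # pragma: no cover - abstract
        raise NotImplementedError

    def genes(self) -> Set[str]:  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass(frozen=True)
class _Gene(_Node):
    name: str

    def evaluate(self, knocked: Set[str]) -> bool:
        return self.name not in knocked

    def genes(self) -> Set[str]:
        return {self.name}

    def to_string(self) -> str:
        return self.name


@dataclass(frozen=True)
class _Bool(_Node):
    op: str  # "and" | "or"
    children: Tuple[_Node, ...]

    def evaluate(self, knocked: Set[str]) -> bool:
        results = (c.evaluate(knocked) for c in self.children)
        return all(results) if self.op == "and" else any(results)

    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def to_string(self) -> str:
        parts = []
        for c in self.children:
            s = c.to_string() if isinstance(c, _Gene) else "(" + c.to_string() + ")"
            parts.append(s)
        return (" %s " % self.op).join(parts)


@dataclass
class GPR:
    """A boolean gene-protein-reaction rule.

    ``and`` encodes an enzyme complex (every subunit required), ``or``
    isozymes (any one suffices).  An empty rule is always active.
    """

    root: Optional[_Node] = None

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def evaluate(self, knocked_out: Iterable[str] = ()) -> bool:
        """Is the reaction still catalysable when *knocked_out* genes are gone?"""
        if self.root is None:
            return True
        return self.root.evaluate(set(knocked_out))

    def genes(self) -> Set[str]:
        return set() if self.root is None else self.root.genes()

    def to_string(self) -> str:
        return "" if self.root is None else self.root.to_string()

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(rule: str) -> GPR:
    """Parse a GPR rule string like ``"(A and B) or C"`` into a :class:`GPR`.

    Gene identifiers are any whitespace/parenthesis-free tokens; ``and`` /
    ``or`` (case-insensitive, also ``&`` / ``|``) are the operators.  An empty
    or whitespace-only string yields the always-active rule.
    """
    tokens = _TOKEN_RE.findall(rule or "")
    if not tokens:
        return GPR(None)

    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def is_op(tok: Optional[str], which: str) -> bool:
        if tok is None:
            return False
        low = tok.lower()
        return low == which or (which == "and" and tok == "&") or (
            which == "or" and tok == "|"
        )

    def parse_factor() -> _Node:
        tok = peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of rule: {rule!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GPRParseError(f"unbalanced parentheses in rule: {rule!r}")
            take()
            return node
        if tok == ")" or is_op(tok, "and") or is_op(tok, "or"):
            raise GPRParseError(f"misplaced token {tok!r} in rule: {rule!r}")
        return _Gene(take())

    def parse_and() -> _Node:
        children = [parse_factor()]
        while is_op(peek(), "and"):
            take()
            children.append(parse_factor())
        return children[0] if len(children) == 1 else _Bool("and", tuple(children))

    def parse_or() -> _Node:
        children = [parse_and()]
        while is_op(peek(), "or"):
            take()
            children.append(parse_and())
        return children[0] if len(children) == 1 else _Bool("or", tuple(children))

    node = parse_or()
    if pos != len(tokens):
        raise GPRParseError(f"trailing tokens in rule: {rule!r}")
    return GPR(node)


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.name:
            self.name = self.id


@dataclass
class Reaction:
    """One column of S: a sparse stoichiometry plus flux bounds.

    Reactants carry negative coefficients, products positive ones.
    Reversibility is encoded purely by ``lower_bound < 0``.
    """

    id: str
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    subsystem: str = ""
    gpr: Optional[GPR] = None
    name: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            self.name = self.id

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def gene_ids(self) -> Set[str]:
        return self.gpr.genes() if self.gpr is not None else set()

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            subsystem=self.subsystem,
            gpr=self.gpr,  # GPR trees are immutable once built
            name=self.name,
        )


@dataclass
class MetabolicModel:
    id: str = "model"
    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    genes: List[str] = field(default_factory=list)
    objective_id: Optional[str] = None
    dha_exchange_id: Optional[str] = None

    # -- lookup helpers ----------------------------------------------------

    def metabolite_index(self) -> Dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    def reaction_index(self) -> Dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(f"no metabolite {met_id!r} in model {self.id!r}")

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(f"no reaction {rxn_id!r} in model {self.id!r}")

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=[_copy.copy(m) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            genes=list(self.genes),
            objective_id=self.objective_id,
            dha_exchange_id=self.dha_exchange_id,
        )

    # -- structure ---------------------------------------------------------

    def is_exchange(self, reaction: Reaction) -> bool:
        """Exchange = touches exactly one metabolite, in the extracellular
        compartment (robust to id naming, per the boundary convention)."""
        if len(reaction.stoichiometry) != 1:
            return False
        (met_id,) = reaction.stoichiometry
        try:
            met = self.metabolite(met_id)
        except KeyError:
            return False
        return met.compartment == EXTRACELLULAR

    def exchange_reactions(self) -> List[Reaction]:
        return [r for r in self.reactions if self.is_exchange(r)]

    def is_transport(self, reaction: Reaction) -> bool:
        """Heuristic: the same chemical species appears in >= 2 compartments."""
        midx = {m.id: m for m in self.metabolites}
        seen: Dict[str, Set[str]] = {}
        for met_id in reaction.stoichiometry:
            met = midx.get(met_id)
            if met is None:
                continue
            base = met_base_name(met)
            seen.setdefault(base, set()).add(met.compartment)
        return any(len(comps) > 1 for comps in seen.values())

    def stoichiometric_matrix(self) -> Tuple[sparse.csr_matrix, List[str], List[str]]:
        """Return (S, metabolite ids, reaction ids) with S of shape m x n."""
        midx = self.metabolite_index()
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(self.reactions):
            for met_id, coef in rxn.stoichiometry.items():
                rows.append(midx[met_id])
                cols.append(j)
                vals.append(float(coef))
        S = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )
        return S, [m.id for m in self.metabolites], [r.id for r in self.reactions]

    def bounds_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Check every structural invariant; raise ModelValidationError."""
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise ModelValidationError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelValidationError("duplicate reaction ids")
        for m in self.metabolites:
            if not m.compartment:
                raise ModelValidationError(f"metabolite {m.id!r}: empty compartment")
        met_set = set(met_ids)
        gene_set = set(self.genes)
        for r in self.reactions:
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(
                    f"reaction {r.id!r}: lower_bound > upper_bound"
                )
            if not r.stoichiometry:
                raise ModelValidationError(f"reaction {r.id!r}: empty stoichiometry")
            missing = set(r.stoichiometry) - met_set
            if missing:
                raise ModelValidationError(
                    f"reaction {r.id!r} references unknown metabolites {sorted(missing)}"
                )
            extra = r.gene_ids() - gene_set
            if extra:
                raise ModelValidationError(
                    f"reaction {r.id!r} GPR uses genes not in model list: {sorted(extra)}"
                )
        if self.objective_id is not None and self.objective_id not in set(rxn_ids):
            raise ModelValidationError(
                f"objective reaction {self.objective_id!r} not in model"
            )
        if self.dha_exchange_id is not None and self.dha_exchange_id not in set(rxn_ids):
            raise ModelValidationError(
                f"DHA exchange {self.dha_exchange_id!r} not in model"
            )

    def summary(self) -> Dict[str, object]:
        return {
            "model": self.id,
            "reactions": len(self.reactions),
            "metabolites": len(self.metabolites),
            "genes": len(self.genes),
            "exchanges": len(self.exchange_reactions()),
            "objective": self.objective_id,
            "dha_exchange": self.dha_exchange_id,
        }


def met_base_name(met: Metabolite) -> str:
    """Chemical species name with the compartment suffix stripped.

    Follows the ``<base>_<compartment>`` id convention when present, falling
    back to the raw id.
    """
    suffix = "_" + met.compartment
    if met.id.endswith(suffix):
        return met.id[: -len(suffix)]
    return met.id


def models_equal(
    a: MetabolicModel,
    b: MetabolicModel,
    *,
    check_names: bool = False,
    atol: float = 1e-9,
) -> bool:
    """Structural equality: same metabolites, reactions, stoichiometry, bounds,
    subsystems, GPRs, gene list and objective/DHA designations."""
    if sorted(m.id for m in a.metabolites) != sorted(m.id for m in b.metabolites):
        return False
    bm = {m.id: m for m in b.metabolites}
    for m in a.metabolites:
        other = bm[m.id]
        if m.compartment != other.compartment:
            return False
        if check_names and (m.name != other.name or m.formula != other.formula):
            return False
    if sorted(r.id for r in a.reactions) != sorted(r.id for r in b.reactions):
        return False
    br = {r.id: r for r in b.reactions}
    for r in a.reactions:
        o = br[r.id]
        if set(r.stoichiometry) != set(o.stoichiometry):
            return False
        for met_id, coef in r.stoichiometry.items():
            if abs(coef - o.stoichiometry[met_id]) > atol:
                return False
        if abs(r.lower_bound - o.lower_bound) > atol:
            return False
        if abs(r.upper_bound - o.upper_bound) > atol:
            return False
        if r.subsystem != o.subsystem:
            return False
        ga = r.gpr.to_string() if r.gpr is not None else ""
        gb = o.gpr.to_string() if o.gpr is not None else ""
        if ga != gb:
            return False
    if sorted(a.genes) != sorted(b.genes):
        return False
    return (
        a.objective_id == b.objective_id and a.dha_exchange_id == b.dha_exchange_id
    )
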
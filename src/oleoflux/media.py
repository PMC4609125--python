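"""In silico media as exchange-bound overrides.

A medium is a named map ``exchange reaction id -> (lower bound, upper bound)``
in mmol/gDW/h.  Applying a medium with ``closed_default=True`` (the default)
closes uptake on every *unlisted* exchange (lower bound 0) while leaving
secretion free (upper bound 1000), which is what makes a minimal medium
minimal: only the listed nutrients exist.

Two standard media are provided, mirroring the usual validation setup for
oleaginous microbes grown on defined substrates:

* **MG** (minimal glucose): glucose uptake at 1.4 mmol/gDW/h, ammonia at 10,
  and free exchange of water, oxygen, phosphate, sulfate and protons.  A
  glycerol variant swaps the carbon source to glycerol at 1.6 mmol/gDW/h.
* **YE** (yeast extract): MG plus all 20 proteinogenic amino acids at a
  maximum uptake of 0.1 mmol/gDW/h each.

Exchange reactions are located by the chemical species they exchange (via an
overridable alias table), not by reaction id, so the same medium definitions
work across model naming dialects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple, Union

from .model import MetabolicModel, met_base_name

__all__ = [
    "Medium",
    "MediumError",
    "make_standard_medium",
    "apply_medium",
    "find_exchange",
    "DEFAULT_ALIASES",
    "AMINO_ACIDS",
    "GLUCOSE_UPTAKE",
    "GLYCEROL_UPTAKE",
    "AMMONIA_UPTAKE",
    "AMINO_ACID_UPTAKE",
    "FREE_BOUND",
]

GLUCOSE_UPTAKE = 1.4
GLYCEROL_UPTAKE = 1.6
AMMONIA_UPTAKE = 10.0
AMINO_ACID_UPTAKE = 0.1
FREE_BOUND = 1000.0

#: the 20 proteinogenic amino acids, three-letter codes
AMINO_ACIDS = [
    "ala", "arg", "asn", "asp", "cys", "gln", "glu", "gly", "his", "ile",
    "leu", "lys", "met", "phe", "pro", "ser", "thr", "trp", "tyr", "val",
]

DEFAULT_ALIASES: Dict[str, List[str]] = {
    "glucose": ["glc", "glc__d", "glc_d", "glucose", "d-glucose"],
    "glycerol": ["glyc", "glycerol"],
    "water": ["h2o", "water"],
    "oxygen": ["o2", "oxygen"],
    "ammonia": ["nh3", "nh4", "ammonia", "ammonium"],
    "phosphate": ["pi", "phosphate", "orthophosphate"],
    "sulfate": ["so4", "sulfate", "sulphate"],
    "proton": ["h", "h+", "proton"],
}
DEFAULT_ALIASES.update({aa: [aa] for aa in AMINO_ACIDS})


class MediumError(ValueError):
    pass


@dataclass
class Medium:
    name: str
    bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, (lb, ub) in self.bounds.items():
            if lb > ub:
                raise MediumError(f"medium {self.name!r}: {rid} has lb > ub")

    def with_bound(self, rxn_id: str, lb: float, ub: float = FREE_BOUND) -> "Medium":
        bounds = dict(self.bounds)
        bounds[rxn_id] = (float(lb), float(ub))
        return Medium(self.name, bounds)

    def without(self, rxn_ids: Iterable[str]) -> "Medium":
        drop = set(rxn_ids)
        return Medium(self.name, {k: v for k, v in self.bounds.items() if k not in drop})

    def to_json(self, path: Optional[Union[str, Path]] = None) -> str:
        payload = json.dumps(
            {"name": self.name, "bounds": {k: list(v) for k, v in sorted(self.bounds.items())}},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "Medium":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = json.loads(text)
        return cls(data["name"], {k: (float(v[0]), float(v[1])) for k, v in data["bounds"].items()})


def find_exchange(
    model: MetabolicModel,
    species: str,
    aliases: Optional[Mapping[str, List[str]]] = None,
) -> Optional[str]:
    """Locate the exchange reaction for a chemical species key.

    Matching is case-insensitive on the exchanged metabolite's base id (its
    id with the compartment suffix stripped) and on its name.
    """
    table = dict(DEFAULT_ALIASES)
    if aliases:
        table.update(aliases)
    wanted = {a.lower() for a in table.get(species, [species])}
    for rxn in model.exchange_reactions():
        (met_id,) = rxn.stoichiometry
        met = model.metabolite(met_id)
        candidates = {met_base_name(met).lower(), met.name.lower(), met.id.lower()}
        if candidates & wanted:
            return rxn.id
    return None


_MG_SPECIES: List[Tuple[str, float]] = [
    ("water", -FREE_BOUND),
    ("oxygen", -FREE_BOUND),
    ("ammonia", -AMMONIA_UPTAKE),
    ("phosphate", -FREE_BOUND),
    ("sulfate", -FREE_BOUND),
    ("proton", -FREE_BOUND),
]


def make_standard_medium(
    kind: str,
    model: MetabolicModel,
    aliases: Optional[Mapping[str, List[str]]] = None,
    amino_acid_uptake: float = AMINO_ACID_UPTAKE,
) -> Medium:
    """Build one of the standard media (``MG_glucose``, ``MG_glycerol``,
    ``YE``) against *model*'s exchange reactions.

    Raises :class:`MediumError` listing any required exchange that cannot be
    located.  For YE, amino-acid exchanges absent from the model are simply
    skipped (models differ in which amino acids they exchange); the mineral
    backbone must be present.
    """
    if kind not in ("MG_glucose", "MG_glycerol", "YE"):
        raise MediumError(f"unknown standard medium kind {kind!r}")

    carbon = "glycerol" if kind == "MG_glycerol" else "glucose"
    carbon_rate = GLYCEROL_UPTAKE if kind == "MG_glycerol" else GLUCOSE_UPTAKE

    required = [(carbon, -carbon_rate)] + _MG_SPECIES
    bounds: Dict[str, Tuple[float, float]] = {}
    missing: List[str] = []
    for species, lb in required:
        rid = find_exchange(model, species, aliases)
        if rid is None:
            missing.append(species)
        else:
            bounds[rid] = (lb, FREE_BOUND)
    if missing:
        raise MediumError(
            f"model {model.id!r} lacks exchange reactions for: {', '.join(missing)}"
        )

    if kind == "YE":
        for aa in AMINO_ACIDS:
            rid = find_exchange(model, aa, aliases)
            if rid is not None and rid not in bounds:
                bounds[rid] = (-amino_acid_uptake, FREE_BOUND)

    return Medium(kind, bounds)


def apply_medium(
    model: MetabolicModel,
    medium: Medium,
    closed_default: bool = True,
) -> MetabolicModel:
    """Return a copy of *model* with the medium's exchange bounds applied.

    With *closed_default*, every exchange not listed in the medium gets
    (0, 1000): no uptake, free secretion.  The input model is not modified.
    Idempotent: applying the same medium twice gives the same bounds.
    """
    rxn_ids = {r.id for r in model.reactions}
    exchange_ids = {r.id for r in model.exchange_reactions()}
    unknown = set(medium.bounds) - rxn_ids
    if unknown:
        raise MediumError(
            f"medium {medium.name!r} references absent reactions: {sorted(unknown)}"
        )
    not_exchange = set(medium.bounds) - exchange_ids
    if not_exchange:
        raise MediumError(
            f"medium {medium.name!r} entries are not exchange reactions: "
            f"{sorted(not_exchange)}"
        )
    out = model.copy()
    for rxn in out.reactions:
        if rxn.id in medium.bounds:
            rxn.lower_bound, rxn.upper_bound = medium.bounds[rxn.id]
        elif closed_default and rxn.id in exchange_ids:
            rxn.lower_bound, rxn.upper_bound = 0.0, FREE_BOUND
    return out
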
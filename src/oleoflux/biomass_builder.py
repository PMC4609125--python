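"""Assemble a biomass pseudo-reaction from measured cell composition.

The biomass equation drains monomeric precursors in the proportions measured
for 1 g of dry cell weight, so that a unit of biomass flux corresponds to a
specific growth rate of 1 /h.  Inputs are macromolecular mass fractions
(g/gDCW) for lipid, protein, carbohydrate, DNA, RNA and ash, plus per-class
monomer profiles and the genomic G+C content.

Nucleotide mole fractions follow directly from GC under the usual two-strand
symmetry: dGTP = dCTP = gc/2 and dATP = dTTP = (1-gc)/2, with the RNA
profile analogous (UTP in place of dTTP).  Monomers are accounted as
polymerised residues by default: one water of condensation (18.0153 g/mol)
is subtracted from each protein and nucleic-acid monomer weight, the
standard convention for biomass equations (toggle with
``residue_weights=False``).

Growth-associated maintenance (GAM) ATP is appended as a configurable
hydrolysis term; reconstructions rarely print it, so the default (30
mmol/gDCW) is the order of magnitude used by reference fungal models and
should be refit when energetic data exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

from .model import Reaction

__all__ = ["BiomassComposition", "CompositionError", "build_biomass_reaction",
           "WATER_MW", "DEFAULT_GAM"]

#: g/mmol of one water of polymerisation
WATER_MW = 0.0180153
#: default growth-associated maintenance, mmol ATP per gDCW
DEFAULT_GAM = 30.0

_MASS_TOL = 0.01


class CompositionError(ValueError):
    pass


def _check_profile(name: str, profile: Mapping[str, float]) -> None:
    if not profile:
        raise CompositionError(f"{name} profile is empty")
    if any(v < 0 for v in profile.values()):
        raise CompositionError(f"{name} profile has negative fractions")
    total = sum(profile.values())
    if abs(total - 1.0) > _MASS_TOL:
        raise CompositionError(f"{name} profile sums to {total:.4f}, not 1")


@dataclass
class BiomassComposition:
    """Macromolecular composition in g/gDCW plus monomer profiles.

    ``protein_profile`` / ``lipid_profile`` / ``carbohydrate_profile`` map
    metabolite ids to *mass* fractions within their class (each summing to
    1).  ``dna_nucleotides`` / ``rna_nucleotides`` map the letters G, C, A
    and T (U for RNA) to metabolite ids; their mole fractions come from
    ``gc_content``.  ``mineral_profile`` distributes the ash fraction.
    """

    lipid: float
    protein: float
    carbohydrate: float
    dna: float
    rna: float
    ash: float = 0.0
    gc_content: float = 0.5
    protein_profile: Dict[str, float] = field(default_factory=dict)
    lipid_profile: Dict[str, float] = field(default_factory=dict)
    carbohydrate_profile: Dict[str, float] = field(default_factory=dict)
    dna_nucleotides: Dict[str, str] = field(default_factory=dict)
    rna_nucleotides: Dict[str, str] = field(default_factory=dict)
    mineral_profile: Dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        fractions = {
            "lipid": self.lipid, "protein": self.protein,
            "carbohydrate": self.carbohydrate, "dna": self.dna,
            "rna": self.rna, "ash": self.ash,
        }
        if any(v < 0 for v in fractions.values()):
            raise CompositionError("macromolecular fractions must be >= 0")
        total = sum(fractions.values())
        if abs(total - 1.0) > _MASS_TOL:
            raise CompositionError(
                f"macromolecular fractions sum to {total:.4f}, expected 1 +/- {_MASS_TOL}"
            )
        if not (0.0 < self.gc_content < 1.0):
            raise CompositionError("gc_content must lie in (0, 1)")
        for name, profile, fraction in (
            ("protein", self.protein_profile, self.protein),
            ("lipid", self.lipid_profile, self.lipid),
            ("carbohydrate", self.carbohydrate_profile, self.carbohydrate),
            ("mineral", self.mineral_profile, self.ash),
        ):
            if fraction > 0:
                _check_profile(name, profile)
        for name, mapping, fraction, letters in (
            ("dna", self.dna_nucleotides, self.dna, "GCAT"),
            ("rna", self.rna_nucleotides, self.rna, "GCAU"),
        ):
            if fraction > 0 and sorted(mapping) != sorted(letters):
                raise CompositionError(
                    f"{name}_nucleotides must map exactly the letters {letters}"
                )

    def nucleotide_mole_fractions(self, kind: str) -> Dict[str, float]:
        """Mole fraction per nucleotide letter implied by the G+C content."""
        gc, at = self.gc_content / 2.0, (1.0 - self.gc_content) / 2.0
        if kind == "dna":
            return {"G": gc, "C": gc, "A": at, "T": at}
        if kind == "rna":
            return {"G": gc, "C": gc, "A": at, "U": at}
        raise ValueError(kind)


def build_biomass_reaction(
    composition: BiomassComposition,
    monomer_weights: Mapping[str, float],
    reaction_id: str = "BIOMASS",
    gam: Optional[float] = DEFAULT_GAM,
    gam_metabolites: Optional[Tuple[str, str]] = None,
    residue_weights: bool = True,
) -> Reaction:
    """Build the biomass reaction (coefficients in mmol/gDCW, negative =
    consumed) so that total drained monomer mass is 1 g/gDCW within 1 %.

    *monomer_weights* maps metabolite id to free-monomer weight in g/mmol;
    with *residue_weights* one water mass is subtracted per polymerised
    monomer (protein and nucleic acids).  *gam_metabolites* is an
    (ATP, ADP) id pair for the maintenance term; GAM mass is not part of
    the 1 g closure (it is energy, not matter incorporated).
    """
    composition.validate()
    stoich: Dict[str, float] = {}

    def weight(met_id: str, polymerised: bool) -> float:
        if met_id not in monomer_weights:
            raise CompositionError(f"no monomer weight for metabolite {met_id!r}")
        w = float(monomer_weights[met_id])
        if polymerised and residue_weights:
            w -= WATER_MW
        if w <= 0:
            raise CompositionError(f"non-positive residue weight for {met_id!r}")
        return w

    def add(met_id: str, mmol: float) -> None:
        stoich[met_id] = stoich.get(met_id, 0.0) - mmol

    # mass-profiled classes: mmol_i = fraction * p_i / w_i
    for profile, fraction, polymerised in (
        (composition.protein_profile, composition.protein, True),
        (composition.lipid_profile, composition.lipid, False),
        (composition.carbohydrate_profile, composition.carbohydrate, False),
        (composition.mineral_profile, composition.ash, False),
    ):
        if fraction <= 0:
            continue
        for met_id, p in profile.items():
            add(met_id, fraction * p / weight(met_id, polymerised))

    # nucleic acids: mole fractions from GC, scaled to the class mass
    for kind, mapping, fraction in (
        ("dna", composition.dna_nucleotides, composition.dna),
        ("rna", composition.rna_nucleotides, composition.rna),
    ):
        if fraction <= 0:
            continue
        moles = composition.nucleotide_mole_fractions(kind)
        mean_w = sum(moles[ltr] * weight(met, True) for ltr, met in mapping.items())
        for ltr, met in mapping.items():
            add(met, fraction * moles[ltr] / mean_w)

    drained = -sum(
        coef * (monomer_weights[met] - (WATER_MW if residue_weights and _is_polymer(met, composition) else 0.0))
        for met, coef in stoich.items()
    )
    if abs(drained - (1.0 - 0.0)) > _MASS_TOL:
        raise CompositionError(
            f"biomass mass closure failed: {drained:.4f} g/gDCW drained, expected 1"
        )

    if gam and gam_metabolites is not None:
        atp, adp = gam_metabolites
        stoich[atp] = stoich.get(atp, 0.0) - float(gam)
        stoich[adp] = stoich.get(adp, 0.0) + float(gam)

    return Reaction(
        id=reaction_id,
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        subsystem="biomass",
        name="biomass assembly",
    )


def _is_polymer(met_id: str, composition: BiomassComposition) -> bool:
    return (
        met_id in composition.protein_profile
        or met_id in composition.dna_nucleotides.values()
        or met_id in composition.rna_nucleotides.values()
    )
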
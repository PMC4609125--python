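"""Single-gene deletion screening across media.

A gene deletion disables every reaction whose GPR rule evaluates to inactive
under the knockout (``and`` = complex, so losing any subunit kills the
reaction; ``or`` = isozymes, so one surviving gene keeps it alive); disabled
reactions get bounds (0, 0).  For each gene and medium the growth ratio
(deleted growth / wild-type growth) is computed by FBA and classified:

* **essential**: ratio < ``essential_threshold`` (default 0.01),
* **partially essential**: ratio < ``partial_threshold`` (default 0.5),
* **non-essential**: otherwise.

The thresholds are configuration, not biology: growth-ratio cutoffs for the
three classes are a modelling convention and should be tuned when matching a
particular study's counts.  Per-subsystem attribution counts a gene toward
every subsystem containing a reaction its deletion disables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import pandas as pd

from .fba_core import InfeasibleError, solve_fba
from .media import Medium, apply_medium
from .model import MetabolicModel

__all__ = [
    "ESSENTIAL_THRESHOLD",
    "PARTIAL_THRESHOLD",
    "EssentialityResult",
    "delete_gene",
    "disabled_reactions",
    "essentiality_screen",
]

ESSENTIAL_THRESHOLD = 0.01
PARTIAL_THRESHOLD = 0.5


def disabled_reactions(model: MetabolicModel, genes: Iterable[str]) -> List[str]:
    """Reactions whose GPR becomes inactive when *genes* are knocked out."""
    knocked = set(genes)
    unknown = knocked - set(model.genes)
    if unknown:
        raise KeyError(f"unknown genes: {sorted(unknown)}")
    out = []
    for rxn in model.reactions:
        if rxn.gpr is not None and not rxn.gpr.is_empty and not rxn.gpr.evaluate(knocked):
            out.append(rxn.id)
    return out


def delete_gene(model: MetabolicModel, gene: str) -> MetabolicModel:
    """Return a copy of *model* with *gene* knocked out (disabled reactions
    bounded to zero; everything else untouched)."""
    dead = set(disabled_reactions(model, [gene]))
    out = model.copy()
    for rxn in out.reactions:
        if rxn.id in dead:
            rxn.lower_bound = rxn.upper_bound = 0.0
    return out


def classify(ratio: float, essential_threshold: float, partial_threshold: float) -> str:
    if ratio < essential_threshold:
        return "essential"
    if ratio < partial_threshold:
        return "partially_essential"
    return "non_essential"


@dataclass
class EssentialityResult:
    records: pd.DataFrame  # columns: gene, medium, growth_ratio, class, subsystems
    wild_type_growth: Dict[str, float]
    essential_threshold: float
    partial_threshold: float

    def essential_in(self, medium: str) -> Set[str]:
        df = self.records
        sel = df[(df["medium"] == medium) & (df["class"] == "essential")]
        return set(sel["gene"])

    def essential_in_all(self) -> Set[str]:
        media = list(self.records["medium"].unique())
        out = self.essential_in(media[0])
        for name in media[1:]:
            out &= self.essential_in(name)
        return out

    def essential_only_in(self, medium: str) -> Set[str]:
        out = self.essential_in(medium)
        for name in self.records["medium"].unique():
            if name != medium:
                out -= self.essential_in(name)
        return out

    def summary(self) -> Dict[str, object]:
        media = list(self.records["medium"].unique())
        return {
            "media": media,
            "essential_in_all": len(self.essential_in_all()),
            **{f"essential_only_in_{m}": len(self.essential_only_in(m)) for m in media},
        }

    def subsystem_percentages(self, medium: str) -> pd.DataFrame:
        """Share of essential genes among the genes attributed to each
        subsystem, for one medium."""
        df = self.records[self.records["medium"] == medium]
        rows = []
        per_sub: Dict[str, Tuple[int, int]] = {}
        for _, rec in df.iterrows():
            subs = [s for s in rec["subsystems"].split(";") if s]
            for sub in set(subs):
                total, ess = per_sub.get(sub, (0, 0))
                per_sub[sub] = (total + 1, ess + (rec["class"] == "essential"))
        for sub, (total, ess) in sorted(per_sub.items()):
            rows.append(
                {"subsystem": sub, "genes": total, "essential": ess,
                 "percent_essential": 100.0 * ess / total}
            )
        return pd.DataFrame(rows)


def essentiality_screen(
    model: MetabolicModel,
    media: Mapping[str, Medium],
    essential_threshold: float = ESSENTIAL_THRESHOLD,
    partial_threshold: float = PARTIAL_THRESHOLD,
    genes: Optional[Iterable[str]] = None,
) -> EssentialityResult:
    """Delete each gene in turn in every medium and classify.

    Aborts with :class:`InfeasibleError` if the wild type does not grow in
    some medium (a screen against a dead wild type is meaningless).
    """
    gene_list = list(genes) if genes is not None else list(model.genes)
    rows = []
    wild: Dict[str, float] = {}
    subsystems = {r.id: r.subsystem for r in model.reactions}
    for name, medium in media.items():
        conditioned = apply_medium(model, medium)
        wt = solve_fba(conditioned)
        if not wt.optimal or wt.objective_value <= 1e-9:
            raise InfeasibleError(
                f"wild type does not grow in medium {name!r} "
                f"(status {wt.status}, growth {wt.objective_value!r})"
            )
        wild[name] = wt.objective_value
        for gene in gene_list:
            dead = disabled_reactions(conditioned, [gene])
            if not dead:
                ratio = 1.0
            else:
                knockout = conditioned.copy()
                for rid in dead:
                    rxn = knockout.reaction(rid)
                    rxn.lower_bound = rxn.upper_bound = 0.0
                sol = solve_fba(knockout)
                growth = sol.objective_value if sol.optimal else 0.0
                ratio = max(growth, 0.0) / wt.objective_value
            rows.append(
                {
                    "gene": gene,
                    "medium": name,
                    "growth_ratio": ratio,
                    "class": classify(ratio, essential_threshold, partial_threshold),
                    "subsystems": ";".join(sorted({subsystems[rid] for rid in dead})),
                }
            )
    return EssentialityResult(
        records=pd.DataFrame(rows),
        wild_type_growth=wild,
        essential_threshold=essential_threshold,
        partial_threshold=partial_threshold,
    )
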
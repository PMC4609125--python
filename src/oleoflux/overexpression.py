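"""In silico single-reaction overexpression screening scored by f_PH.

The screen asks which enzyme amplifications push extra flux into a product
(here DHA) without collapsing growth.  Five steps:

1. impose a product floor: the DHA exchange lower bound is set to
   ``dha_floor`` (default 0.01 mmol/gDW/h), above the negligible wild-type
   secretion at the growth optimum;
2. compute the wild-type reference flux distribution on the given medium
   (parsimonious FBA maximising biomass, a deterministic representative of
   the degenerate optimum);
3. for each internal biochemical reaction carrying flux, amplify: force
   ``|v| >= amplification x |v_ref|`` in the reference direction (default
   two-fold).  ``mode="pin"`` instead pins the flux to exactly the amplified
   value;
4. re-solve the perturbed model by MOMA against the reference — the
   metabolic state a cell overexpressing that one enzyme would relax to;
5. keep targets with DHA production above the floor and

       f_PH = f_biomass x f_DHA
            = (v_biomass,over / v_biomass,wild) x (v_DHA,over / v_DHA,wild) > 1.

The wild-type DHA denominator is the floored reference value (the floor is
imposed before the reference solve).  Exchange reactions and the biomass
reaction are never amplified; transport reactions are excluded by default.
Reactions whose amplification is MOMA-infeasible (the forced flux cannot be
carried) are skipped and listed in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .fba_core import InfeasibleError, parsimonious_fba
from .media import Medium, apply_medium
from .model import MetabolicModel
from .moma import solve_moma

__all__ = ["OverexpressionHit", "ScreenResult", "compute_fph", "overexpression_screen"]

_ACTIVE_TOL = 1e-6


@dataclass
class OverexpressionHit:
    reaction_id: str
    gene_ids: List[str]
    v_biomass_over: float
    v_dha_over: float
    f_biomass: float
    f_dha: float
    f_ph: float


@dataclass
class ScreenResult:
    hits: List[OverexpressionHit]
    all_results: pd.DataFrame
    skipped: List[str]  # MOMA-infeasible amplifications
    v_biomass_wild: float
    v_dha_wild: float

    def hit_genes(self) -> Set[str]:
        out: Set[str] = set()
        for h in self.hits:
            out |= set(h.gene_ids)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "reaction": h.reaction_id,
                    "genes": ";".join(h.gene_ids),
                    "v_biomass": h.v_biomass_over,
                    "v_dha": h.v_dha_over,
                    "f_biomass": h.f_biomass,
                    "f_dha": h.f_dha,
                    "f_ph": h.f_ph,
                }
                for h in self.hits
            ]
        )


def compute_fph(
    v_biomass_over: float,
    v_biomass_wild: float,
    v_dha_over: float,
    v_dha_wild: float,
) -> Tuple[float, float, float]:
    """Return (f_biomass, f_dha, f_ph) for one amplification outcome."""
    if v_biomass_wild <= 0 or v_dha_wild <= 0:
        raise ValueError(
            "wild-type biomass and DHA fluxes must be positive; the screen "
            "uses the floored wild-type DHA value as denominator"
        )
    f_biomass = v_biomass_over / v_biomass_wild
    f_dha = v_dha_over / v_dha_wild
    return f_biomass, f_dha, f_biomass * f_dha


def overexpression_screen(
    model: MetabolicModel,
    medium: Medium,
    dha_floor: float = 0.01,
    amplification: float = 2.0,
    mode: str = "lb",
    include_transport: bool = False,
    reactions: Optional[Sequence[str]] = None,
) -> ScreenResult:
    """Run the five-step screen; hits come back sorted by descending f_PH.

    ``mode="lb"`` forces at-least-amplified flux in the reference direction
    (raising the opposing bound only if the amplified value exceeds it);
    ``mode="pin"`` fixes the flux to exactly the amplified value.
    """
    if mode not in ("lb", "pin"):
        raise ValueError("mode must be 'lb' or 'pin'")
    if model.objective_id is None or model.dha_exchange_id is None:
        raise ValueError("model must designate both biomass and DHA exchange reactions")

    work = apply_medium(model, medium)
    dha_rxn = work.reaction(model.dha_exchange_id)
    dha_rxn.lower_bound = max(dha_rxn.lower_bound, dha_floor)

    reference = parsimonious_fba(work)
    if not reference.optimal:
        raise InfeasibleError(
            f"model infeasible with DHA floor {dha_floor} in medium {medium.name!r}"
        )
    v_biomass_wild = reference.fluxes[model.objective_id]
    v_dha_wild = reference.fluxes[model.dha_exchange_id]

    if reactions is not None:
        pool = [work.reaction(rid) for rid in reactions]
    else:
        pool = []
        for rxn in work.reactions:
            if work.is_exchange(rxn) or rxn.id == model.objective_id:
                continue
            if not include_transport and work.is_transport(rxn):
                continue
            pool.append(rxn)

    rows = []
    hits: List[OverexpressionHit] = []
    skipped: List[str] = []
    for rxn in pool:
        v_ref = reference.fluxes[rxn.id]
        if abs(v_ref) <= _ACTIVE_TOL:
            continue
        target = amplification * v_ref
        perturbed = work.copy()
        p = perturbed.reaction(rxn.id)
        if mode == "pin":
            p.lower_bound = p.upper_bound = target
        elif v_ref > 0:
            p.lower_bound = target
            p.upper_bound = max(p.upper_bound, target)
        else:
            p.upper_bound = target
            p.lower_bound = min(p.lower_bound, target)
        sol = solve_moma(perturbed, reference)
        if not sol.optimal:
            skipped.append(rxn.id)
            continue
        v_bio = sol.fluxes[model.objective_id]
        v_dha = sol.fluxes[model.dha_exchange_id]
        f_bio, f_dha, f_ph = compute_fph(v_bio, v_biomass_wild, v_dha, v_dha_wild)
        rows.append(
            {
                "reaction": rxn.id,
                "v_biomass": v_bio,
                "v_dha": v_dha,
                "f_biomass": f_bio,
                "f_dha": f_dha,
                "f_ph": f_ph,
                "moma_distance": sol.distance,
            }
        )
        if v_dha > dha_floor and f_ph > 1.0:
            hits.append(
                OverexpressionHit(
                    reaction_id=rxn.id,
                    gene_ids=sorted(rxn.gene_ids()),
                    v_biomass_over=v_bio,
                    v_dha_over=v_dha,
                    f_biomass=f_bio,
                    f_dha=f_dha,
                    f_ph=f_ph,
                )
            )
    hits.sort(key=lambda h: (-h.f_ph, h.reaction_id))
    return ScreenResult(
        hits=hits,
        all_results=pd.DataFrame(
            rows,
            columns=["reaction", "v_biomass", "v_dha", "f_biomass", "f_dha", "f_ph", "moma_distance"],
        ),
        skipped=skipped,
        v_biomass_wild=v_biomass_wild,
        v_dha_wild=v_dha_wild,
    )
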
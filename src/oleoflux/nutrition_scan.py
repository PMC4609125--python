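"""Nutrient-utilisation testing, gap checking, supplementation scans and
cofactor flux accounting.

*Source utilisation* asks whether the network can grow when a single carbon
(or nitrogen) source replaces the default one — a standard reconstruction
sanity check against phenotype panels.  A negative call against a positive
phenotype points at a network gap; :func:`check_gap_candidates` searches a
candidate reaction pool for a minimal-cardinality subset whose addition
restores growth.

*Supplementation scans* quantify how opening an extra uptake (malate,
citrate, single amino acids) changes the optimum of a production target at a
held growth demand.  Production is computed lexicographically: maximise
biomass, hold it at ``fraction`` of the baseline optimum, then maximise the
production flux.  By default the growth floor computed for the *baseline*
medium is reused for every supplemented condition, so each supplement purely
relaxes the LP and production can never decrease; re-fixing growth at each
condition's own optimum is available via ``refix_biomass=True``.

*Cofactor accounting* splits a steady-state flux vector into producers and
consumers of one metabolite (e.g. NADPH, acetyl-CoA): per-reaction rate =
stoichiometric coefficient x flux, and the totals balance by construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .fba_core import (
    FluxDistribution,
    InfeasibleError,
    lexicographic_max,
    solve_fba,
)
from .media import FREE_BOUND, Medium, apply_medium
from .model import MetabolicModel, Reaction

__all__ = [
    "GROWTH_EPSILON",
    "SourceUtilizationRow",
    "SupplementResult",
    "CofactorReport",
    "test_sources",
    "check_gap_candidates",
    "supplement_scan",
    "cofactor_flux_report",
]

GROWTH_EPSILON = 1e-6
_FLUX_EPS = 1e-6


@dataclass
class SourceUtilizationRow:
    source_id: str
    role: str  # carbon | nitrogen
    grows: bool
    growth_rate: Optional[float]
    testable: bool = True


@dataclass
class SupplementResult:
    supplement_id: str
    uptake_bound: float
    baseline_production: float
    supplemented_production: float
    percent_change: float
    growth_change: float


@dataclass
class CofactorReport:
    cofactor_id: str
    rates: pd.DataFrame  # columns: reaction, coefficient, flux, rate
    total_production: float
    total_consumption: float

    @property
    def n_active_reactions(self) -> int:
        """Reactions involving the cofactor that carry non-zero flux."""
        return int((self.rates["flux"].abs() > _FLUX_EPS).sum())


def test_sources(
    model: MetabolicModel,
    base_medium: Medium,
    sources: Sequence[Tuple[str, str, float]],
    growth_epsilon: float = GROWTH_EPSILON,
) -> List[SourceUtilizationRow]:
    """Open each (exchange id, role, uptake bound) source in turn on top of
    *base_medium* and record whether the model grows.

    The caller supplies a base medium with the default carbon (for carbon
    tests) or nitrogen (for nitrogen tests) exchange already closed — see
    :meth:`Medium.without`.  A missing exchange flags the row untestable and
    the scan continues.
    """
    rxn_ids = {r.id for r in model.reactions}
    rows: List[SourceUtilizationRow] = []
    for exchange_id, role, bound in sources:
        if exchange_id not in rxn_ids:
            rows.append(SourceUtilizationRow(exchange_id, role, False, None, testable=False))
            continue
        medium = base_medium.with_bound(exchange_id, -abs(bound), FREE_BOUND)
        sol = solve_fba(apply_medium(model, medium))
        growth = sol.objective_value if sol.optimal else 0.0
        rows.append(
            SourceUtilizationRow(exchange_id, role, growth > growth_epsilon, growth)
        )
    return rows


def _grows_on(model: MetabolicModel, medium: Medium, growth_epsilon: float) -> bool:
    sol = solve_fba(apply_medium(model, medium))
    return sol.optimal and sol.objective_value > growth_epsilon


def check_gap_candidates(
    model: MetabolicModel,
    candidates: Sequence[Reaction],
    source: Tuple[str, str, float],
    base_medium: Medium,
    max_set_size: int = 3,
    growth_epsilon: float = GROWTH_EPSILON,
) -> List[str]:
    """Find a minimal-cardinality subset of *candidates* that lets the model
    grow on *source* (an (exchange id, role, uptake bound) triple).

    Subsets are tried in order of increasing size up to *max_set_size*; the
    first enabling subset is returned (empty list = no fix within the cap).
    Raises if the model already grows — there is nothing to fill.
    """
    exchange_id, _role, bound = source
    medium = base_medium.with_bound(exchange_id, -abs(bound), FREE_BOUND)
    if _grows_on(model, medium, growth_epsilon):
        raise ValueError(
            f"model already grows on {exchange_id}; no gap to fill"
        )
    for size in range(1, min(max_set_size, len(candidates)) + 1):
        for subset in itertools.combinations(candidates, size):
            trial = model.copy()
            for rxn in subset:
                new = rxn.copy()
                # candidate reactions may introduce new metabolites
                known = {m.id for m in trial.metabolites}
                for met_id in new.stoichiometry:
                    if met_id not in known:
                        raise ValueError(
                            f"candidate {new.id!r} references unknown metabolite {met_id!r}; "
                            "add it to the model first"
                        )
                trial.reactions.append(new)
                trial.genes = sorted(set(trial.genes) | new.gene_ids())
            if _grows_on(trial, medium, growth_epsilon):
                return [r.id for r in subset]
    return []


def supplement_scan(
    model: MetabolicModel,
    base_medium: Medium,
    supplements: Sequence[Tuple[str, float]],
    production_target: Optional[str] = None,
    fraction: float = 1.0,
    refix_biomass: bool = False,
) -> List[SupplementResult]:
    """Effect of each extra uptake on the production optimum.

    *supplements* are (exchange id, uptake bound) pairs; *production_target*
    defaults to the model's DHA exchange.  Percent change is computed on
    production fluxes: (supplemented - baseline)/baseline x 100.
    """
    target = production_target or model.dha_exchange_id
    if target is None:
        raise ValueError("no production target: set production_target or dha_exchange_id")
    biomass = model.objective_id
    if biomass is None:
        raise ValueError("model has no objective (biomass) reaction")

    base = apply_medium(model, base_medium)
    base_growth, base_prod, _ = lexicographic_max(base, biomass, target, fraction)
    if base_prod <= 0:
        raise InfeasibleError(
            f"baseline production of {target} is {base_prod!r}; "
            "percent changes are undefined (lower the growth fraction)"
        )
    growth_floor = fraction * base_growth

    results: List[SupplementResult] = []
    for supplement_id, bound in supplements:
        medium = base_medium.with_bound(supplement_id, -abs(bound), FREE_BOUND)
        work = apply_medium(model, medium)
        growth_opt = solve_fba(work, biomass).objective_value
        if refix_biomass:
            floor = fraction * growth_opt
        else:
            floor = growth_floor
        pinned = work.copy()
        rxn = pinned.reaction(biomass)
        rxn.lower_bound = max(rxn.lower_bound, floor)
        prod = solve_fba(pinned, target)
        if not prod.optimal:
            raise InfeasibleError(f"supplemented problem infeasible for {supplement_id}")
        results.append(
            SupplementResult(
                supplement_id=supplement_id,
                uptake_bound=float(bound),
                baseline_production=base_prod,
                supplemented_production=prod.objective_value,
                percent_change=100.0 * (prod.objective_value - base_prod) / base_prod,
                growth_change=growth_opt - base_growth,
            )
        )
    return results


def cofactor_flux_report(
    model: MetabolicModel,
    flux: FluxDistribution,
    cofactor_id: str,
) -> CofactorReport:
    """Per-reaction production/consumption rates of one metabolite under a
    steady-state flux vector; totals balance to numerical tolerance."""
    if cofactor_id not in {m.id for m in model.metabolites}:
        raise KeyError(f"no metabolite {cofactor_id!r} in model")
    rows = []
    for rxn in model.reactions:
        coef = rxn.stoichiometry.get(cofactor_id)
        if coef is None:
            continue
        v = flux.fluxes.get(rxn.id, 0.0)
        rows.append(
            {"reaction": rxn.id, "coefficient": coef, "flux": v, "rate": coef * v}
        )
    df = pd.DataFrame(rows, columns=["reaction", "coefficient", "flux", "rate"])
    production = float(df.loc[df["rate"] > 0, "rate"].sum()) if len(df) else 0.0
    consumption = float(-df.loc[df["rate"] < 0, "rate"].sum()) if len(df) else 0.0
    return CofactorReport(cofactor_id, df, production, consumption)
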
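"""Flux balance analysis under the pseudo-steady-state constraint S·v = 0.

FBA is the linear program

    max (or min)  c'v   s.t.   S v = 0,   lb <= v <= ub

with c selecting the objective reaction (typically biomass, whose flux is the
specific growth rate in /h).  Solved with scipy's HiGHS backend.  Every
optimal solution is audited post hoc: ``||S v||_inf <= AUDIT_TOL`` and all
bounds respected to the same tolerance, so a silently inconsistent solver
answer cannot propagate.

Because LP optima are typically degenerate in genome-scale networks, a
parsimonious variant (:func:`parsimonious_fba`) is provided: it fixes the
objective at its optimum and minimises total absolute flux, yielding a
deterministic representative flux vector — the convention used wherever a
single reference distribution is needed downstream (MOMA references,
cofactor accounting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .media import Medium, apply_medium
from .model import MetabolicModel

__all__ = [
    "FluxDistribution",
    "RobustnessCurve",
    "RobustnessSurface",
    "SolverAuditError",
    "InfeasibleError",
    "solve_fba",
    "parsimonious_fba",
    "flux_variability",
    "robustness_scan",
    "robustness_surface",
    "lexicographic_max",
    "AUDIT_TOL",
]

#: post-solve audit threshold on steady state and bound violations
AUDIT_TOL = 1e-6
#: numeric slack below which a flux counts as zero
ZERO_TOL = 1e-6


class SolverAuditError(RuntimeError):
    """An 'optimal' LP solution failed the steady-state/bounds audit."""


class InfeasibleError(RuntimeError):
    """Raised by operations that require a feasible optimum."""


@dataclass
class FluxDistribution:
    fluxes: Dict[str, float]
    objective_value: float
    objective_id: Optional[str]
    status: str  # optimal | infeasible | unbounded | error

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


@dataclass
class RobustnessCurve:
    parameter_id: str
    grid: List[float]
    responses: List[Optional[float]]  # None marks an infeasible point


@dataclass
class RobustnessSurface:
    parameter_ids: Tuple[str, str]
    grids: Tuple[List[float], List[float]]
    values: np.ndarray  # shape (len(grid1), len(grid2)); NaN = infeasible


_STATUS = {0: "optimal", 1: "error", 2: "infeasible", 3: "unbounded", 4: "error"}


def _lp_arrays(model: MetabolicModel):
    S, met_ids, rxn_ids = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    return S, rxn_ids, lb, ub


def _audit(model: MetabolicModel, v: np.ndarray, lb: np.ndarray, ub: np.ndarray, S) -> None:
    residual = np.abs(S @ v).max() if S.shape[0] else 0.0
    if residual > AUDIT_TOL:
        raise SolverAuditError(f"steady-state residual {residual:.3e} > {AUDIT_TOL}")
    if (v < lb - AUDIT_TOL).any() or (v > ub + AUDIT_TOL).any():
        worst = max(np.max(lb - v), np.max(v - ub))
        raise SolverAuditError(f"bound violation {worst:.3e} > {AUDIT_TOL}")


def solve_fba(
    model: MetabolicModel,
    objective_id: Optional[str] = None,
    sense: str = "max",
) -> FluxDistribution:
    """Solve the FBA linear program; never silent about infeasibility."""
    objective_id = objective_id or model.objective_id
    if objective_id is None:
        raise ValueError("no objective reaction specified")
    S, rxn_ids, lb, ub = _lp_arrays(model)
    j = rxn_ids.index(objective_id)
    c = np.zeros(len(rxn_ids))
    c[j] = -1.0 if sense == "max" else 1.0
    res = linprog(
        c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=list(zip(lb, ub)), method="highs"
    )
    status = _STATUS.get(res.status, "error")
    if status != "optimal":
        return FluxDistribution({}, float("nan"), objective_id, status)
    v = np.asarray(res.x)
    _audit(model, v, lb, ub, S)
    return FluxDistribution(dict(zip(rxn_ids, v.tolist())), float(v[j]), objective_id, "optimal")


def parsimonious_fba(
    model: MetabolicModel,
    objective_id: Optional[str] = None,
    sense: str = "max",
) -> FluxDistribution:
    """Two-stage FBA: optimise the objective, then minimise total |v| with the
    objective pinned at its optimum.  Returns the minimum-total-flux vector
    with ``objective_value`` set to the stage-1 optimum."""
    objective_id = objective_id or model.objective_id
    first = solve_fba(model, objective_id, sense)
    if not first.optimal:
        return first
    S, rxn_ids, lb, ub = _lp_arrays(model)
    n = len(rxn_ids)
    j = rxn_ids.index(objective_id)

    # variables [v; t], minimise sum(t) with -t <= v <= t
    c = np.concatenate([np.zeros(n), np.ones(n)])
    pin = sparse.csr_matrix(([1.0], ([0], [j])), shape=(1, n))
    A_eq = sparse.hstack([sparse.vstack([S, pin]), sparse.csr_matrix((S.shape[0] + 1, n))])
    b_eq = np.concatenate([np.zeros(S.shape[0]), [first.objective_value]])
    eye = sparse.identity(n, format="csr")
    A_ub = sparse.vstack(
        [sparse.hstack([eye, -eye]), sparse.hstack([-eye, -eye])]
    )
    b_ub = np.zeros(2 * n)
    big = float(np.abs(np.concatenate([lb, ub])).max()) + 1.0
    bounds = list(zip(lb, ub)) + [(0.0, big)] * n
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if _STATUS.get(res.status, "error") != "optimal":
        # the pinned problem is feasible by construction; tiny numerical slack
        # can still break it, in which case the plain optimum is returned
        return first
    v = np.asarray(res.x[:n])
    _audit(model, v, lb, ub, S)
    return FluxDistribution(dict(zip(rxn_ids, v.tolist())), first.objective_value, objective_id, "optimal")


def flux_variability(
    model: MetabolicModel,
    medium: Optional[Medium] = None,
    objective_fraction: float = 1.0,
    objective_id: Optional[str] = None,
    reactions: Optional[Sequence[str]] = None,
) -> Dict[str, Tuple[float, float]]:
    """Per-reaction (min, max) flux subject to objective >= fraction * optimum."""
    work = apply_medium(model, medium) if medium is not None else model
    objective_id = objective_id or work.objective_id
    base = solve_fba(work, objective_id)
    if not base.optimal:
        raise InfeasibleError(f"FVA: no FBA optimum ({base.status})")
    S, rxn_ids, lb, ub = _lp_arrays(work)
    j = rxn_ids.index(objective_id)
    floor = objective_fraction * base.objective_value
    A_ub = sparse.csr_matrix(([-1.0], ([0], [j])), shape=(1, len(rxn_ids)))
    b_ub = np.array([-floor])
    targets = list(reactions) if reactions is not None else rxn_ids
    out: Dict[str, Tuple[float, float]] = {}
    for rid in targets:
        k = rxn_ids.index(rid)
        span = []
        for sign in (1.0, -1.0):
            c = np.zeros(len(rxn_ids))
            c[k] = sign
            res = linprog(
                c, A_ub=A_ub, b_ub=b_ub, A_eq=S, b_eq=np.zeros(S.shape[0]),
                bounds=list(zip(lb, ub)), method="highs",
            )
            if _STATUS.get(res.status, "error") != "optimal":
                raise InfeasibleError(f"FVA infeasible for {rid} at fraction {objective_fraction}")
            span.append(float(res.x[k]))
        lo, hi = min(span), max(span)
        out[rid] = (lo, hi)
    return out


def _fix(model: MetabolicModel, rxn_id: str, value: float) -> None:
    rxn = model.reaction(rxn_id)
    rxn.lower_bound = rxn.upper_bound = float(value)


def robustness_scan(
    model: MetabolicModel,
    medium: Optional[Medium],
    parameter_id: str,
    grid: Sequence[float],
    objective_id: Optional[str] = None,
    sense: str = "max",
) -> RobustnessCurve:
    """Objective response as one reaction's flux is fixed (LB = UB) across a
    grid.  Infeasible points are recorded as None and the scan continues."""
    work = apply_medium(model, medium) if medium is not None else model.copy()
    work.reaction(parameter_id)  # raises KeyError early if absent
    responses: List[Optional[float]] = []
    for value in grid:
        point = work.copy()
        _fix(point, parameter_id, value)
        sol = solve_fba(point, objective_id, sense)
        responses.append(sol.objective_value if sol.optimal else None)
    return RobustnessCurve(parameter_id, [float(g) for g in grid], responses)


def robustness_surface(
    model: MetabolicModel,
    medium: Optional[Medium],
    parameter_ids: Tuple[str, str],
    grids: Tuple[Sequence[float], Sequence[float]],
    objective_id: Optional[str] = None,
    sense: str = "max",
) -> RobustnessSurface:
    """2D variant: both parameter fluxes fixed at each grid-point pair."""
    work = apply_medium(model, medium) if medium is not None else model.copy()
    p1, p2 = parameter_ids
    g1 = [float(g) for g in grids[0]]
    g2 = [float(g) for g in grids[1]]
    values = np.full((len(g1), len(g2)), np.nan)
    for i, v1 in enumerate(g1):
        for k, v2 in enumerate(g2):
            point = work.copy()
            _fix(point, p1, v1)
            _fix(point, p2, v2)
            sol = solve_fba(point, objective_id, sense)
            if sol.optimal:
                values[i, k] = sol.objective_value
    return RobustnessSurface((p1, p2), (g1, g2), values)


def lexicographic_max(
    model: MetabolicModel,
    primary_id: str,
    secondary_id: str,
    fraction: float = 1.0,
) -> Tuple[float, float, FluxDistribution]:
    """Maximise *primary*, fix it at ``fraction`` of its optimum (as a floor),
    then maximise *secondary*.  Returns (primary optimum, secondary optimum,
    the stage-2 flux distribution).

    This is the production-capacity convention: e.g. growth first, then
    product secretion with the growth demand held.
    """
    first = solve_fba(model, primary_id)
    if not first.optimal:
        raise InfeasibleError(f"lexicographic: primary objective {first.status}")
    work = model.copy()
    rxn = work.reaction(primary_id)
    floor = fraction * first.objective_value
    rxn.lower_bound = max(rxn.lower_bound, floor)
    second = solve_fba(work, secondary_id)
    if not second.optimal:
        raise InfeasibleError(f"lexicographic: secondary objective {second.status}")
    return first.objective_value, second.objective_value, second
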
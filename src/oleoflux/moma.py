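"""Minimization of Metabolic Adjustment (MOMA).

After a perturbation (gene deletion, forced overexpression), MOMA assumes the
cell does not instantly re-optimise growth but instead operates at the
feasible flux state closest — in Euclidean distance — to its pre-perturbation
distribution:

    min  sum_i (v_i - v_ref,i)^2   s.t.   S v = 0,   lb' <= v <= ub'

a strictly convex quadratic program whose optimum is the projection of the
reference onto the perturbed flux polytope.  The objective is unweighted (all
reactions count equally) and the reference is not normalised.

The QP is solved with a primal active-set method written for this box-plus-
equality structure (the Hessian is the identity, so each subproblem is a
linear KKT solve and the iteration terminates finitely).  If the active-set
loop fails to converge on a degenerate instance, a scipy ``trust-constr``
solve is used as a fallback; both paths are subject to the same post-solve
steady-state and bounds audit.  The optimal *distance* is unique even when
the minimiser is not (strict convexity in v).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Union

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, minimize

from .fba_core import AUDIT_TOL, FluxDistribution, SolverAuditError
from .model import MetabolicModel

__all__ = ["MomaSolution", "solve_moma", "ZERO_DISTANCE_TOL"]

#: distances below this are reported as exactly zero (reference feasible)
ZERO_DISTANCE_TOL = 1e-6

_FEAS_TOL = 1e-9


@dataclass
class MomaSolution:
    fluxes: Dict[str, float]
    distance: float
    status: str  # optimal | infeasible | error

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _feasible_point(S, lb, ub):
    res = linprog(
        np.zeros(len(lb)), A_eq=S, b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)), method="highs",
    )
    if res.status != 0:
        return None
    return np.asarray(res.x)


def _box_eq_qp(Sd: np.ndarray, lb: np.ndarray, ub: np.ndarray, r: np.ndarray,
               v0: np.ndarray, max_iter: int) -> Optional[np.ndarray]:
    """Primal active-set solve of min 1/2||v - r||^2 s.t. Sd v = 0, lb<=v<=ub.

    Returns the minimiser, or None if the loop did not converge.
    """
    n = len(r)
    v = v0.copy()
    fixed = np.isclose(lb, ub, rtol=0.0, atol=0.0)
    # working set: index -> 'lb' | 'ub' | 'eq'
    work: Dict[int, str] = {i: "eq" for i in np.where(fixed)[0]}
    for i in range(n):
        if i in work:
            continue
        if v[i] <= lb[i] + _FEAS_TOL:
            work[i] = "lb"
        elif v[i] >= ub[i] - _FEAS_TOL:
            work[i] = "ub"

    m = Sd.shape[0]
    for _ in range(max_iter):
        idx = sorted(work)
        bw = np.array([lb[i] if work[i] in ("lb", "eq") else ub[i] for i in idx])
        k = len(idx)
        # KKT in (lambda, mu):  [S S', S E'; E S', I][lam; mu] = [S r; E r - bw]
        SE = Sd[:, idx] if k else np.zeros((m, 0))
        top = np.hstack([Sd @ Sd.T, SE])
        bot = np.hstack([SE.T, np.eye(k)])
        K = np.vstack([top, bot]) if k else top
        rhs = np.concatenate([Sd @ r, r[idx] - bw]) if k else Sd @ r
        sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
        lam, mu = sol[:m], sol[m:]
        v_new = r - Sd.T @ lam
        if k:
            v_new[idx] -= mu
        # lstsq can mask rank trouble; verify the subproblem constraints hold
        if np.abs(Sd @ v_new).max(initial=0.0) > 1e-7:
            return None
        if k and np.abs(v_new[idx] - bw).max() > 1e-7:
            return None

        p = v_new - v
        if np.abs(p).max(initial=0.0) < 1e-10:
            grad = v - r + Sd.T @ lam
            worst_i, worst_v = None, -1e-9
            for i, side in work.items():
                if side == "eq":
                    continue
                viol = -grad[i] if side == "lb" else grad[i]
                if viol > max(worst_v, 1e-9):
                    worst_i, worst_v = i, viol
            if worst_i is None:
                return v
            del work[worst_i]
            continue

        # ratio test against bounds not in the working set
        alpha, block, side = 1.0, None, None
        for i in range(n):
            if i in work or abs(p[i]) < 1e-13:
                continue
            if p[i] > 0 and v[i] + alpha * p[i] > ub[i]:
                a = (ub[i] - v[i]) / p[i]
                if a < alpha:
                    alpha, block, side = a, i, "ub"
            elif p[i] < 0 and v[i] + alpha * p[i] < lb[i]:
                a = (lb[i] - v[i]) / p[i]
                if a < alpha:
                    alpha, block, side = a, i, "lb"
        v = v + max(alpha, 0.0) * p
        if block is not None:
            v[block] = lb[block] if side == "lb" else ub[block]
            work[block] = side
    return None


def _fallback_qp(Sd, lb, ub, r, v0):
    n = len(r)

    def fun(v):
        d = v - r
        return 0.5 * float(d @ d)

    res = minimize(
        fun, v0, jac=lambda v: v - r, hess=lambda v: np.eye(n),
        method="trust-constr",
        constraints=[LinearConstraint(Sd, 0.0, 0.0)],
        bounds=Bounds(lb, ub),
        options={"gtol": 1e-12, "xtol": 1e-12, "maxiter": 2000, "verbose": 0},
    )
    return np.asarray(res.x)


def solve_moma(
    perturbed: MetabolicModel,
    reference: Union[FluxDistribution, Mapping[str, float]],
) -> MomaSolution:
    """Project *reference* onto the flux polytope of *perturbed*.

    Reference fluxes for reactions absent from the reference are taken as 0.
    An infeasible perturbed model (empty polytope) is reported as status
    ``infeasible`` — the signature of a lethal perturbation.
    """
    ref_map = reference.fluxes if isinstance(reference, FluxDistribution) else dict(reference)
    S, met_ids, rxn_ids = perturbed.stoichiometric_matrix()
    lb, ub = perturbed.bounds_arrays()
    r = np.array([float(ref_map.get(rid, 0.0)) for rid in rxn_ids])

    v0 = _feasible_point(S, lb, ub)
    if v0 is None:
        return MomaSolution({}, float("nan"), "infeasible")

    Sd = S.toarray()
    n = len(rxn_ids)
    v = _box_eq_qp(Sd, lb, ub, r, v0, max_iter=100 + 10 * n)
    if v is None:
        v = _fallback_qp(Sd, lb, ub, r, v0)

    residual = np.abs(Sd @ v).max(initial=0.0)
    if residual > AUDIT_TOL:
        raise SolverAuditError(f"MOMA steady-state residual {residual:.3e}")
    if (v < lb - AUDIT_TOL).any() or (v > ub + AUDIT_TOL).any():
        raise SolverAuditError("MOMA bound violation above tolerance")

    distance = float(np.linalg.norm(v - r))
    if distance < ZERO_DISTANCE_TOL:
        distance = 0.0
    return MomaSolution(dict(zip(rxn_ids, v.tolist())), distance, "optimal")
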
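"""Independent oracles used by the test suite.

Each oracle deliberately avoids the code path it checks: LP optima by
brute-force basic-solution enumeration, GPR rules via Python's own boolean
evaluator, MOMA via a generic dense NLP solve, and FBA cross-checked against
cobrapy (GLPK backend).
"""

from __future__ import annotations

import itertools
import re
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np


def gpr_truth_oracle(rule: str, knocked: Set[str]) -> bool:
    """Evaluate a GPR rule with Python's eval as an independent referee."""
    def repl(m: re.Match) -> str:
        tok = m.group(0)
        if tok.lower() in ("and", "or"):
            return tok.lower()
        return "False" if tok in knocked else "True"

    expr = re.sub(r"[^\s()]+", repl, rule)
    return bool(eval(expr))  # noqa: S307 - controlled test input


def enumerate_lp_optimum(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    c: np.ndarray,
    sense: str = "max",
    tol: float = 1e-9,
) -> Optional[float]:
    """Brute-force LP optimum over basic feasible solutions.

    Fixes every choice of (n - rank S) variables at one of their bounds,
    solves the remaining square system, keeps feasible points, and returns
    the best objective (None if nothing feasible).  Exponential — only for
    micro instances.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S) if S.size else 0
    n_fix = n - rank
    best = None
    for fixed in itertools.combinations(range(n), n_fix):
        free = [j for j in range(n) if j not in fixed]
        for sides in itertools.product((0, 1), repeat=n_fix):
            x = np.zeros(n)
            for j, s in zip(fixed, sides):
                x[j] = lb[j] if s == 0 else ub[j]
            if free:
                A = S[:, free]
                b = -S[:, fixed] @ x[list(fixed)] if fixed else np.zeros(S.shape[0])
                sol, *_ = np.linalg.lstsq(A, b, rcond=None)
                x[free] = sol
            if np.abs(S @ x).max(initial=0.0) > 1e-7:
                continue
            if (x < lb - tol).any() or (x > ub + tol).any():
                continue
            val = float(c @ x)
            if best is None:
                best = val
            elif sense == "max":
                best = max(best, val)
            else:
                best = min(best, val)
    return best


def dense_qp_oracle(
    S: np.ndarray, lb: np.ndarray, ub: np.ndarray, r: np.ndarray
) -> Tuple[np.ndarray, float]:
    """Independent solve of the MOMA projection with OSQP (a first-order
    ADMM QP solver, a different algorithm family from the package's
    active-set method), at high accuracy with polishing."""
    import osqp
    from scipy import sparse

    n = len(r)
    m = S.shape[0]
    P = sparse.identity(n, format="csc")
    A = sparse.vstack([sparse.csc_matrix(S), sparse.identity(n)], format="csc")
    low = np.concatenate([np.zeros(m), lb])
    high = np.concatenate([np.zeros(m), ub])
    prob = osqp.OSQP()
    prob.setup(P, -np.asarray(r, dtype=float), A, low, high,
               eps_abs=1e-10, eps_rel=1e-10, max_iter=200000,
               polish=True, verbose=False)
    res = prob.solve()
    assert "solved" in res.info.status, f"oracle QP status: {res.info.status}"
    v = np.asarray(res.x)
    return v, float(np.linalg.norm(v - r))


def to_cobra(model):
    """Convert a MetabolicModel to a cobrapy model (GLPK cross-check)."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {
        m.id: cobra.Metabolite(m.id, name=m.name, compartment=m.compartment)
        for m in model.metabolites
    }
    reactions = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        reactions.append(cr)
    cm.add_reactions(reactions)
    for r in model.reactions:
        cr = cm.reactions.get_by_id(r.id)
        cr.add_metabolites({mets[mid]: coef for mid, coef in r.stoichiometry.items()})
        if r.gpr is not None and not r.gpr.is_empty:
            cr.gene_reaction_rule = r.gpr.to_string()
    if model.objective_id is not None:
        cm.objective = model.objective_id
    return cm


def cobra_optimum(model, objective_id: Optional[str] = None) -> Optional[float]:
    cm = to_cobra(model)
    if objective_id is not None:
        cm.objective = objective_id
    value = cm.slim_optimize(error_value=None)
    return None if value is None else float(value)
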
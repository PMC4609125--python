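import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oleoflux.fba_core import (
    AUDIT_TOL,
    InfeasibleError,
    flux_variability,
    lexicographic_max,
    parsimonious_fba,
    robustness_scan,
    robustness_surface,
    solve_fba,
)
from oleoflux.media import apply_medium

from ._oracles import cobra_optimum, enumerate_lp_optimum


def _arrays(model):
    S, _mets, rxn_ids = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    return S.toarray(), rxn_ids, lb, ub


@pytest.mark.parametrize("sense", ["max", "min"])
def test_fba_matches_vertex_enumeration(micro_model, sense):
    """HiGHS optimum equals the brute-force optimum over basic feasible
    solutions on micro networks."""
    S, rxn_ids, lb, ub = _arrays(micro_model)
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(micro_model.objective_id)] = 1.0
    expected = enumerate_lp_optimum(S, lb, ub, c, sense)
    sol = solve_fba(micro_model, sense=sense)
    assert sol.optimal
    assert sol.objective_value == pytest.approx(expected, abs=1e-8)


def test_micro_chain_optimum_frozen_value(micro_model):
    # chain/parallel saturate uptake at 10; the lossy variant halves 8 -> 4
    expected = {"micro_chain": 10.0, "micro_parallel": 10.0, "micro_lossy": 4.0}
    sol = solve_fba(micro_model)
    assert sol.objective_value == pytest.approx(expected[micro_model.id], abs=1e-9)


@pytest.mark.parametrize("medium", ["MG_glucose", "MG_glycerol", "YE"])
def test_growth_agrees_with_independent_solver_backend(toy_model, toy_media, medium):
    """Same optimum from scipy/HiGHS and cobrapy/GLPK on the toy model."""
    conditioned = apply_medium(toy_model, toy_media[medium])
    ours = solve_fba(conditioned)
    theirs = cobra_optimum(conditioned)
    assert ours.optimal and theirs is not None
    assert ours.objective_value == pytest.approx(theirs, abs=1e-6)


def test_no_uptake_means_no_growth(toy_model):
    closed = toy_model.copy()
    for rxn in closed.exchange_reactions():
        rxn.lower_bound = 0.0
    assert solve_fba(closed).objective_value == pytest.approx(0.0, abs=1e-9)


def test_infeasible_status_is_explicit(toy_model, toy_media):
    broken = apply_medium(toy_model, toy_media["MG_glucose"])
    broken.reaction("BIOMASS").lower_bound = 1e6  # unreachable demand
    broken.reaction("BIOMASS").upper_bound = 1e6 + 1
    sol = solve_fba(broken)
    assert sol.status == "infeasible"
    assert sol.fluxes == {}


def test_optimum_passes_steady_state_and_bounds_audit(toy_model, toy_media):
    conditioned = apply_medium(toy_model, toy_media["YE"])
    for solver in (solve_fba, parsimonious_fba):
        sol = solver(conditioned)
        S, rxn_ids, lb, ub = _arrays(conditioned)
        v = np.array([sol.fluxes[r] for r in rxn_ids])
        assert np.abs(S @ v).max() <= AUDIT_TOL
        assert (v >= lb - AUDIT_TOL).all() and (v <= ub + AUDIT_TOL).all()


def test_parsimonious_keeps_the_optimum_and_shrinks_flux(toy_model, toy_media):
    conditioned = apply_medium(toy_model, toy_media["MG_glucose"])
    plain = solve_fba(conditioned)
    pfba = parsimonious_fba(conditioned)
    assert pfba.objective_value == pytest.approx(plain.objective_value, abs=1e-9)
    total = sum(abs(v) for v in pfba.fluxes.values())
    total_plain = sum(abs(v) for v in plain.fluxes.values())
    assert total <= total_plain + 1e-6


@settings(max_examples=20, deadline=None, derandomize=True)
@given(extra=st.lists(st.floats(0.0, 5.0), min_size=1, max_size=3),
       which=st.lists(st.sampled_from(["EX_glc", "EX_nh3", "EX_mal", "EX_cit"]),
                      min_size=1, max_size=3))
def test_relaxing_uptake_never_reduces_growth(toy, extra, which):
    """Opening any uptake lower bound enlarges the feasible set, so the
    growth optimum is monotone non-decreasing."""
    model, media, _ = toy
    base = apply_medium(model, media["MG_glucose"])
    before = solve_fba(base).objective_value
    relaxed = base.copy()
    for rid, amount in zip(which, extra):
        rxn = relaxed.reaction(rid)
        rxn.lower_bound -= amount
    after = solve_fba(relaxed).objective_value
    assert after >= before - 1e-9


# ---------------------------------------------------------------------------
# FVA
# ---------------------------------------------------------------------------

def test_fva_blocked_reaction_is_zero(toy_model, toy_media):
    spans = flux_variability(toy_model, toy_media["MG_glucose"], 0.0,
                             reactions=["EX_xyl"])
    lo, hi = spans["EX_xyl"]
    assert lo == pytest.approx(0.0, abs=1e-9) and hi == pytest.approx(0.0, abs=1e-9)


def test_fva_objective_pinned_at_fraction_one(toy_model, toy_media):
    spans = flux_variability(toy_model, toy_media["MG_glucose"], 1.0,
                             reactions=["BIOMASS"])
    lo, hi = spans["BIOMASS"]
    opt = solve_fba(apply_medium(toy_model, toy_media["MG_glucose"])).objective_value
    assert lo == pytest.approx(opt, abs=1e-6) and hi == pytest.approx(opt, abs=1e-6)


def test_fva_parallel_paths_match_enumeration_oracle():
    from .conftest import micro_parallel

    micro_model = micro_parallel()
    spans = flux_variability(micro_model, None, 1.0, reactions=["P1", "P2"])
    # optimum 10 with per-route capacity 6: each route spans [4, 6]
    S, rxn_ids, lb, ub = _arrays(micro_model)
    pinned_lb, pinned_ub = lb.copy(), ub.copy()
    j = rxn_ids.index("EX_b")
    pinned_lb[j] = pinned_ub[j] = 10.0
    for rid in ("P1", "P2"):
        c = np.zeros(len(rxn_ids)); c[rxn_ids.index(rid)] = 1.0
        lo = enumerate_lp_optimum(S, pinned_lb, pinned_ub, c, "min")
        hi = enumerate_lp_optimum(S, pinned_lb, pinned_ub, c, "max")
        assert spans[rid][0] == pytest.approx(lo, abs=1e-8)
        assert spans[rid][1] == pytest.approx(hi, abs=1e-8)
    assert spans["P1"] == (pytest.approx(4.0, abs=1e-8), pytest.approx(6.0, abs=1e-8))


def test_fva_infeasible_fraction_raises(toy_model, toy_media):
    # demanding 150 % of the optimum empties the feasible set
    with pytest.raises(InfeasibleError):
        flux_variability(toy_model, toy_media["MG_glucose"], 1.5,
                         reactions=["EX_glc"])


# ---------------------------------------------------------------------------
# Robustness scans
# ---------------------------------------------------------------------------

def test_scan_over_unused_exchange(toy_model, toy_media):
    """A metabolite nothing consumes pins its exchange flux to zero: the
    scan is flat at zero (= the unconstrained optimum) and every forced
    nonzero uptake is recorded infeasible in place."""
    baseline = solve_fba(apply_medium(toy_model, toy_media["MG_glucose"]))
    curve = robustness_scan(toy_model, toy_media["MG_glucose"], "EX_h2o",
                            [-3.0, -2.0, -1.0, 0.0])
    assert curve.responses[:3] == [None, None, None]
    assert curve.responses[3] == pytest.approx(baseline.objective_value, abs=1e-9)


def test_growth_vs_glucose_uptake_piecewise_linear_non_decreasing(toy_model, toy_media):
    """Growth against fixed glucose uptake: matches independent per-point
    solves and is non-decreasing up to saturation."""
    grid = [-v for v in (0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.4)]
    curve = robustness_scan(toy_model, toy_media["MG_glucose"], "EX_glc", grid)
    for value, response in zip(curve.grid, curve.responses):
        point = apply_medium(toy_model, toy_media["MG_glucose"])
        rxn = point.reaction("EX_glc")
        rxn.lower_bound = rxn.upper_bound = value
        oracle = cobra_optimum(point)
        assert response == pytest.approx(oracle, abs=1e-6)
    growth = curve.responses
    assert all(b >= a - 1e-9 for a, b in zip(growth, growth[1:]))


def test_robustness_records_infeasible_points_in_place(toy_model, toy_media):
    # forcing huge glucose uptake with nothing to absorb it is infeasible
    curve = robustness_scan(toy_model, toy_media["MG_glucose"], "EX_glc",
                            [-1.0, -1e5])
    assert curve.responses[0] is not None
    assert curve.responses[1] is None


def test_2d_surface_shape_and_feasible_core(toy_model, toy_media):
    surface = robustness_surface(
        toy_model, toy_media["MG_glucose"],
        ("EX_glc", "EX_o2"),
        ([-0.5, -1.0], [-1.0, -2.0, -4.0]),
    )
    assert surface.values.shape == (2, 3)
    assert np.isfinite(surface.values).any()


def test_lexicographic_production(toy_model, toy_media, toy_manifest):
    conditioned = apply_medium(toy_model, toy_media["MG_glucose"])
    growth, dha, fd = lexicographic_max(conditioned, "BIOMASS", "EX_dha",
                                        toy_manifest["production_fraction"])
    assert growth == pytest.approx(toy_manifest["growth"]["MG_glucose"], abs=1e-6)
    assert dha == pytest.approx(toy_manifest["dha"]["wild_MG_glucose"], rel=1e-6)
    assert fd.fluxes["BIOMASS"] >= toy_manifest["production_fraction"] * growth - 1e-9
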
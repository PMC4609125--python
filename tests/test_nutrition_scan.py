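import itertools

import numpy as np
import pytest

from oleoflux.fba_core import parsimonious_fba, solve_fba
from oleoflux.media import apply_medium
from oleoflux.nutrition_scan import (
    check_gap_candidates,
    cofactor_flux_report,
    supplement_scan,
)
from oleoflux.nutrition_scan import test_sources as run_source_tests
from oleoflux.synthetic_data import ToySpec, candidate_reactions, generate_toy_model


@pytest.fixture(scope="module")
def gapped_pair():
    return generate_toy_model(ToySpec(seed=5, include_gaps=2))


@pytest.fixture(scope="module")
def gapped_single():
    return generate_toy_model(ToySpec(seed=4, include_gaps=1))


# ---------------------------------------------------------------------------
# Source utilisation
# ---------------------------------------------------------------------------

def test_sole_carbon_sources(toy_model, toy_media):
    base = toy_media["MG_glucose"].without(["EX_glc"])
    rows = run_source_tests(
        toy_model, base,
        [("EX_glc", "carbon", 1.4), ("EX_glyc", "carbon", 1.6),
         ("EX_xyl", "carbon", 10.0), ("EX_missing", "carbon", 1.0)],
    )
    by_id = {r.source_id: r for r in rows}
    assert by_id["EX_glc"].grows and by_id["EX_glyc"].grows
    assert not by_id["EX_xyl"].grows  # dead-end sugar: no catabolic route
    assert not by_id["EX_missing"].testable  # scan continues past missing ids


def test_sole_nitrogen_source(toy_model, toy_media):
    base = toy_media["MG_glucose"].without(["EX_nh3"])
    rows = run_source_tests(toy_model, base, [("EX_nh3", "nitrogen", 10.0)])
    assert rows[0].grows
    # without any nitrogen the biomass amino-acid demand is unmeetable
    no_n = run_source_tests(toy_model, base, [("EX_h2o", "nitrogen", 10.0)])
    assert not no_n[0].grows


# ---------------------------------------------------------------------------
# Gap filling
# ---------------------------------------------------------------------------

def test_singleton_gap_fix(gapped_single):
    model, media, manifest = gapped_single
    gap = manifest["gap"]
    base = media["MG_glucose"].without(["EX_glc"])
    fix = check_gap_candidates(
        model, candidate_reactions(manifest),
        (gap["source_exchange"], "carbon", gap["uptake"]), base,
    )
    assert fix == gap["minimal_fix"] and len(fix) == 1


def test_two_reaction_gap_needs_exactly_the_pair(gapped_pair):
    model, media, manifest = gapped_pair
    gap = manifest["gap"]
    base = media["MG_glucose"].without(["EX_glc"])
    candidates = candidate_reactions(manifest)
    source = (gap["source_exchange"], "carbon", gap["uptake"])
    fix = check_gap_candidates(model, candidates, source, base)
    assert sorted(fix) == sorted(gap["minimal_fix"]) and len(fix) == 2
    # exhaustive minimality: no strict subset of the pair restores growth
    for subset in itertools.combinations(candidates, 1):
        trial = model.copy()
        trial.reactions.append(subset[0].copy())
        trial.genes = sorted(set(trial.genes) | subset[0].gene_ids())
        medium = base.with_bound(gap["source_exchange"], -gap["uptake"])
        assert solve_fba(apply_medium(trial, medium)).objective_value < 1e-9


def test_empty_candidate_list_returns_empty(gapped_pair):
    model, media, manifest = gapped_pair
    gap = manifest["gap"]
    base = media["MG_glucose"].without(["EX_glc"])
    n_before = len(model.reactions)
    fix = check_gap_candidates(model, [], (gap["source_exchange"], "carbon", 1.0), base)
    assert fix == []
    assert len(model.reactions) == n_before  # model unchanged


def test_gap_check_refuses_growing_model(toy_model, toy_media):
    base = toy_media["MG_glucose"]
    with pytest.raises(ValueError, match="already grows"):
        check_gap_candidates(toy_model, [], ("EX_glc", "carbon", 1.4), base)


# ---------------------------------------------------------------------------
# Supplementation
# ---------------------------------------------------------------------------

def test_malate_relieves_nadph_bottleneck(toy_model, toy_media, toy_manifest):
    frac = toy_manifest["production_fraction"]
    res = supplement_scan(toy_model, toy_media["YE"], [("EX_mal", 1.0)],
                          "EX_dha", frac)
    assert res[0].percent_change > 0.0
    assert res[0].percent_change == pytest.approx(
        toy_manifest["dha"]["malate_gain_pct"], rel=1e-6
    )


def test_zero_bound_supplement_changes_nothing(toy_model, toy_media, toy_manifest):
    res = supplement_scan(toy_model, toy_media["YE"], [("EX_mal", 0.0)],
                          "EX_dha", toy_manifest["production_fraction"])
    assert res[0].percent_change == pytest.approx(0.0, abs=1e-6)


def test_supplementation_is_monotone(toy_model, toy_media, toy_manifest):
    """Opening any uptake relaxes the production LP: percent change >= 0."""
    # only exchanges absent from the base medium: re-listing an existing
    # nutrient at a smaller bound would be a restriction, not a supplement
    supplements = [(f"EX_{sp}", 1.0) for sp in
                   ("mal", "cit", "ac", "glyc", "ala", "cys", "xyl")]
    res = supplement_scan(toy_model, toy_media["MG_glucose"], supplements,
                          "EX_dha", toy_manifest["production_fraction"])
    for row in res:
        assert row.percent_change >= -1e-6
    # percent-change arithmetic holds row by row
    for row in res:
        expect = 100.0 * (row.supplemented_production - row.baseline_production) / row.baseline_production
        assert row.percent_change == pytest.approx(expect, abs=1e-9)


def test_citrate_relieves_accoa_bottleneck(toy_accoa):
    model, media, manifest = toy_accoa
    res = supplement_scan(model, media["YE"], [("EX_cit", 1.0)], "EX_dha",
                          manifest["production_fraction"])
    assert res[0].percent_change == pytest.approx(
        manifest["dha"]["citrate_gain_pct"], rel=1e-6
    )


# ---------------------------------------------------------------------------
# Cofactor accounting
# ---------------------------------------------------------------------------

def test_nadph_report_balances_and_names_sources(toy_model, toy_media):
    conditioned = apply_medium(toy_model, toy_media["YE"])
    flux = parsimonious_fba(conditioned)
    report = cofactor_flux_report(conditioned, flux, "nadph_c")
    assert report.total_production == pytest.approx(report.total_consumption, abs=1e-6)
    producers = set(report.rates[report.rates["rate"] > 1e-9]["reaction"])
    assert producers <= {"G6PD", "PGD", "ME"}
    consumers = set(report.rates[report.rates["rate"] < -1e-9]["reaction"])
    assert consumers <= {"LIPS", "PKS"}
    assert report.n_active_reactions >= 3


def test_accoa_report_balances(toy_model, toy_media):
    conditioned = apply_medium(toy_model, toy_media["YE"])
    flux = parsimonious_fba(conditioned)
    report = cofactor_flux_report(conditioned, flux, "accoa_c")
    assert report.total_production == pytest.approx(report.total_consumption, abs=1e-6)


def test_zero_flux_vector_gives_all_zero_report(toy_model):
    from oleoflux.fba_core import FluxDistribution

    zero = FluxDistribution({r.id: 0.0 for r in toy_model.reactions}, 0.0, None, "optimal")
    report = cofactor_flux_report(toy_model, zero, "nadph_c")
    assert report.n_active_reactions == 0
    assert report.total_production == 0.0 == report.total_consumption


def test_absent_cofactor_raises(toy_model, toy_media):
    flux = parsimonious_fba(apply_medium(toy_model, toy_media["MG_glucose"]))
    with pytest.raises(KeyError):
        cofactor_flux_report(toy_model, flux, "nadph_x")
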
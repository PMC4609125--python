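import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oleoflux.model import (
    GPRParseError,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    models_equal,
    parse_gpr,
)
from oleoflux.model_io import (
    EquationParseError,
    format_equation,
    parse_equation,
    read_model,
    read_tabular,
    summarize_subsystems,
    write_model,
)
from oleoflux.synthetic_data import ToySpec, generate_toy_model

from ._oracles import gpr_truth_oracle


# ---------------------------------------------------------------------------
# GPR parsing and knockout semantics
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "rule,knocked,active",
    [
        ("A and B", {"A"}, False),          # complex loses a subunit
        ("A and B", set(), True),
        ("A or B", {"A"}, True),            # isozyme backup survives
        ("A or B", {"A", "B"}, False),
        ("(A and B) or (A and C)", {"B"}, True),
        ("(A and B) or (A and C)", {"A"}, False),
        ("", {"A"}, True),                  # empty rule is always active
    ],
)
def test_gpr_knockout_semantics(rule, knocked, active):
    assert parse_gpr(rule).evaluate(knocked) is active


@pytest.mark.parametrize("rule", ["(A and B", "A and", "and A", "A (B)", "A or or B"])
def test_gpr_malformed_rules_raise(rule):
    with pytest.raises(GPRParseError):
        parse_gpr(rule)


def _rule_strategy():
    genes = st.sampled_from(["A", "B", "C", "D"])
    return st.recursive(
        genes,
        lambda sub: st.tuples(sub, st.sampled_from(["and", "or"]), sub).map(
            lambda t: f"({t[0]} {t[1]} {t[2]})"
        ),
        max_leaves=6,
    )


@settings(max_examples=60, deadline=None, derandomize=True)
@given(rule=_rule_strategy())
def test_gpr_matches_truth_table_oracle(rule):
    """Parser agrees with an exhaustive eval-based truth table over every
    knockout subset of up to four genes."""
    gpr = parse_gpr(rule)
    genes = sorted(gpr.genes())
    for k in range(len(genes) + 1):
        for subset in itertools.combinations(genes, k):
            assert gpr.evaluate(set(subset)) == gpr_truth_oracle(rule, set(subset))


# ---------------------------------------------------------------------------
# Equations
# ---------------------------------------------------------------------------

def test_equation_round_trip_preserves_stoichiometry():
    stoich, comps = parse_equation("2 a_c[c] + b_e[e] => 0.5 c_c[c]", "R1")
    assert stoich == {"a_c": -2.0, "b_e": -1.0, "c_c": 0.5}
    assert comps == {"a_c": "c", "b_e": "e", "c_c": "c"}


def test_equation_error_names_the_reaction():
    with pytest.raises(EquationParseError, match="RBAD"):
        parse_equation("a_c[c] + => b_c[c]", "RBAD")
    with pytest.raises(EquationParseError, match="no reaction arrow"):
        parse_equation("a_c[c] + b_c[c]", "R2")


def test_unknown_metabolite_reference_fails_validation():
    model = MetabolicModel(
        metabolites=[Metabolite("a_c", compartment="c")],
        reactions=[Reaction("R", {"a_c": -1.0, "ghost": 1.0})],
    )
    with pytest.raises(ModelValidationError, match="ghost"):
        model.validate()


# ---------------------------------------------------------------------------
# Round trips
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("fmt", ["tabular", "sbml"])
def test_round_trip_identity(tmp_path, toy_model, fmt):
    path = tmp_path / ("m.tsv" if fmt == "tabular" else "m.xml")
    write_model(toy_model, path, format=fmt)
    back = read_model(path, format=fmt)
    assert models_equal(toy_model, back, check_names=True)


def test_cross_format_exports_agree(tmp_path, toy_model):
    write_model(toy_model, tmp_path / "m.tsv")
    write_model(toy_model, tmp_path / "m.xml")
    assert models_equal(read_model(tmp_path / "m.tsv"), read_model(tmp_path / "m.xml"))


@pytest.mark.parametrize("seed", [0, 3, 11])
def test_round_trip_over_generated_models(tmp_path, seed):
    model, _media, _man = generate_toy_model(
        ToySpec(seed=seed, include_gaps=seed % 3), verify=False
    )
    for fmt, name in (("tabular", f"{seed}.tsv"), ("sbml", f"{seed}.xml")):
        write_model(model, tmp_path / name, format=fmt)
        assert models_equal(model, read_model(tmp_path / name), check_names=True)


def test_reversible_bounds_preserved_exactly(tmp_path):
    model = MetabolicModel(
        metabolites=[Metabolite("a_e", compartment="e")],
        reactions=[Reaction("EX_a", {"a_e": -1.0}, -12.345, 67.89)],
    )
    write_model(model, tmp_path / "m.tsv")
    back = read_model(tmp_path / "m.tsv")
    assert back.reaction("EX_a").lower_bound == -12.345
    assert back.reaction("EX_a").upper_bound == 67.89
    assert back.reaction("EX_a").reversible


def test_tabular_column_mapping(tmp_path, toy_model):
    write_model(toy_model, tmp_path / "m.tsv")
    text = (tmp_path / "m.tsv").read_text().replace(
        "id\tname\tequation", "rxn\tlabel\tformula_str"
    )
    (tmp_path / "renamed.tsv").write_text(text)
    back = read_tabular(
        tmp_path / "renamed.tsv",
        column_map={"id": "rxn", "name": "label", "equation": "formula_str"},
    )
    assert models_equal(toy_model, back, check_names=True)


# ---------------------------------------------------------------------------
# Subsystems
# ---------------------------------------------------------------------------

def test_subsystem_percentages_sum_to_100(toy_model):
    df = summarize_subsystems(toy_model)
    assert abs(df["percent"].sum() - 100.0) < 0.1
    assert df["n_reactions"].sum() == len(toy_model.reactions)


def test_single_reaction_model_is_100_percent():
    model = MetabolicModel(
        metabolites=[Metabolite("a_e", compartment="e")],
        reactions=[Reaction("EX_a", {"a_e": -1.0}, subsystem="exchange reactions")],
    )
    df = summarize_subsystems(model)
    assert len(df) == 1 and df["percent"].iloc[0] == 100.0


def test_exchange_detection_by_structure(toy_model):
    ex = {r.id for r in toy_model.exchange_reactions()}
    assert "EX_glc" in ex and "EX_dha" in ex
    assert "DHAt" not in ex  # transport touches two compartments
    assert "BIOMASS" not in ex
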
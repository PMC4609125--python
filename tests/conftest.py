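import pytest

from oleoflux.model import MetabolicModel, Metabolite, Reaction
from oleoflux.synthetic_data import ToySpec, generate_toy_model


@pytest.fixture(scope="session")
def toy():
    """Default toy (NADPH-bottlenecked), with generation-time verification."""
    return generate_toy_model(ToySpec(seed=1))


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_media(toy):
    return toy[1]


@pytest.fixture(scope="session")
def toy_manifest(toy):
    return toy[2]


@pytest.fixture(scope="session")
def toy_accoa():
    """Acetyl-CoA-bottlenecked variant (PKS amplification is feasible here)."""
    return generate_toy_model(ToySpec(seed=2, bottleneck="accoa"))


@pytest.fixture(scope="session")
def toy_three_aa():
    """Three amino-acid pathways: exercises the partially-essential class."""
    return generate_toy_model(ToySpec(seed=7, n_amino_acid_pathways=3))


def micro_chain(cap: float = 10.0) -> MetabolicModel:
    """A -> B linear chain: uptake, conversion, secretion."""
    return MetabolicModel(
        id="micro_chain",
        metabolites=[Metabolite("a_e", compartment="e"), Metabolite("b_e", compartment="e")],
        reactions=[
            Reaction("EX_a", {"a_e": -1.0}, -cap, 1000.0),
            Reaction("CONV", {"a_e": -1.0, "b_e": 1.0}, 0.0, 1000.0),
            Reaction("EX_b", {"b_e": -1.0}, 0.0, 1000.0),
        ],
        objective_id="EX_b",
    )


def micro_parallel() -> MetabolicModel:
    """Two parallel routes with individual capacities feeding one product."""
    return MetabolicModel(
        id="micro_parallel",
        metabolites=[Metabolite("a_e", compartment="e"), Metabolite("b_e", compartment="e")],
        reactions=[
            Reaction("EX_a", {"a_e": -1.0}, -10.0, 1000.0),
            Reaction("P1", {"a_e": -1.0, "b_e": 1.0}, 0.0, 6.0),
            Reaction("P2", {"a_e": -1.0, "b_e": 1.0}, 0.0, 6.0),
            Reaction("EX_b", {"b_e": -1.0}, 0.0, 1000.0),
        ],
        objective_id="EX_b",
    )


def micro_lossy() -> MetabolicModel:
    """Conversion with 50 % carbon loss (non-unit stoichiometry)."""
    return MetabolicModel(
        id="micro_lossy",
        metabolites=[Metabolite("a_e", compartment="e"), Metabolite("b_e", compartment="e")],
        reactions=[
            Reaction("EX_a", {"a_e": -1.0}, -8.0, 1000.0),
            Reaction("CONV", {"a_e": -1.0, "b_e": 0.5}, 0.0, 1000.0),
            Reaction("EX_b", {"b_e": -1.0}, 0.0, 1000.0),
        ],
        objective_id="EX_b",
    )


@pytest.fixture(params=[micro_chain, micro_parallel, micro_lossy],
                ids=["chain", "parallel", "lossy"])
def micro_model(request):
    return request.param()
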
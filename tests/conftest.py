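import pytest

from ecmkit import (
    MetabolicModel,
    Metabolite,
    Reaction,
    build_toy_ec_model,
    make_toy_gem,
    parse_gpr,
)
from ecmkit.synthetic_data import ToySpec


@pytest.fixture(scope="session")
def toy_spec():
    return ToySpec()


@pytest.fixture(scope="session")
def toy(toy_spec):
    return make_toy_gem(toy_spec, seed=1)


@pytest.fixture(scope="session")
def closed_form(toy):
    return toy.closed_form


@pytest.fixture(scope="session")
def toy_ecm(toy, toy_spec):
    """Enzyme-constrained toy; treat as read-only (copy before mutating)."""
    return build_toy_ec_model(toy, toy_spec)


def make_chain_model(gpr_text: str = "", reversible_transport: bool = False):
    """Minimal substrate -> internal -> sink chain for structural tests."""
    lb = -1000.0 if reversible_transport else 0.0
    model = MetabolicModel(
        metabolites=[
            Metabolite("a_e", formula="C2H4O2", compartment="e"),
            Metabolite("a_c", formula="C2H4O2", compartment="c"),
        ],
        reactions=[
            Reaction("EX_a_e", {"a_e": -1.0}, -10.0, 1000.0),
            Reaction("T", {"a_e": -1.0, "a_c": 1.0}, lb, 1000.0,
                     gpr=parse_gpr(gpr_text)),
            Reaction("DM_a_c", {"a_c": -1.0}, 0.0, 1000.0),
        ],
        genes=sorted(parse_gpr(gpr_text).genes),
        objective_reaction_id="DM_a_c",
        id="chain",
    )
    model.validate()
    return model


@pytest.fixture
def chain_model():
    return make_chain_model("g1 or g2")


def cobra_fba_optimum(model, overrides=None) -> float:
    """Independent LP oracle: cobrapy FBA optimum on an ecmkit model."""
    from ecmkit.model_core import to_cobra

    cm = to_cobra(model)
    for rxn_id, value in (overrides or {}).items():
        rxn = cm.reactions.get_by_id(rxn_id)
        if isinstance(value, tuple):
            rxn.bounds = value
        else:
            rxn.lower_bound = value
    solution = cm.optimize()
    assert solution.status == "optimal"
    return float(solution.objective_value)
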
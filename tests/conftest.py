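import logging

import pytest

from lactoflux import (
    Medium,
    MetabolicModel,
    Metabolite,
    Reaction,
    build_community,
    make_milk_fixture,
)

logging.getLogger("lactoflux").setLevel(logging.ERROR)


def _toy(model_id: str, n_paths: int = 1) -> MetabolicModel:
    """Linear chain (or n parallel paths): exchange -> transport -> biomass,
    all unit coefficients. With uptake bound u the optimum is u."""
    model = MetabolicModel(id=model_id, compartments={"c", "e"})
    model.metabolites = [
        Metabolite(id="sub_e", compartment="e"),
        Metabolite(id="sub_c", compartment="c"),
    ]
    model.reactions.append(
        Reaction(id="EX_sub_e", stoichiometry={"sub_e": -1.0}, lower_bound=0.0,
                 upper_bound=1000.0, kind="exchange")
    )
    for i in range(n_paths):
        model.reactions.append(
            Reaction(id=f"T{i}", stoichiometry={"sub_e": -1.0, "sub_c": 1.0},
                     lower_bound=0.0, upper_bound=1000.0, kind="transport")
        )
    model.reactions.append(
        Reaction(id="BIO", stoichiometry={"sub_c": -1.0}, lower_bound=0.0,
                 upper_bound=1000.0, kind="biomass")
    )
    model.objective_reaction_id = "BIO"
    return model


@pytest.fixture
def chain_model():
    return _toy("chain")


@pytest.fixture
def parallel_model():
    return _toy("parallel", n_paths=2)


@pytest.fixture
def sub_medium():
    return Medium(uptake_bounds={"sub": 10.0}, name="sub10")


@pytest.fixture(scope="session")
def milk_trio():
    return make_milk_fixture()


@pytest.fixture(scope="session")
def milk_community(milk_trio):
    st, lr, milk = milk_trio
    return build_community(st, lr, milk)


def make_chain(model_id: str, n_paths: int = 1) -> MetabolicModel:
    return _toy(model_id, n_paths)
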
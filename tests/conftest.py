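import numpy as np
import pytest

from redgem import (
    MetabolicModel,
    Metabolite,
    Reaction,
    ToyNetworkConfig,
    generate_toy_network,
)


@pytest.fixture(scope="session")
def toy():
    """Default toy CA-production network with its ground truth."""
    return generate_toy_network()


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_truth(toy):
    return toy[1]


@pytest.fixture()
def chain_model():
    """Uptake-limited linear chain: EX_A (lb=-10) -> A -> B -> EX_B."""
    m = MetabolicModel(id="chain", objective_id="EX_B")
    m.add_metabolite(Metabolite(id="A_c"))
    m.add_metabolite(Metabolite(id="B_c"))
    m.add_reaction(Reaction(id="EX_A", stoichiometry={"A_c": -1},
                            lower_bound=-10, upper_bound=0, is_exchange=True))
    m.add_reaction(Reaction(id="AB", stoichiometry={"A_c": -1, "B_c": 1},
                            lower_bound=0, upper_bound=1000))
    m.add_reaction(Reaction(id="EX_B", stoichiometry={"B_c": -1},
                            lower_bound=0, upper_bound=1000, is_exchange=True))
    return m


def make_box_model(widths):
    """Product-of-intervals polytope: per axis an inflow bounded by the
    width and an unbounded outflow, so each inflow is uniform on [0, w]."""
    m = MetabolicModel(id="box", objective_id="")
    for i, w in enumerate(widths):
        m.add_metabolite(Metabolite(id=f"B{i}_c"))
        m.add_reaction(Reaction(id=f"IN_{i}", stoichiometry={f"B{i}_c": 1},
                                lower_bound=0, upper_bound=w))
        m.add_reaction(Reaction(id=f"EX_out{i}",
                                stoichiometry={f"B{i}_c": -1},
                                lower_bound=0, upper_bound=1000,
                                is_exchange=True))
    return m


@pytest.fixture()
def box_factory():
    return make_box_model


@pytest.fixture(scope="session")
def pinned_growth_model(toy_model):
    """Toy model with growth pinned at 30% of its maximum and succinate
    export capped: yields all three shadow-price classes."""
    from redgem import fba

    m = toy_model.copy()
    mu_max = fba(m, "BIOMASS").objective_value
    growth = m.reaction("BIOMASS")
    growth.lower_bound = growth.upper_bound = 0.3 * mu_max
    m.reaction("EX_succ").upper_bound = 1.0
    return m
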
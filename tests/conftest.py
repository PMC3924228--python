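import pytest

from ccrsim import build_fixture_network, split_reversible
from ccrsim.network import Metabolite, MetabolicNetwork, Reaction


@pytest.fixture(scope="session")
def fixture_net():
    return build_fixture_network()


@pytest.fixture(scope="session")
def split_net(fixture_net):
    return split_reversible(fixture_net)


@pytest.fixture(scope="session")
def fixture_caps(fixture_net):
    return {
        s: fixture_net.reaction(ex).upper_bound
        for s, ex in fixture_net.substrate_exchange_ids.items()
    }


@pytest.fixture
def two_substrate_toy():
    """Two parallel substrate→biomass chains: yields (1,1), a=(0.1,0.2), U=(5,5)."""
    mets = [
        Metabolite("s1_e", is_external=True),
        Metabolite("s2_e", is_external=True),
        Metabolite("s1"),
        Metabolite("s2"),
        Metabolite("b"),
    ]
    rxns = [
        Reaction("EX_1", {"s1_e": -1, "s1": 1}, 0, 5, 0, "exchange"),
        Reaction("EX_2", {"s2_e": -1, "s2": 1}, 0, 5, 0, "exchange"),
        Reaction("r1", {"s1": -1, "b": 1}, 0, 100, 0.1),
        Reaction("r2", {"s2": -1, "b": 1}, 0, 100, 0.2),
        Reaction("biomass", {"b": -1}, 0, 100, 0.0, "biomass"),
    ]
    return MetabolicNetwork(
        mets, rxns, "biomass", {"s1": "EX_1", "s2": "EX_2"}, None, 1.0
    )
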
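import pytest

from refnet.network_routing import (
    assign_catchments,
    build_network,
    build_route_catalog,
)
from refnet.synthetic_geography import ScenarioConfig, generate_scenario, table_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """The printed-table bundle (speed table, route catalog, zone rows,
    compliance table)."""
    return table_fixtures()


@pytest.fixture(scope="session")
def scenario():
    """A quarter-scale synthetic study area, seed 1."""
    return generate_scenario(ScenarioConfig(seed=1))


@pytest.fixture(scope="session")
def network(scenario):
    return build_network(
        scenario.villages, scenario.roads, constraints=scenario.constraints
    )


@pytest.fixture(scope="session")
def route_catalog(scenario, network):
    routes = build_route_catalog(network, scenario.hubs, scenario.facilities)
    assign_catchments(routes, scenario.villages, network)
    return routes
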
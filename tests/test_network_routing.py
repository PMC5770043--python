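"""Graph construction, deterministic shortest paths (against an exhaustive
oracle), route catalogues, catchment assignment and arrival estimates."""

import itertools
import random

import networkx as nx
import pytest
from shapely.geometry import LineString, Point, Polygon

from refnet.errors import UnreachableError
from refnet.geodata import (
    HealthFacility,
    Hub,
    RoadSegment,
    TransportMode as M,
    Village,
)
from refnet.network_routing import (
    TransportNetwork,
    assign_catchments,
    build_network,
    build_route_catalog,
    closest_hub,
    estimate_arrival,
    exclude_route,
    include_route,
    shortest_time_path,
)
from refnet.travel_time import SpeedTable


def _road(sid, coords, road_type="paved", width=8.0, fixed=()):
    return RoadSegment(
        sid, LineString(coords), road_type,
        width_ft=None if road_type == "waterway" else width,
        fixed_route_modes=frozenset(fixed),
    )


def _village(vid, cx, cy, pop=100, half=0.2):
    return Village(
        vid, vid,
        Polygon([(cx - half, cy - half), (cx + half, cy - half),
                 (cx + half, cy + half), (cx - half, cy + half)]),
        population=pop,
    )


class TestBuildNetwork:
    def test_shared_endpoint_gives_three_vertices_two_edges(self):
        net = build_network(
            [], [_road("a", [(0, 0), (1, 0)]), _road("b", [(1, 0), (1, 1)])]
        )
        assert net.graph.number_of_nodes() == 3
        assert net.graph.number_of_edges() == 2

    def test_crossing_roads_are_noded(self):
        net = build_network(
            [], [_road("a", [(0, 0), (2, 0)]), _road("b", [(1, -1), (1, 1)])]
        )
        # crossing splits both lines: 5 vertices, 4 edges
        assert net.graph.number_of_nodes() == 5
        assert net.graph.number_of_edges() == 4

    def test_village_connector_is_walking_time(self):
        net = build_network(
            [_village("v1", 0.0, 1.0)], [_road("a", [(0, 0), (3, 0)])]
        )
        vv = net.village_vertex["v1"]
        (rv,) = net.graph[vv]
        assert net.graph[vv][rv]["times"][M.WALK] == pytest.approx(15.0)

    def test_distant_village_raises_isolation_warning(self):
        with pytest.warns(match="v1"):
            net = build_network(
                [_village("v1", 0.0, 9.0)], [_road("a", [(0, 0), (1, 0)])],
                max_connector_km=5.0,
            )
        assert not list(net.graph[net.village_vertex["v1"]])

    def test_island_without_boats_is_unreachable(self, scenario):
        """Severing the waterways strands every island village."""
        net = build_network(
            scenario.villages, scenario.land_roads,
            constraints=scenario.constraints,
        )
        island = sorted(scenario.island_village_ids)[0]
        facility_vertex = net.nearest_vertex(scenario.facilities[0].location)
        with pytest.raises(UnreachableError):
            shortest_time_path(net, island, facility_vertex)


def _random_network(rng: random.Random, n: int) -> TransportNetwork:
    """A small abstract network with integer edge minutes (ties likely)."""
    g = nx.Graph()
    ids = [f"n{i}" for i in range(n)]
    g.add_nodes_from(ids)
    for u, v in itertools.combinations(range(n), 2):
        if rng.random() < 0.45:
            t = float(rng.randint(1, 4))
            g.add_edge(
                ids[u], ids[v], length_km=t / 10, road_type="paved",
                modes=(M.RICKSHAW,), times={M.RICKSHAW: t},
            )
    coords = {v: (i * 1.0, 0.0) for i, v in enumerate(ids)}
    return TransportNetwork(g, coords, {}, SpeedTable.default())


def _oracle(net: TransportNetwork, src: str, dst: str):
    """Exhaustive enumeration of all simple paths, same tie-break."""
    best = None
    for path in nx.all_simple_paths(net.graph, src, dst):
        t = sum(net.graph[u][v]["times"][M.RICKSHAW] for u, v in zip(path, path[1:]))
        key = (t, len(path) - 1, tuple(path))
        if best is None or key < best:
            best = key
    return best


class TestShortestPath:
    def test_matches_exhaustive_enumeration(self):
        rng = random.Random(7)
        compared = 0
        for _ in range(60):
            net = _random_network(rng, rng.randint(4, 9))
            nodes = sorted(net.graph.nodes)
            src, dst = rng.sample(nodes, 2)
            expected = _oracle(net, src, dst)
            if expected is None:
                with pytest.raises(UnreachableError):
                    shortest_time_path(net, src, dst)
                continue
            path, t, _d = shortest_time_path(net, src, dst)
            assert t == expected[0]
            assert tuple(path) == expected[2]
            compared += 1
        assert compared >= 30

    def test_origin_equals_destination(self):
        net = _random_network(random.Random(1), 5)
        v = sorted(net.graph.nodes)[0]
        assert shortest_time_path(net, v, v) == ([], 0.0, 0.0)

    def test_single_tempo_edge_reproduces_catalog_time(self):
        net = build_network(
            [], [_road("a", [(0, 0), (5.64, 0)], fixed={"tempo"})]
        )
        u = net.nearest_vertex(Point(0, 0))
        v = net.nearest_vertex(Point(5.64, 0))
        _path, t, d = shortest_time_path(net, u, v, ("single_mode", M.TEMPO))
        assert round(t, 2) == 26.77
        assert d == pytest.approx(5.64)

    def test_removing_an_edge_never_speeds_anything_up(self):
        rng = random.Random(11)
        for _ in range(20):
            net = _random_network(rng, 7)
            edges = sorted(net.graph.edges)
            if not edges:
                continue
            u0, v0 = edges[rng.randrange(len(edges))]
            nodes = sorted(net.graph.nodes)
            before = {}
            for a, b in itertools.combinations(nodes, 2):
                try:
                    before[(a, b)] = shortest_time_path(net, a, b)[1]
                except UnreachableError:
                    pass
            net.graph.remove_edge(u0, v0)
            for (a, b), t_before in before.items():
                try:
                    t_after = shortest_time_path(net, a, b)[1]
                except UnreachableError:
                    continue
                assert t_after >= t_before - 1e-12


class TestClosestHub:
    def _linear(self):
        roads = [_road("ab", [(0, 0), (2, 0)]), _road("bc", [(2, 0), (3.5, 0)])]
        village = _village("v1", 2.0, 0.0)
        net = build_network([village], roads)
        return net

    def test_nearer_sub_hub_beats_farther_hub(self):
        net = self._linear()
        hub = Hub("hA", Point(0, 0), kind="hub")
        sub = Hub("shC", Point(3.5, 0), kind="sub_hub")
        chosen, t = closest_hub(net, "v1", [hub, sub])
        assert chosen.hub_id == "shC"
        assert t == pytest.approx(60 * 1.5 / 8.05)

    def test_equal_times_prefer_full_hub(self):
        roads = [_road("ab", [(0, 0), (2, 0)]), _road("bc", [(2, 0), (4, 0)])]
        net = build_network([_village("v1", 2.0, 0.0)], roads)
        hub = Hub("hA", Point(0, 0), kind="hub")
        sub = Hub("shC", Point(4, 0), kind="sub_hub")
        chosen, _t = closest_hub(net, "v1", [hub, sub])
        assert chosen.hub_id == "hA"


class TestRouteCatalog:
    def test_one_hub_one_road_single_route(self):
        net = build_network([], [_road("a", [(0, 0), (5.64, 0)], fixed={"tempo"})])
        hub = Hub("h1", Point(0, 0), kind="hub", name="Market")
        fac = HealthFacility("f1", Point(5.64, 0), name="UHC")
        (route,) = build_route_catalog(net, [hub], [fac])
        assert route.distance_km == pytest.approx(5.64)
        assert round(route.time_min, 2) == 26.77
        assert route.mode_label == "Tempo"
        assert route.active

    def test_nasiman_only_corridor_is_catalogued_inactive(self):
        net = build_network(
            [], [_road("a", [(0, 0), (8.34, 0)], fixed={"nasiman"})],
            speed_table=SpeedTable.with_nasiman(),
        )
        hub = Hub("h1", Point(0, 0), kind="hub")
        fac = HealthFacility("f1", Point(8.34, 0))
        (route,) = build_route_catalog(net, [hub], [fac])
        assert route.uses_unsafe_mode
        assert not route.active
        assert round(route.time_min, 2) == round(60 * 8.34 / 12.63, 2)

    def test_scenario_routes_one_per_hub(self, scenario, route_catalog):
        n_anchor = sum(1 for h in scenario.hubs if h.kind == "hub")
        assert len(route_catalog) == n_anchor
        assert len({r.route_id for r in route_catalog}) == n_anchor

    def test_scenario_has_an_excluded_unsafe_route(self, route_catalog):
        inactive = [r for r in route_catalog if not r.active]
        assert len(inactive) == 1
        assert inactive[0].uses_unsafe_mode


class TestCatchments:
    @pytest.fixture()
    def fresh(self, scenario, network):
        routes = build_route_catalog(network, scenario.hubs, scenario.facilities)
        catchments = assign_catchments(routes, scenario.villages, network)
        return routes, catchments

    def test_active_catchments_partition_villages(self, scenario, fresh):
        routes, catchments = fresh
        sets = [r.catchment_village_ids for r in routes if r.active]
        union = set().union(*sets)
        assert sum(len(s) for s in sets) == len(union)
        assert union == set(catchments)
        assert union == {v.village_id for v in scenario.villages}

    def test_population_is_conserved(self, scenario, fresh):
        routes, _ = fresh
        assert sum(r.catchment_population for r in routes) == \
            scenario.total_population

    def test_inactive_routes_receive_no_villages(self, fresh):
        routes, _ = fresh
        assert all(not r.catchment_village_ids for r in routes if not r.active)

    def test_exclusion_reassigns_and_conserves(self, scenario, network, fresh):
        routes, before = fresh
        victim = next(r for r in routes if r.active and r.catchment_village_ids)
        moved = set(victim.catchment_village_ids)
        after = exclude_route(routes, victim.route_id, scenario.villages, network)
        assert not victim.active
        assert sum(r.catchment_population for r in routes) == \
            scenario.total_population
        assert all(after[v].route_id != victim.route_id for v in moved
                   if v in after)

    def test_exclude_then_include_restores_assignment(self, scenario, network, fresh):
        routes, before = fresh
        victim = next(r for r in routes if r.active and r.catchment_village_ids)
        exclude_route(routes, victim.route_id, scenario.villages, network)
        restored = include_route(routes, victim.route_id, scenario.villages, network)
        assert restored == before

    def test_excluding_empty_route_changes_nothing(self):
        # two corridors from one facility; the only village sits on corridor A,
        # so corridor B's route carries an empty catchment
        roads = [
            _road("a", [(0, 0), (-4, 0)], fixed={"tempo"}),
            _road("b", [(0, 0), (4, 0)], fixed={"tempo"}),
        ]
        village = _village("v1", -4.0, 0.0)
        net = build_network([village], roads)
        hubs = [Hub("hA", Point(-4, 0), kind="hub"),
                Hub("hB", Point(4, 0), kind="hub")]
        fac = HealthFacility("f1", Point(0, 0))
        routes = build_route_catalog(net, hubs, [fac])
        before = assign_catchments(routes, [village], net)
        empty = next(r for r in routes if not r.catchment_village_ids)
        after = exclude_route(routes, empty.route_id, [village], net)
        assert after == before
        assert sum(r.catchment_population for r in routes) == 100

    def test_manual_override_pins_village_to_route(self, scenario, network, fresh):
        routes, before = fresh
        vid = sorted(before)[0]
        other = next(r.route_id for r in routes
                     if r.active and r.route_id != before[vid].route_id)
        after = assign_catchments(
            routes, scenario.villages, network, manual_overrides={vid: other}
        )
        assert after[vid].route_id == other


class TestArrivalEstimates:
    def _setup(self):
        corridor = _road("cor", [(0, 0), (5.64, 0)], fixed={"tempo"})
        access = _road("acc", [(-1, 0), (0, 0)])
        at_hub = _village("v_hub", 0.0, 0.0, pop=300)
        away = _village("v_away", -1.0, 0.0, pop=700)
        net = build_network([at_hub, away], [corridor, access])
        hub = Hub("h1", Point(0, 0), kind="hub")
        fac = HealthFacility("f1", Point(5.64, 0))
        routes = build_route_catalog(net, [hub], [fac])
        catchments = assign_catchments(routes, [at_hub, away], net)
        return net, routes, catchments

    def test_village_at_hub_arrives_in_route_time(self):
        net, routes, catchments = self._setup()
        assert estimate_arrival(net, "v_hub", catchments, routes) == \
            pytest.approx(60 * 5.64 / 12.64)

    def test_access_leg_adds_rickshaw_time(self):
        net, routes, catchments = self._setup()
        expected = 60 * 1 / 8.05 + 60 * 5.64 / 12.64
        assert estimate_arrival(net, "v_away", catchments, routes) == \
            pytest.approx(expected)

    def test_catchment_population_sums_village_populations(self):
        _net, routes, _catchments = self._setup()
        assert routes[0].catchment_population == 1000
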
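"""Facility travel times, isochrone reach polygons, the 50%-coverage zone
rule, and the zone summary table."""

import pytest
from shapely.geometry import LineString, Point, Polygon, box

from refnet.errors import ConsistencyError, DegenerateGeometryError
from refnet.geodata import HealthFacility, RoadSegment, Village
from refnet.network_routing import build_network
from refnet.zoning import (
    ZoneLabel,
    assign_zone,
    assign_zones,
    service_polygons,
    village_facility_time,
    zone_summary,
)


def _road(sid, coords, road_type="paved", width=8.0):
    return RoadSegment(sid, LineString(coords), road_type, width_ft=width)


def _village(vid, poly, pop=100):
    return Village(vid, vid, poly, population=pop)


def _single_road_setup(length=10.0):
    fac = HealthFacility("f1", Point(0, 0))
    v = _village("v1", box(3.9, -0.1, 4.15, 0.1))
    net = build_network([v], [_road("r", [(0, 0), (length, 0)])])
    return net, fac, v


class TestVillageFacilityTime:
    def test_half_hour_at_rickshaw_speed(self):
        """4.025 km of paved road at 8.05 km/h is exactly 30 minutes."""
        fac = HealthFacility("f1", Point(0, 0))
        v = _village("v1", box(3.925, -0.1, 4.125, 0.1))  # centroid 4.025
        net = build_network([v], [_road("r", [(0, 0), (10, 0)])])
        # centroid sits on the road, so the connector is (near-)zero
        t = village_facility_time(net, "v1", [fac])
        assert t == pytest.approx(30.0, abs=1e-6)

    def test_village_at_facility_is_green(self):
        fac = HealthFacility("f1", Point(0, 0))
        v = _village("v1", box(-0.1, -0.1, 0.1, 0.1))
        net = build_network([v], [_road("r", [(0, 0), (5, 0)])])
        assert village_facility_time(net, "v1", [fac]) == pytest.approx(0.0, abs=1e-9)
        zones = assign_zones(net, [v], [fac])
        assert zones["v1"] is ZoneLabel.GREEN

    def test_matches_exhaustive_enumeration_on_random_networks(self):
        import itertools
        import random

        import networkx as nx

        from refnet.geodata import TransportMode as M
        from refnet.network_routing import TransportNetwork, _dijkstra
        from refnet.travel_time import SpeedTable

        rng = random.Random(5)
        for _ in range(25):
            g = nx.Graph()
            ids = [f"n{i}" for i in range(6)]
            g.add_nodes_from(ids)
            for a, b in itertools.combinations(range(6), 2):
                if rng.random() < 0.5:
                    t = float(rng.randint(1, 5))
                    g.add_edge(ids[a], ids[b], length_km=t / 8, road_type="paved",
                               modes=(M.RICKSHAW,), times={M.RICKSHAW: t})
            net = TransportNetwork(g, {v: (i, 0) for i, v in enumerate(ids)},
                                   {}, SpeedTable.default())
            labels = _dijkstra(net, "n0", "rickshaw_only")
            for dst in ids[1:]:
                brute = None
                for path in nx.all_simple_paths(g, "n0", dst):
                    t = sum(g[u][v]["times"][M.RICKSHAW]
                            for u, v in zip(path, path[1:]))
                    brute = t if brute is None else min(brute, t)
                if brute is None:
                    assert dst not in labels
                else:
                    assert labels[dst][0] == brute


class TestServicePolygons:
    def test_straight_road_reach_ends_at_exact_distance(self):
        """30 min at 8.05 km/h reaches 4.025 km along the road, no farther."""
        net, fac, _v = _single_road_setup()
        polys = service_polygons(net, fac, [30, 50])
        p30 = polys[30.0]
        assert p30.covers(Point(4.0, 0))
        assert not p30.covers(Point(4.05, 0))
        # off-road reach shrinks with distance along the road (walking discs)
        assert p30.covers(Point(0, 1.9))
        assert not p30.covers(Point(4.0, 1.0))

    def test_polygons_are_nested(self, scenario, network):
        polys = service_polygons(network, scenario.facilities[0], [30, 50])
        assert polys[50.0].covers(polys[30.0])

    def test_island_facility_polygons_confined_without_boats(self, scenario):
        net = build_network(scenario.villages, scenario.land_roads)
        island_fac = HealthFacility("fi", Point(2.0, 7.0))
        polys = service_polygons(net, island_fac, [30, 50])
        mainland_fac = scenario.facilities[0]
        assert not polys[50.0].covers(mainland_fac.location)


class TestAssignZone:
    def _polys(self):
        return {30.0: box(0, 0, 10, 10), 50.0: box(0, 0, 20, 10)}

    def test_wholly_inside_inner_is_green(self):
        v = _village("v", box(1, 1, 3, 3))
        assert assign_zone(v, self._polys()) is ZoneLabel.GREEN

    def test_majority_band_wins(self):
        # 60% in the yellow band, 40% beyond the outer polygon
        v = _village("v", box(17, 0, 22, 10))
        assert assign_zone(v, self._polys()) is ZoneLabel.YELLOW

    def test_even_split_goes_to_faster_band(self):
        v = _village("v", box(8, 0, 12, 10))  # 50% green, 50% yellow
        assert assign_zone(v, self._polys()) is ZoneLabel.GREEN

    def test_no_majority_takes_largest_share(self):
        # 22.7% green, 45.5% yellow, 31.8% red: no band majority
        v = _village("v", box(5, 0, 27, 10))
        assert assign_zone(v, self._polys()) is ZoneLabel.YELLOW
        # 40% green, 40% yellow, 20% red: largest-share tie -> faster band
        v2 = _village("v2", box(0, 0, 25, 10))
        assert assign_zone(v2, self._polys()) is ZoneLabel.GREEN

    def test_zero_area_village_is_degenerate(self):
        with pytest.raises((DegenerateGeometryError, Exception)):
            _village("v", Polygon([(0, 0), (1, 0), (0, 0)]))


class TestZoneAssignmentProperties:
    def test_labels_partition_and_follow_polygons(self, scenario, network):
        from shapely.ops import unary_union

        zones = assign_zones(network, scenario.villages, scenario.facilities)
        assert set(zones) == {v.village_id for v in scenario.villages}
        polys = [service_polygons(network, f, [30, 50])
                 for f in scenario.facilities]
        inner = unary_union([p[30.0] for p in polys])
        outer = unary_union([p[50.0] for p in polys])
        for v in scenario.villages:
            z = zones[v.village_id]
            if inner.covers(v.boundary):
                assert z is ZoneLabel.GREEN
            if not outer.intersects(v.boundary):
                assert z is ZoneLabel.RED

    def test_wider_breaks_move_labels_greener(self, scenario, network):
        order = {ZoneLabel.GREEN: 0, ZoneLabel.YELLOW: 1, ZoneLabel.RED: 2}
        tight = assign_zones(network, scenario.villages, scenario.facilities,
                             breaks=(30, 50))
        loose = assign_zones(network, scenario.villages, scenario.facilities,
                             breaks=(40, 65))
        assert all(order[loose[v]] <= order[tight[v]] for v in tight)

    def test_exclusion_list_labels_excluded(self, scenario, network):
        vid = scenario.villages[0].village_id
        zones = assign_zones(network, scenario.villages, scenario.facilities,
                             exclusion_list=[vid])
        assert zones[vid] is ZoneLabel.EXCLUDED


class TestZoneSummary:
    def test_published_zone_rows_reproduce_percentages(self, fixtures):
        rows = {r.zone: r for r in fixtures.zone_summary()}
        assert rows["green"].population_pct == 24
        assert rows["yellow"].population_pct == 28
        assert rows["red"].population_pct == 44
        assert rows["excluded"].population_pct == 4
        assert rows["total"].population == sum(
            r["population"] for r in fixtures.zone_rows
        )
        pct_sum = sum(r.population_pct for r in fixtures.zone_summary()
                      if r.zone != "total")
        assert abs(pct_sum - 100) <= 1

    def test_all_green_summary(self):
        villages = [_village(f"v{i}", box(i, 0, i + 1, 1), pop=50)
                    for i in range(3)]
        rows = zone_summary(villages, {v.village_id: ZoneLabel.GREEN
                                       for v in villages})
        green = next(r for r in rows if r.zone == "green")
        assert green.n_villages == 3
        assert green.population_pct == 100

    def test_assigned_and_excluded_is_inconsistent(self):
        v = _village("v1", box(0, 0, 1, 1))
        with pytest.raises(ConsistencyError):
            zone_summary([v], {"v1": ZoneLabel.GREEN}, exclusion_list=["v1"])

    def test_population_conserved_through_summary(self, scenario, network):
        zones = assign_zones(network, scenario.villages, scenario.facilities)
        rows = zone_summary(scenario.villages, zones)
        total = next(r for r in rows if r.zone == "total")
        assert total.population == scenario.total_population
        assert sum(r.population for r in rows if r.zone != "total") == \
            total.population
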
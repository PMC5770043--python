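"""Multimodal transport graph construction and closest-facility routing.

The network is an undirected graph whose edges are noded road/waterway
pieces carrying per-mode traversal minutes. Routing follows the referral
model's structure: a patient travels from the village centre to the nearest
pick-up point (hub or sub-hub) of an active fixed route, then rides that
route's corridor to its facility.

Shortest paths minimise total minutes with a fully deterministic tie-break
(fewer edges, then lexicographically smallest vertex-id sequence) so that
repeated runs are bit-identical.
"""

from __future__ import annotations

import csv
import heapq
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
from shapely.geometry import LineString, Point
from shapely.ops import substring, unary_union
from shapely.strtree import STRtree

from ._util import round_half_up
from .errors import (
    IsolationWarning,
    PartialCoverageWarning,
    SchemaError,
    UnassignedVillageError,
    UnassignedWarning,
    UnreachableError,
)
from .geodata import (
    Constraint,
    HealthFacility,
    Hub,
    RoadSegment,
    TransportMode,
    UNSAFE_MODES,
    Village,
)
from .travel_time import MODE_ORDER, SpeedTable, applicable_modes

__all__ = [
    "TransportNetwork",
    "Route",
    "CatchmentAssignment",
    "build_network",
    "shortest_time_path",
    "closest_hub",
    "build_route_catalog",
    "assign_catchments",
    "exclude_route",
    "include_route",
    "estimate_arrival",
    "write_route_catalog",
    "read_route_catalog",
]

M = TransportMode

#: Snap tolerance for merging polyline endpoints into one vertex (km).
_SNAP = 1e-6


def _vkey(x: float, y: float) -> tuple[float, float]:
    return (round(x / _SNAP) * _SNAP, round(y / _SNAP) * _SNAP)


@dataclass
class TransportNetwork:
    """The weighted multimodal graph plus lookup tables.

    Edge data: ``length_km``, ``road_type``, ``modes`` (tuple, fastest
    first), ``times`` (mode -> minutes), ``geometry`` (oriented from the
    vertex stored in ``start``), ``segment_id`` of the parent polyline.
    Village centroids are attached by walk-only connector edges to their
    nearest network vertex.
    """

    graph: nx.Graph
    coords: dict[str, tuple[float, float]]
    village_vertex: dict[str, str]
    speed_table: SpeedTable

    def vertex_point(self, vertex: str) -> Point:
        return Point(*self.coords[vertex])

    def nearest_vertex(self, point: Point, *, exclude_villages: bool = True) -> str:
        """Closest network vertex to a point (deterministic id tie-break)."""
        best = None
        for v, (x, y) in self.coords.items():
            if exclude_villages and v in self._village_vertices:
                continue
            d = point.distance(Point(x, y))
            key = (d, v)
            if best is None or key < best:
                best = key
        if best is None:
            raise UnreachableError("network has no vertices")
        return best[1]

    @property
    def _village_vertices(self) -> set[str]:
        return set(self.village_vertex.values())

    def resolve(self, origin: str) -> str:
        """Map a village id or vertex id to a graph vertex."""
        if origin in self.village_vertex:
            return self.village_vertex[origin]
        if origin in self.graph:
            return origin
        raise KeyError(f"unknown origin {origin!r}")


def _edge_options(
    data: Mapping, policy, *, allow_unsafe: bool
) -> tuple[float, TransportMode] | None:
    """Minutes and mode for traversing an edge under a mode policy.

    Policies: ``"fastest_available"`` (fastest applicable mode, unsafe modes
    excluded unless allowed), ``"rickshaw_only"`` (rickshaw on vehicle
    roads, walking on narrow roads, boats on water — the zoning convention),
    a single TransportMode, or ``("single_mode", mode)``.
    """
    times: Mapping[TransportMode, float] = data["times"]
    if policy == "fastest_available":
        cands = [
            (t, m) for m, t in times.items() if allow_unsafe or m not in UNSAFE_MODES
        ]
        if not cands:
            return None
        return min(cands, key=lambda tm: (tm[0], MODE_ORDER.index(tm[1])))
    if policy == "rickshaw_only":
        if data["road_type"] == "waterway":
            mode = M.BOAT
        elif M.RICKSHAW in times:
            mode = M.RICKSHAW
        elif M.WALK in times:
            mode = M.WALK
        else:
            return None
        return (times[mode], mode) if mode in times else None
    if isinstance(policy, tuple) and policy[0] == "single_mode":
        policy = policy[1]
    mode = TransportMode(policy)
    if mode in times:
        return times[mode], mode
    return None


def _weld_junctions(lines: list[LineString], tol: float = 1e-6) -> list[LineString]:
    """Insert other lines' endpoints as vertices where they touch mid-line.

    A T-junction produced by projecting a point onto a polyline is off the
    line by float epsilon, so plain noding misses it; welding the endpoint
    into the host line's coordinate sequence makes the junction exact.
    """
    endpoints = []
    for line in lines:
        endpoints.append(line.coords[0])
        endpoints.append(line.coords[-1])
    tree = STRtree([Point(p) for p in endpoints])
    welded = []
    for line in lines:
        hits = tree.query(line.buffer(tol))
        inserts = []
        for idx in sorted(int(i) for i in hits):
            p = endpoints[idx]
            pt = Point(p)
            if line.distance(pt) > tol:
                continue
            proj = line.project(pt)
            if proj < tol or proj > line.length - tol:
                continue  # touches at an end: plain noding handles it
            if any(abs(proj - q) < tol for q, _ in inserts):
                continue
            inserts.append((proj, p))
        if not inserts:
            welded.append(line)
            continue
        coords = list(line.coords)
        dists = [line.project(Point(c)) for c in coords]
        merged_pts = sorted(
            [(d, c, False) for d, c in zip(dists, coords)]
            + [(d, p, True) for d, p in inserts]
        )
        out = []
        for d, c, is_insert in merged_pts:
            if out and abs(d - out[-1][0]) < tol:
                if is_insert:
                    out[-1] = (d, c, True)  # welded point wins the slot
                continue
            out.append((d, c, is_insert))
        welded.append(LineString([c for _d, c, _i in out]))
    return welded


def build_network(
    villages: Sequence[Village],
    roads: Sequence[RoadSegment],
    waterways: Sequence[RoadSegment] = (),
    constraints: Sequence[Constraint] = (),
    *,
    speed_table: SpeedTable | None = None,
    max_connector_km: float = 5.0,
) -> TransportNetwork:
    """Node the polylines, weight edges per mode, attach villages.

    Polylines are noded at shared endpoints and crossings (waterways may be
    passed separately or mixed into ``roads`` with road_type "waterway").
    Each noded piece inherits its parent segment's attributes; point
    constraints modify the piece they touch. Every village centroid becomes
    a vertex joined by a walking connector to the nearest road vertex; a
    village farther than ``max_connector_km`` raises an isolation warning
    and stays unconnected.
    """
    table = speed_table or SpeedTable.with_nasiman()
    segments = list(roads) + list(waterways)
    if not segments:
        raise SchemaError("cannot build a network without road segments")

    geometries = _weld_junctions([s.geometry for s in segments])
    merged = unary_union(geometries)
    pieces: list[LineString] = (
        [merged] if isinstance(merged, LineString) else list(merged.geoms)
    )
    parent_tree = STRtree([s.geometry for s in segments])

    # constraint -> nearest piece index, resolved after pieces exist
    graph = nx.Graph()
    coords: dict[str, tuple[float, float]] = {}
    key_to_id: dict[tuple[float, float], str] = {}

    endpoint_keys = sorted(
        {_vkey(*line.coords[0]) for line in pieces}
        | {_vkey(*line.coords[-1]) for line in pieces}
    )
    for i, key in enumerate(endpoint_keys):
        vid = f"n{i:05d}"
        key_to_id[key] = vid
        coords[vid] = key
        graph.add_node(vid)

    piece_records = []
    for line in pieces:
        mid = line.interpolate(0.5, normalized=True)
        idx = parent_tree.nearest(mid)
        parent = segments[int(idx)]
        piece_records.append((line, parent))

    # point constraints attach to the piece nearest their location
    constraint_effect: dict[int, str] = {}
    for con in constraints:
        best = None
        for j, (line, _parent) in enumerate(piece_records):
            d = con.location.distance(line)
            if best is None or (d, j) < best:
                best = (d, j)
        if best is not None and best[0] <= 0.05:
            # blocks_passage dominates forces_walk if both hit one piece
            prev = constraint_effect.get(best[1])
            if prev != "blocks_passage":
                constraint_effect[best[1]] = con.effect

    for j, (line, parent) in enumerate(piece_records):
        u = key_to_id[_vkey(*line.coords[0])]
        v = key_to_id[_vkey(*line.coords[-1])]
        if u == v:
            continue
        modes = applicable_modes(parent, constraint_effect.get(j))
        modes = tuple(m for m in modes if table.defines(m, parent.road_type))
        if not modes:
            continue
        length = line.length
        times = {
            m: 60.0 * length / table.speed(m, parent.road_type) for m in modes
        }
        if graph.has_edge(u, v):
            # keep the faster parallel edge under the fastest-available policy
            if min(graph[u][v]["times"].values()) <= min(times.values()):
                continue
        graph.add_edge(
            u, v,
            length_km=length, road_type=parent.road_type, modes=modes,
            times=times, geometry=line,
            start=u if _vkey(*line.coords[0]) == coords[u] else v,
            segment_id=parent.segment_id,
        )

    # Attach each village by a walking connector to the nearest point on the
    # network, splitting the host edge when that point falls mid-edge.
    village_vertex: dict[str, str] = {}
    n_split = 0
    for vil in sorted(villages, key=lambda v: v.village_id):
        c = vil.centroid
        best_vertex = None
        for rv in sorted(graph.nodes):
            if rv.startswith("v_"):
                continue
            d = c.distance(Point(*coords[rv]))
            if best_vertex is None or (d, rv) < best_vertex:
                best_vertex = (d, rv)
        best_edge = None
        for u, v in sorted(graph.edges):
            if u.startswith("v_") or v.startswith("v_"):
                continue
            d = graph[u][v]["geometry"].distance(c)
            if best_edge is None or (d, u, v) < best_edge:
                best_edge = (d, u, v)
        vid = f"v_{vil.village_id}"
        coords[vid] = (c.x, c.y)
        village_vertex[vil.village_id] = vid
        nearest_km = min(
            b[0] for b in (best_vertex, best_edge) if b is not None
        ) if (best_vertex or best_edge) else float("inf")
        if nearest_km > max_connector_km:
            warnings.warn(
                f"village {vil.village_id} is {nearest_km:.2f} km from the "
                f"network (max connector {max_connector_km} km); left "
                f"unconnected",
                IsolationWarning,
            )
            graph.add_node(vid)
            continue
        if best_edge is not None and best_edge[0] < best_vertex[0] - 1e-9:
            d, u, v = best_edge
            data = dict(graph[u][v])
            geom = data["geometry"]
            proj = geom.project(c)
            if proj <= 1e-9:
                anchor = data["start"]
            elif proj >= geom.length - 1e-9:
                anchor = v if data["start"] == u else u
            else:
                anchor = f"m{n_split:05d}"
                n_split += 1
                p = geom.interpolate(proj)
                coords[anchor] = (p.x, p.y)
                first = data["start"]
                second = v if first == u else u
                graph.remove_edge(u, v)
                for a, b, sub in (
                    (first, anchor, substring(geom, 0.0, proj)),
                    (anchor, second, substring(geom, proj, geom.length)),
                ):
                    frac = sub.length / geom.length if geom.length else 0.0
                    graph.add_edge(
                        a, b,
                        length_km=sub.length,
                        road_type=data["road_type"],
                        modes=data["modes"],
                        times={m: t * frac for m, t in data["times"].items()},
                        geometry=sub, start=a,
                        segment_id=data["segment_id"],
                    )
        else:
            d, anchor = best_vertex
        line = LineString([(c.x, c.y), coords[anchor]])
        walk_min = 0.0 if d == 0 else 60.0 * d / table.speed(M.WALK, "unpaved")
        graph.add_edge(
            vid, anchor, length_km=d, road_type="unpaved", modes=(M.WALK,),
            times={M.WALK: walk_min}, geometry=line, start=vid,
            segment_id=f"conn_{vil.village_id}",
        )
    return TransportNetwork(graph, coords, village_vertex, table)


# --------------------------------------------------------------------------
# Deterministic shortest paths


def _dijkstra(
    network: TransportNetwork,
    source: str,
    policy="fastest_available",
    *,
    allow_unsafe: bool = False,
    targets: set[str] | None = None,
) -> dict[str, tuple[float, int, tuple[str, ...]]]:
    """Single-source shortest paths with the deterministic tie-break.

    Labels order by (minutes, edge count, vertex-id sequence); the first
    label popped for a vertex is final under this total order because every
    component is monotone under edge appension.
    """
    G = network.graph
    final: dict[str, tuple[float, int, tuple[str, ...]]] = {}
    heap: list[tuple[float, int, tuple[str, ...]]] = [(0.0, 0, (source,))]
    remaining = set(targets) if targets is not None else None
    while heap:
        t, k, path = heapq.heappop(heap)
        v = path[-1]
        if v in final:
            continue
        final[v] = (t, k, path)
        if remaining is not None:
            remaining.discard(v)
            if not remaining:
                break
        for w, data in sorted(G[v].items()):
            if w in final:
                continue
            opt = _edge_options(data, policy, allow_unsafe=allow_unsafe)
            if opt is None:
                continue
            heapq.heappush(heap, (t + opt[0], k + 1, path + (w,)))
    return final


def _path_metrics(
    network: TransportNetwork, path: Sequence[str], policy, *, allow_unsafe: bool
) -> tuple[float, float, list[tuple[TransportMode, float, str]]]:
    """(minutes, km, legs) along a vertex path under a policy."""
    minutes = 0.0
    dist = 0.0
    legs: list[tuple[TransportMode, float, str]] = []
    for u, v in zip(path, path[1:]):
        data = network.graph[u][v]
        opt = _edge_options(data, policy, allow_unsafe=allow_unsafe)
        if opt is None:
            raise UnreachableError(f"edge {u}-{v} not traversable under policy")
        minutes += opt[0]
        dist += data["length_km"]
        legs.append((opt[1], data["length_km"], data["road_type"]))
    return minutes, dist, legs


def shortest_time_path(
    network: TransportNetwork,
    origin: str,
    destination: str,
    mode_policy="fastest_available",
    *,
    allow_unsafe: bool = False,
) -> tuple[list[str], float, float]:
    """Minimum-minutes path between vertices (or village ids).

    Returns (vertex path, minutes, distance_km). Ties in minutes break on
    fewer edges, then the lexicographically smallest vertex-id sequence.
    """
    src = network.resolve(origin)
    dst = network.resolve(destination)
    if src == dst:
        return [], 0.0, 0.0
    labels = _dijkstra(
        network, src, mode_policy, allow_unsafe=allow_unsafe, targets={dst}
    )
    if dst not in labels:
        raise UnreachableError(f"{destination!r} unreachable from {origin!r}")
    t, _k, path = labels[dst]
    _, dist, _legs = _path_metrics(
        network, path, mode_policy, allow_unsafe=allow_unsafe
    )
    return list(path), t, dist


def closest_hub(
    network: TransportNetwork, village_id: str, hubs: Sequence[Hub]
) -> tuple[Hub, float]:
    """Nearest pick-up point by travel time from the village centre.

    Ties break on kind (hub before sub_hub), then hub id.
    """
    if not hubs:
        raise UnreachableError("no hubs supplied")
    src = network.resolve(village_id)
    labels = _dijkstra(network, src, "fastest_available", allow_unsafe=False)
    best = None
    for hub in hubs:
        hv = network.nearest_vertex(hub.location)
        if hv not in labels:
            continue
        t = labels[hv][0]
        key = (t, 0 if hub.kind == "hub" else 1, hub.hub_id)
        if best is None or key < best[0]:
            best = (key, hub)
    if best is None:
        raise UnreachableError(f"village {village_id}: no reachable hub")
    return best[1], best[0][0]


# --------------------------------------------------------------------------
# Route catalog


@dataclass
class Route:
    """One hub-to-facility transport corridor (a catalog row)."""

    route_id: str
    name: str
    origin_hub: Hub
    facility: HealthFacility
    path: list[str]
    mode_legs: list[tuple[TransportMode, float, str]]
    distance_km: float
    time_min: float
    sub_hubs: list[Hub] = field(default_factory=list)
    catchment_village_ids: set[str] = field(default_factory=set)
    catchment_population: int = 0
    active: bool = True

    @property
    def mode_label(self) -> str:
        """Human-readable vehicle modes in travel order, e.g. 'Boat and Tempo'."""
        seen: list[str] = []
        for mode, _l, _r in self.mode_legs:
            if mode is M.WALK:
                continue
            label = mode.value.upper() if mode is M.CNG else mode.value.capitalize()
            if label not in seen:
                seen.append(label)
        return " and ".join(seen) if seen else "Walk"

    @property
    def uses_unsafe_mode(self) -> bool:
        return any(m in UNSAFE_MODES for m, _l, _r in self.mode_legs)


def build_route_catalog(
    network: TransportNetwork,
    hubs: Sequence[Hub],
    facilities: Sequence[HealthFacility],
) -> list[Route]:
    """One route per community-end hub, to its nearest facility.

    Corridor times are computed with every fixed-route mode available
    (including the unsafe nasiman, so that an unsafe corridor is catalogued
    with its true time and then deactivated rather than silently re-routed).
    Sub-hubs lying on the corridor attach in travel order.
    """
    if not facilities:
        raise UnreachableError("no facilities supplied")
    anchors = sorted((h for h in hubs if h.kind == "hub"), key=lambda h: h.hub_id)
    sub_hubs = sorted((h for h in hubs if h.kind == "sub_hub"), key=lambda h: h.hub_id)
    sub_vertex = {h.hub_id: network.nearest_vertex(h.location) for h in sub_hubs}
    fac_vertex = {f.facility_id: network.nearest_vertex(f.location) for f in facilities}

    routes: list[Route] = []
    for i, hub in enumerate(anchors, start=1):
        hv = network.nearest_vertex(hub.location)
        labels = _dijkstra(
            network, hv, "fastest_available", allow_unsafe=True,
            targets=set(fac_vertex.values()),
        )
        best = None
        for fac in sorted(facilities, key=lambda f: f.facility_id):
            fv = fac_vertex[fac.facility_id]
            if fv not in labels:
                continue
            key = (labels[fv][0], fac.facility_id)
            if best is None or key < best[0]:
                best = (key, fac, fv)
        if best is None:
            raise UnreachableError(f"hub {hub.hub_id}: no reachable facility")
        _key, fac, fv = best
        path = list(labels[fv][2])
        minutes, dist, legs = _path_metrics(
            network, path, "fastest_available", allow_unsafe=True
        )
        on_path = {v: j for j, v in enumerate(path)}
        attached = sorted(
            (h for h in sub_hubs if sub_vertex[h.hub_id] in on_path),
            key=lambda h: (on_path[sub_vertex[h.hub_id]], h.hub_id),
        )
        route = Route(
            route_id=f"{i:02d}",
            name=f"{hub.name or hub.hub_id} to {fac.name or fac.facility_id}",
            origin_hub=hub,
            facility=fac,
            path=path,
            mode_legs=legs,
            distance_km=dist,
            time_min=minutes,
            sub_hubs=attached,
        )
        route.active = not route.uses_unsafe_mode
        routes.append(route)
    return routes


@dataclass(frozen=True)
class CatchmentAssignment:
    village_id: str
    route_id: str
    pickup_id: str
    access_min: float


def _pickup_points(
    network: TransportNetwork, routes: Sequence[Route]
) -> list[tuple[str, str, str, str]]:
    """(vertex, kind, pickup_id, route_id) for every active-route pickup."""
    out = []
    for route in routes:
        if not route.active:
            continue
        hv = network.nearest_vertex(route.origin_hub.location)
        out.append((hv, "hub", route.origin_hub.hub_id, route.route_id))
        for sh in route.sub_hubs:
            out.append(
                (network.nearest_vertex(sh.location), "sub_hub", sh.hub_id,
                 route.route_id)
            )
    return out


def assign_catchments(
    routes: Sequence[Route],
    villages: Sequence[Village],
    network: TransportNetwork,
    *,
    exclusion_list: Iterable[str] = (),
    manual_overrides: Mapping[str, str] | None = None,
) -> dict[str, CatchmentAssignment]:
    """Assign every non-excluded village to its quickest active-route pickup.

    Proximity is operationalised purely as minimum travel time from the
    village centre under the fastest dispatchable mode; a manual override
    table (village -> route) can re-pin villages afterwards, standing in for
    the villagers'-preference adjustments that automatic assignment cannot
    reproduce. Route catchment populations are recomputed in place.
    """
    excluded = set(exclusion_list)
    overrides = dict(manual_overrides or {})
    pickups = _pickup_points(network, routes)
    by_route: dict[str, list[tuple[str, str, str, str]]] = {}
    for p in pickups:
        by_route.setdefault(p[3], []).append(p)
    route_by_id = {r.route_id: r for r in routes}

    assignments: dict[str, CatchmentAssignment] = {}
    for route in routes:
        route.catchment_village_ids = set()
        route.catchment_population = 0
    for vil in sorted(villages, key=lambda v: v.village_id):
        if vil.village_id in excluded:
            continue
        labels = _dijkstra(
            network, network.resolve(vil.village_id), "fastest_available",
            allow_unsafe=False,
        )
        candidates = by_route.get(overrides[vil.village_id], pickups) \
            if vil.village_id in overrides else pickups
        best = None
        for vx, kind, pid, rid in candidates:
            if vx not in labels:
                continue
            key = (labels[vx][0], 0 if kind == "hub" else 1, pid, rid)
            if best is None or key < best:
                best = key
        if best is None:
            warnings.warn(
                f"village {vil.village_id} reaches no active route pickup",
                UnassignedWarning,
            )
            continue
        t, _kindrank, pid, rid = best
        assignments[vil.village_id] = CatchmentAssignment(
            vil.village_id, rid, pid, t
        )
        route = route_by_id[rid]
        route.catchment_village_ids.add(vil.village_id)
        route.catchment_population += vil.population
    return assignments


def exclude_route(
    routes: Sequence[Route],
    route_id: str,
    villages: Sequence[Village],
    network: TransportNetwork,
    **assign_kwargs,
) -> dict[str, CatchmentAssignment]:
    """Deactivate a route and reassign its villages to nearby active routes.

    Population is conserved across the reassignment; if some village then
    reaches no active route a partial-coverage warning is raised.
    """
    route = next((r for r in routes if r.route_id == route_id), None)
    if route is None:
        raise KeyError(f"no route {route_id!r}")
    route.active = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        assignments = assign_catchments(routes, villages, network, **assign_kwargs)
    uncovered = [w for w in caught if issubclass(w.category, UnassignedWarning)]
    for w in caught:
        warnings.warn_explicit(w.message, w.category, w.filename, w.lineno)
    if uncovered:
        warnings.warn(
            f"excluding route {route_id} left {len(uncovered)} village(s) "
            f"without an active route", PartialCoverageWarning,
        )
    return assignments


def include_route(
    routes: Sequence[Route],
    route_id: str,
    villages: Sequence[Village],
    network: TransportNetwork,
    **assign_kwargs,
) -> dict[str, CatchmentAssignment]:
    """Re-activate a route (unless unsafe) and recompute assignments."""
    route = next((r for r in routes if r.route_id == route_id), None)
    if route is None:
        raise KeyError(f"no route {route_id!r}")
    route.active = not route.uses_unsafe_mode
    return assign_catchments(routes, villages, network, **assign_kwargs)


def estimate_arrival(
    network: TransportNetwork,
    village_id: str,
    catchments: Mapping[str, CatchmentAssignment],
    routes: Sequence[Route],
) -> float:
    """Minutes from pickup request to facility arrival for a village.

    Access time (village centre to its assigned pickup) plus the route's
    remaining corridor time from that pickup, additive leg by leg.
    """
    if village_id not in catchments:
        raise UnassignedVillageError(f"village {village_id} has no assignment")
    a = catchments[village_id]
    route = next(r for r in routes if r.route_id == a.route_id)
    pickup = (
        route.origin_hub
        if route.origin_hub.hub_id == a.pickup_id
        else next(h for h in route.sub_hubs if h.hub_id == a.pickup_id)
    )
    pv = network.nearest_vertex(pickup.location)
    try:
        start = route.path.index(pv)
    except ValueError:
        start = 0
    remaining = sum(
        _edge_options(
            network.graph[u][v], "fastest_available", allow_unsafe=True
        )[0]
        for u, v in zip(route.path[start:], route.path[start + 1:])
    )
    return a.access_min + remaining


# --------------------------------------------------------------------------
# Catalog CSV (the printed route-table layout)

_CATALOG_COLUMNS = [
    "route_id", "route_name", "mode", "distance_km", "time_min",
    "catchment_population",
]


def write_route_catalog(routes: Sequence[Route], path: str | Path) -> None:
    """Write the catalog in the published column layout (inactive routes
    keep their row, matching the printed table's footnoted exclusion)."""
    if not routes:
        raise SchemaError("refusing to write an empty route catalog")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CATALOG_COLUMNS + ["active"])
        for r in routes:
            w.writerow([
                r.route_id, r.name, r.mode_label,
                f"{r.distance_km:.2f}", f"{round_half_up(r.time_min, 2):.2f}",
                r.catchment_population, int(r.active),
            ])


def read_route_catalog(path: str | Path) -> list[dict]:
    """Read a catalog CSV back as plain row dicts (numbers parsed)."""
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            row["distance_km"] = float(row["distance_km"])
            row["time_min"] = float(row["time_min"])
            row["catchment_population"] = int(row["catchment_population"])
            if "active" in row:
                row["active"] = bool(int(row["active"]))
            rows.append(row)
    return rows
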
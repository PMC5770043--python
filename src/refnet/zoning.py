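"""Travel-time service areas and catchment zoning.

The project area is banded by rickshaw travel time to the nearest facility:
green (<= 30 min), yellow (30-50 min), red (> 50 min). Rickshaws are the
zoning yardstick because they are the most common and universally available
vehicle; the cost convention is rickshaw speed on vehicle-passable roads,
walking speed on sub-5-ft roads, boat speed on water.

Service polygons are realised as buffered network reach: each edge is
truncated at the remaining time budget and buffered into a corridor. The
contract is the village-level label, not polygon aesthetics — a village
wholly inside the 30-minute reach is green, wholly outside the 50-minute
reach is red, and a village straddling a boundary is assigned by the
50%-area-coverage rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from shapely.geometry import Point, Polygon
from shapely.ops import substring, unary_union

from ._util import percent
from .errors import (
    ConsistencyError,
    DegenerateGeometryError,
    UnreachableError,
)
from .geodata import HealthFacility, Village
from .network_routing import TransportNetwork, _dijkstra, _edge_options

__all__ = [
    "ZoneLabel",
    "ZoneSummaryRow",
    "village_facility_time",
    "service_polygons",
    "assign_zone",
    "assign_zones",
    "zone_summary",
    "DEFAULT_BREAKS",
]

#: Zone break minutes: green <= 30 < yellow <= 50 < red.
DEFAULT_BREAKS = (30.0, 50.0)


class ZoneLabel(str, Enum):
    GREEN = "green"
    YELLOW = "yellow"
    RED = "red"
    EXCLUDED = "excluded"


#: Ordering used for "faster band wins" tie-breaks and summaries.
ZONE_ORDER = (ZoneLabel.GREEN, ZoneLabel.YELLOW, ZoneLabel.RED, ZoneLabel.EXCLUDED)


def village_facility_time(
    network: TransportNetwork,
    village_id: str,
    facilities: Sequence[HealthFacility],
) -> float:
    """Minutes from the village centre to the nearest facility under the
    rickshaw zoning convention."""
    src = network.resolve(village_id)
    labels = _dijkstra(network, src, "rickshaw_only")
    best = None
    for fac in sorted(facilities, key=lambda f: f.facility_id):
        fv = network.nearest_vertex(fac.location)
        if fv in labels:
            t = labels[fv][0]
            if best is None or t < best:
                best = t
    if best is None:
        raise UnreachableError(
            f"village {village_id}: no facility reachable by rickshaw/walk/boat"
        )
    return best


#: Off-network walking speed used to widen network reach into an area.
_WALK_KMH = 4.0

#: Along-edge sampling step (km) for the walking-disc envelope.
_SAMPLE_KM = 0.15


def service_polygons(
    network: TransportNetwork,
    facility: HealthFacility,
    breaks: Sequence[float] = DEFAULT_BREAKS,
    *,
    walk_kmh: float = _WALK_KMH,
    sample_km: float = _SAMPLE_KM,
) -> dict[float, Polygon]:
    """Nested multipart reach polygons around a facility.

    The b-minute polygon is the network reach widened by off-network
    walking: every point p on the network reachable in t(p) <= b minutes
    contributes a disc of radius (b - t(p)) * walk speed, and each edge is
    truncated at the exact distance coverable within the remaining budget.
    Because walking is the slowest mode, the envelope never extends past
    the on-road reach point along the road itself, so a straight road from
    the facility yields a polygon ending exactly at speed * b / 60 km.
    Polygons are nested by construction; multipart shapes arise naturally
    around islands.
    """
    breaks = sorted(breaks)
    if not breaks:
        raise ValueError("at least one break value required")
    fv = network.nearest_vertex(facility.location)
    labels = _dijkstra(network, fv, "rickshaw_only")
    if len(labels) <= 1 and not network.graph[fv]:
        raise DegenerateGeometryError(
            f"facility {facility.facility_id}: empty reachable set"
        )
    polygons: dict[float, Polygon] = {}
    previous = None
    for b in breaks:
        parts = []
        for vx, (t, _k, _p) in labels.items():
            if t <= b:
                r = (b - t) * walk_kmh / 60.0
                if r > 0:
                    parts.append(Point(*network.coords[vx]).buffer(r))
        for u, v, data in network.graph.edges(data=True):
            opt = _edge_options(data, "rickshaw_only", allow_unsafe=False)
            if opt is None:
                continue
            cost = opt[0]
            geom = data["geometry"]
            length = data["length_km"]
            start_u = data["start"] == u
            for end_vertex, from_start in ((u, start_u), (v, not start_u)):
                t0 = labels.get(end_vertex, (None,))[0]
                if t0 is None or t0 > b:
                    continue
                frac = 1.0 if cost == 0 else min(1.0, (b - t0) / cost)
                reach = length * frac
                if reach <= 0 or length == 0:
                    continue
                sub = (
                    substring(geom, 0.0, reach)
                    if from_start
                    else substring(geom, length - reach, length)
                )
                if from_start:
                    def t_at(d):
                        return t0 + cost * d / length
                    interp = sub.interpolate
                else:
                    def t_at(d):
                        return t0 + cost * d / length
                    interp = lambda d: sub.interpolate(sub.length - d)  # noqa: E731
                # thin flat-capped ribbon keeps the exact on-road reach tip
                parts.append(sub.buffer(1e-3, cap_style="flat"))
                n_steps = max(1, int(reach / sample_km))
                for j in range(n_steps + 1):
                    d = reach * j / n_steps
                    r = (b - t_at(d)) * walk_kmh / 60.0
                    if r > 1e-9:
                        parts.append(interp(d).buffer(r))
        if not parts:
            raise DegenerateGeometryError(
                f"facility {facility.facility_id}: empty {b}-minute reach"
            )
        poly = unary_union(parts)
        if previous is not None:
            poly = unary_union([poly, previous])
        polygons[float(b)] = poly
        previous = poly
    return polygons


def assign_zone(
    village: Village,
    polygons: Mapping[float, Polygon],
    *,
    coverage_threshold: float = 0.5,
) -> ZoneLabel:
    """Zone a village by the area-coverage rule.

    The band (green: inside the first polygon; yellow: in the second minus
    the first; red: the remainder) covering at least the threshold share of
    the village area wins; if no band reaches it, the largest share wins,
    with exact ties going to the faster band.
    """
    area = village.boundary.area
    if area <= 0:
        raise DegenerateGeometryError(f"village {village.village_id}: zero area")
    b1, b2 = sorted(polygons)[:2]
    inner = polygons[b1]
    outer = polygons[b2]
    green = village.boundary.intersection(inner).area / area
    yellow = village.boundary.intersection(outer).area / area - green
    red = max(0.0, 1.0 - green - yellow)
    shares = [
        (ZoneLabel.GREEN, green),
        (ZoneLabel.YELLOW, yellow),
        (ZoneLabel.RED, red),
    ]
    for label, share in shares:
        if share >= coverage_threshold:
            return label
    best = max(shares, key=lambda ls: ls[1])
    # exact tie -> faster band (shares listed fastest first)
    for label, share in shares:
        if share == best[1]:
            return label
    return best[0]


def assign_zones(
    network: TransportNetwork,
    villages: Sequence[Village],
    facilities: Sequence[HealthFacility],
    breaks: Sequence[float] = DEFAULT_BREAKS,
    *,
    exclusion_list: Iterable[str] = (),
    coverage_threshold: float = 0.5,
) -> dict[str, ZoneLabel]:
    """Zone every village: polygon containment first, overlap rule at
    boundaries, network time as fallback for villages the polygons miss.

    A village wholly inside the inner polygon is green and wholly outside
    the outer polygon is red, by construction; only villages crossed by a
    polygon boundary invoke the 50%-coverage rule.
    """
    breaks = sorted(breaks)
    b1, b2 = breaks[:2]
    polys = [
        service_polygons(network, fac, breaks) for fac in facilities
    ]
    inner = unary_union([p[b1] for p in polys])
    outer = unary_union([p[b2] for p in polys])
    merged = {b1: inner, b2: outer}
    excluded = set(exclusion_list)
    zones: dict[str, ZoneLabel] = {}
    for vil in sorted(villages, key=lambda v: v.village_id):
        if vil.village_id in excluded:
            zones[vil.village_id] = ZoneLabel.EXCLUDED
            continue
        if inner.covers(vil.boundary):
            zones[vil.village_id] = ZoneLabel.GREEN
        elif not outer.intersects(vil.boundary):
            zones[vil.village_id] = ZoneLabel.RED
        else:
            zones[vil.village_id] = assign_zone(
                vil, merged, coverage_threshold=coverage_threshold
            )
    return zones


@dataclass(frozen=True)
class ZoneSummaryRow:
    """One row of the zone summary table (plus a grand-total row)."""

    zone: str
    n_villages: int
    settlement_area_km2: float
    population: int
    population_pct: int


def zone_summary(
    villages: Sequence[Village],
    assignments: Mapping[str, ZoneLabel | str],
    exclusion_list: Iterable[str] = (),
) -> list[ZoneSummaryRow]:
    """Per-zone village counts, settlement areas, populations and integer
    population percentages, plus a total row. Percentages are half-up on
    the exact population share, so they sum to 100 +/- 1."""
    excluded = set(exclusion_list)
    by_zone: dict[ZoneLabel, list[Village]] = {z: [] for z in ZONE_ORDER}
    for vil in villages:
        if vil.village_id in excluded:
            label = assignments.get(vil.village_id)
            if label is not None and ZoneLabel(label) is not ZoneLabel.EXCLUDED:
                raise ConsistencyError(
                    f"village {vil.village_id} both zoned and excluded"
                )
            by_zone[ZoneLabel.EXCLUDED].append(vil)
            continue
        label = assignments.get(vil.village_id)
        if label is None:
            raise ConsistencyError(f"village {vil.village_id} has no zone")
        by_zone[ZoneLabel(label)].append(vil)
    total_pop = sum(v.population for v in villages)
    rows = []
    for zone in ZONE_ORDER:
        members = by_zone[zone]
        if zone is ZoneLabel.EXCLUDED and not members:
            continue
        pop = sum(v.population for v in members)
        rows.append(
            ZoneSummaryRow(
                zone=zone.value,
                n_villages=len(members),
                settlement_area_km2=round(sum(v.area_km2 for v in members), 2),
                population=pop,
                population_pct=int(percent(pop, total_pop, dp=0)) if total_pop else 0,
            )
        )
    rows.append(
        ZoneSummaryRow(
            zone="total",
            n_villages=len(villages),
            settlement_area_km2=round(sum(v.area_km2 for v in villages), 2),
            population=total_pop,
            population_pct=100 if total_pop else 0,
        )
    )
    return rows


def summary_from_counts(
    rows: Sequence[tuple[str, int, float, int]]
) -> list[ZoneSummaryRow]:
    """Build a summary table from already-tabulated (zone, n_villages,
    area_km2, population) rows — e.g. a published table — recomputing the
    percentage column and the total row from the printed populations."""
    total_pop = sum(r[3] for r in rows)
    out = [
        ZoneSummaryRow(z, n, a, p, int(percent(p, total_pop, dp=0)))
        for (z, n, a, p) in rows
    ]
    out.append(
        ZoneSummaryRow(
            "total",
            sum(r[1] for r in rows),
            round(sum(r[2] for r in rows), 2),
            total_pop,
            100,
        )
    )
    return out
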
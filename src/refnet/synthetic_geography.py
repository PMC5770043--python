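"""Seeded generators of study-shaped geodata and call logs, plus the
published-table fixture bundle.

The scenario generator emulates the structure of a two-subdistrict rural
study area: each subdistrict is a ~14x14 km block with one subdistrict
hospital at its headquarters, villages tiling the block as a planar
partition (Voronoi cells around settlement seeds), fixed tempo/CNG road
corridors radiating from the hospital to boundary markets (the community
hubs), narrow and unpaved village access roads, and — in the first
subdistrict — a river that severs island villages from all road
connectivity, bridged only by boat edges between landing ghats.

It makes no attempt to mimic any real geography; it reproduces the
*statistical and topological* features the pipeline must handle.
"""

from __future__ import annotations

import csv
import datetime as dt
import math
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import LineString, Point, Polygon, box

from .errors import ConsistencyError, GenerationError
from .geodata import (
    CallRecord,
    Constraint,
    HealthFacility,
    Hub,
    RoadSegment,
    SEMESTER_WINDOWS,
    TransportMode,
    UNKNOWN_VILLAGE,
    Village,
)
from .referral_analytics import ComplianceTable, ZoneCount
from .travel_time import SpeedTable
from .zoning import ZoneSummaryRow, summary_from_counts

__all__ = [
    "ScenarioConfig",
    "ScenarioBundle",
    "CallLogConfig",
    "generate_scenario",
    "generate_call_log",
    "table_fixtures",
    "TableFixtures",
]

M = TransportMode


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of the synthetic study area.

    Defaults produce a quarter-scale area (~84 villages) so the whole
    pipeline runs in seconds; :meth:`paper_scale` sizes it like the study
    (~338 villages, 17 hub corridors).
    """

    seed: int = 0
    n_subdistricts: int = 2
    villages_per_subdistrict: int = 42
    river: bool = True
    island_fraction: float = 1.0 / 3.0
    road_type_mix: tuple = (("paved", 0.45), ("herringbone", 0.25), ("unpaved", 0.30))
    narrow_road_fraction: float = 0.15
    hubs_per_subdistrict: int = 4
    fixed_route_fraction: float = 0.7
    include_unsafe_corridor: bool = True
    include_constraints: bool = True
    subdistrict_size_km: float = 14.0
    mean_village_population: float = 1300.0

    def __post_init__(self) -> None:
        mix = dict(self.road_type_mix)
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise GenerationError("road_type_mix proportions must sum to 1")
        if min(self.n_subdistricts, self.villages_per_subdistrict,
               self.hubs_per_subdistrict) <= 0:
            raise GenerationError("counts must be positive")
        for frac in (self.island_fraction, self.narrow_road_fraction,
                     self.fixed_route_fraction):
            if not 0.0 <= frac <= 1.0:
                raise GenerationError("fractions must lie in [0, 1]")
        if self.hubs_per_subdistrict > 8:
            raise GenerationError(
                "at most 8 hub corridors fit around one headquarters"
            )

    @classmethod
    def paper_scale(cls, seed: int = 0) -> "ScenarioConfig":
        return cls(seed=seed, villages_per_subdistrict=169,
                   hubs_per_subdistrict=8)


@dataclass
class ScenarioBundle:
    """A full synthetic geodata bundle."""

    villages: list[Village]
    roads: list[RoadSegment]
    hubs: list[Hub]
    facilities: list[HealthFacility]
    constraints: list[Constraint]
    island_village_ids: set[str] = field(default_factory=set)

    @property
    def waterways(self) -> list[RoadSegment]:
        return [r for r in self.roads if r.road_type == "waterway"]

    @property
    def land_roads(self) -> list[RoadSegment]:
        return [r for r in self.roads if r.road_type != "waterway"]

    @property
    def total_population(self) -> int:
        return sum(v.population for v in self.villages)


def _voronoi_cells(points: np.ndarray, frame: Polygon) -> list[Polygon]:
    """Bounded Voronoi cells of ``points`` clipped to ``frame``.

    Cells are made finite by mirroring the seeds across the frame edges.
    """
    minx, miny, maxx, maxy = frame.bounds
    mirrored = [points]
    for axis, lo, hi in ((0, minx, maxx), (1, miny, maxy)):
        for bound in (lo, hi):
            m = points.copy()
            m[:, axis] = 2 * bound - m[:, axis]
            mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))
    cells = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        poly = Polygon(vor.vertices[region]).buffer(0).intersection(frame)
        if poly.geom_type == "MultiPolygon":
            seed = Point(points[i])
            poly = min(poly.geoms, key=lambda p: p.distance(seed))
        cells.append(poly)
    return cells


def _corridor_line(
    rng: np.random.Generator,
    origin: tuple[float, float],
    angle: float,
    reach: float,
    frame: Polygon,
) -> LineString:
    """A gently jittered polyline from the origin outward along ``angle``."""
    ox, oy = origin
    pts = [(ox, oy)]
    n_steps = 4
    for k in range(1, n_steps + 1):
        r = reach * k / n_steps
        lateral = rng.uniform(-0.35, 0.35) if k < n_steps else 0.0
        x = ox + r * math.cos(angle) - lateral * math.sin(angle)
        y = oy + r * math.sin(angle) + lateral * math.cos(angle)
        pts.append((x, y))
    line = LineString(pts)
    clipped = line.intersection(frame.buffer(-0.4))
    if clipped.is_empty or clipped.geom_type != "LineString":
        return line
    return clipped


def generate_scenario(config: ScenarioConfig) -> ScenarioBundle:
    """Deterministically generate the full geodata bundle for a seed."""
    rng = np.random.default_rng(config.seed)
    W = config.subdistrict_size_km
    mix_types, mix_probs = zip(*config.road_type_mix)

    villages: list[Village] = []
    roads: list[RoadSegment] = []
    hubs: list[Hub] = []
    facilities: list[HealthFacility] = []
    constraints: list[Constraint] = []
    island_ids: set[str] = set()

    for s in range(config.n_subdistricts):
        x0 = s * W
        frame = box(x0, 0.0, x0 + W, W)
        has_island = config.river and s == 0 and config.island_fraction > 0
        if has_island:
            xr = x0 + W * config.island_fraction
            river = box(xr - 0.25, -1.0, xr + 0.25, W + 1.0)
            mainland = box(xr + 0.25, 0.0, x0 + W, W)
        else:
            xr = None
            river = None
            mainland = frame

        fx = x0 + W * ((config.island_fraction + 1.0) / 2.0) if has_island else x0 + W / 2
        fy = W / 2
        facilities.append(
            HealthFacility(
                facility_id=f"uhc{s}", location=Point(fx, fy), level="UHC",
                name=f"Subdistrict {s} UHC",
            )
        )

        # --- villages: Voronoi partition of settlement seeds
        pts = []
        while len(pts) < config.villages_per_subdistrict:
            p = rng.uniform([x0 + 0.2, 0.2], [x0 + W - 0.2, W - 0.2])
            if river is not None and river.buffer(0.05).contains(Point(p)):
                continue
            pts.append(p)
        pts = np.array(pts)
        cells = _voronoi_cells(pts, frame)
        for i, cell in enumerate(cells):
            if river is not None:
                cell = cell.difference(river)
                if cell.geom_type == "MultiPolygon":
                    seed_pt = Point(pts[i])
                    cell = min(cell.geoms, key=lambda p: p.distance(seed_pt))
            pop = int(round(rng.lognormal(
                math.log(config.mean_village_population), 0.55)))
            vid = f"v{s}{i:03d}"
            villages.append(
                Village(
                    village_id=vid, name=f"Village {s}-{i}", boundary=cell,
                    population=max(pop, 40), households=max(pop, 40) // 5,
                    union_id=f"u{s}{i % 7}", upazila_id=f"s{s}",
                )
            )
            if has_island and pts[i][0] < xr - 0.25:
                island_ids.add(vid)

        # --- fixed corridors radiating from the headquarters
        n_cor = config.hubs_per_subdistrict
        base_angles = np.linspace(0.0, 2 * math.pi, n_cor, endpoint=False)
        base_angles = base_angles + rng.uniform(-0.15, 0.15, size=n_cor)
        n_fixed = max(1, int(round(config.fixed_route_fraction * n_cor)))
        corridors: list[LineString] = []
        for j, angle in enumerate(base_angles):
            # reach: distance to the mainland boundary along the ray, shy of it
            reach = 0.5 * W
            for r in np.linspace(0.5 * W, 1.5 * W, 60):
                probe = Point(fx + r * math.cos(angle), fy + r * math.sin(angle))
                if not mainland.contains(probe):
                    reach = max(2.0, r - 0.8)
                    break
            line = _corridor_line(rng, (fx, fy), float(angle), float(reach), mainland)
            is_fixed = j < n_fixed
            if is_fixed:
                road_type = "paved"
                unsafe = (
                    config.include_unsafe_corridor
                    and s == min(1, config.n_subdistricts - 1)
                    and j == n_fixed - 1
                )
                fixed_modes = (
                    frozenset({M.NASIMAN}) if unsafe
                    else frozenset({M.TEMPO if j % 2 == 0 else M.CNG})
                )
            else:
                road_type = str(rng.choice(mix_types, p=mix_probs))
                fixed_modes = frozenset()
            roads.append(
                RoadSegment(
                    segment_id=f"cor{s}{j}", geometry=line, road_type=road_type,
                    width_ft=float(rng.uniform(8.0, 14.0)),
                    fixed_route_modes=fixed_modes,
                )
            )
            corridors.append(line)
            end = line.coords[-1]
            hubs.append(
                Hub(hub_id=f"h{s}{j}", location=Point(end), kind="hub",
                    name=f"Market {s}-{j}")
            )
            mid = line.interpolate(0.5, normalized=True)
            # snap the sub-hub onto a corridor vertex so it sits on the graph
            mid_vertex = min(
                list(line.coords)[1:-1] or [end],
                key=lambda c: Point(c).distance(mid),
            )
            hubs.append(
                Hub(hub_id=f"sh{s}{j}", location=Point(mid_vertex),
                    kind="sub_hub", name=f"Stop {s}-{j}")
            )

        # --- village access roads to the nearest corridor
        narrow_candidates: list[RoadSegment] = []
        for vil in villages:
            if vil.upazila_id != f"s{s}" or vil.village_id in island_ids:
                continue
            c = vil.centroid
            near = min(corridors, key=lambda line: line.distance(c))
            snap = near.interpolate(near.project(c))
            if snap.distance(c) < 1e-6:
                continue
            narrow = rng.uniform() < config.narrow_road_fraction
            road_type = str(rng.choice(mix_types, p=mix_probs))
            seg = RoadSegment(
                segment_id=f"acc_{vil.village_id}",
                geometry=LineString([(c.x, c.y), (snap.x, snap.y)]),
                road_type=road_type,
                width_ft=4.0 if narrow else float(rng.uniform(5.5, 10.0)),
            )
            roads.append(seg)
            if not narrow and road_type == "unpaved":
                narrow_candidates.append(seg)

        # --- island side: ghats, boat crossings, island access roads
        if has_island:
            ghat_ys = (W / 3, 2 * W / 3)
            for g, gy in enumerate(ghat_ys):
                ig = (xr - 0.3, gy)
                mg = (xr + 0.3, gy)
                roads.append(
                    RoadSegment(
                        segment_id=f"boat{s}{g}",
                        geometry=LineString([ig, mg]),
                        road_type="waterway",
                    )
                )
                # mainland ghat feeds the corridor network by a paved link
                near = min(corridors, key=lambda line: line.distance(Point(mg)))
                snap = near.interpolate(near.project(Point(mg)))
                roads.append(
                    RoadSegment(
                        segment_id=f"ghlink{s}{g}",
                        geometry=LineString([mg, (snap.x, snap.y)]),
                        road_type="paved", width_ft=10.0,
                    )
                )
                hubs.append(
                    Hub(hub_id=f"hg{s}{g}", location=Point(ig), kind="hub",
                        name=f"Ghat {s}-{g}")
                )
                hubs.append(
                    Hub(hub_id=f"shg{s}{g}", location=Point(mg), kind="sub_hub",
                        name=f"Landing {s}-{g}")
                )
            for vil in villages:
                if vil.village_id not in island_ids:
                    continue
                c = vil.centroid
                gy = min(ghat_ys, key=lambda y: abs(y - c.y))
                roads.append(
                    RoadSegment(
                        segment_id=f"iacc_{vil.village_id}",
                        geometry=LineString([(c.x, c.y), (xr - 0.3, gy)]),
                        road_type="unpaved", width_ft=6.0,
                    )
                )

        if config.include_constraints and narrow_candidates:
            seg = min(narrow_candidates, key=lambda r: r.segment_id)
            constraints.append(
                Constraint(
                    constraint_id=f"bb{s}",
                    location=seg.geometry.interpolate(0.5, normalized=True),
                    kind="bamboo_bridge", effect="forces_walk",
                )
            )

    return ScenarioBundle(villages, roads, hubs, facilities, constraints,
                          island_ids)


# --------------------------------------------------------------------------
# Call-log generator


@dataclass(frozen=True)
class CallLogConfig:
    """Zone-conditional Bernoulli model of referral calls.

    Default probabilities mirror the published compliance table's empirical
    rates (compliance ~0.7-0.8 per zone; dispatched-transport use ~0.06 in
    the yellow zone, ~0.30 in the red, structurally zero in the green where
    the service did not operate); semester weights mirror its call volumes.
    """

    seed: int = 0
    n_calls: int = 1200
    referral_probability: float = 0.565
    compliance_probability_by_zone: tuple = (
        ("green", 0.77), ("yellow", 0.72), ("red", 0.69), ("excluded", 0.5),
    )
    ipsi_probability_by_zone: tuple = (("yellow", 0.06), ("red", 0.30))
    semester_weights: tuple = (0.39, 0.28, 0.25, 0.08)

    def __post_init__(self) -> None:
        for _z, p in self.compliance_probability_by_zone + self.ipsi_probability_by_zone:
            if not 0.0 <= p <= 1.0:
                raise GenerationError("probabilities must lie in [0, 1]")
        ipsi = dict(self.ipsi_probability_by_zone)
        if ipsi.get("green", 0.0) != 0.0:
            raise GenerationError(
                "green-zone transport-use probability is structurally zero"
            )
        if abs(sum(self.semester_weights) - 1.0) > 1e-9 or len(self.semester_weights) != 4:
            raise GenerationError("semester_weights must be 4 proportions summing to 1")


def generate_call_log(
    config: CallLogConfig,
    zone_assignments: dict[str, str],
    village_weights: dict[str, float] | None = None,
) -> list[CallRecord]:
    """Draw a seeded call log over zoned villages.

    Every drawn village must have a zone; used_ipsi implies complied by
    construction. Village draws are population-weighted when weights are
    given, uniform otherwise.
    """
    if not zone_assignments:
        raise ConsistencyError("zone assignments required")
    rng = np.random.default_rng(config.seed)
    village_ids = sorted(zone_assignments)
    if village_weights is not None:
        missing = [v for v in village_ids if v not in village_weights]
        if missing:
            raise ConsistencyError(f"missing weights for villages {missing[:3]}")
        w = np.array([village_weights[v] for v in village_ids], dtype=float)
        w = w / w.sum()
    else:
        w = None
    p_comply = dict(config.compliance_probability_by_zone)
    p_ipsi = dict(config.ipsi_probability_by_zone)
    records = []
    for i in range(config.n_calls):
        vid = str(rng.choice(village_ids, p=w))
        zone = str(getattr(zone_assignments[vid], "value", zone_assignments[vid]))
        if zone not in p_comply and zone != "excluded":
            raise ConsistencyError(f"village {vid}: no zone probability for {zone!r}")
        sem = int(rng.choice([1, 2, 3, 4], p=config.semester_weights))
        lo, hi = SEMESTER_WINDOWS[sem]
        date = lo + dt.timedelta(days=int(rng.integers(0, (hi - lo).days + 1)))
        referred = bool(rng.uniform() < config.referral_probability)
        complied = bool(referred and rng.uniform() < p_comply.get(zone, 0.5))
        used = bool(complied and rng.uniform() < p_ipsi.get(zone, 0.0))
        records.append(
            CallRecord(
                call_id=f"c{i:05d}", date=date, village_id=vid,
                referred=referred, complied=complied, used_ipsi=used,
                zone=zone,
            )
        )
    return records


# --------------------------------------------------------------------------
# Published-table fixtures


def _data_rows(name: str) -> list[dict]:
    with resources.files("refnet.data").joinpath(name).open() as fh:
        return list(csv.DictReader(fh))


@dataclass(frozen=True)
class TableFixtures:
    """The printed-data bundle: the speed table, the 17-route catalog, the
    zone summary rows, and the compliance table with its printed margins."""

    speed_table: SpeedTable
    routes: tuple
    zone_rows: tuple
    compliance_table: ComplianceTable
    #: Grand total population as printed; the zone rows sum to 306 fewer.
    printed_total_population: int = 0

    def zone_summary(self) -> list[ZoneSummaryRow]:
        """Summary recomputed (percent column, total row) from the printed
        per-zone populations."""
        return summary_from_counts(
            [(r["zone"], r["n_villages"], r["area_km2"], r["population"])
             for r in self.zone_rows]
        )

    def call_records(self) -> list[CallRecord]:
        """The compliance table expanded to one record per referred call
        (2,731 records), with deterministic dates inside each semester and
        one pseudo-village per zone."""
        records = []
        i = 0
        for (sem, complied, zone), cell in sorted(
            self.compliance_table.counts.items()
        ):
            lo, hi = SEMESTER_WINDOWS[sem]
            span = (hi - lo).days
            for k in range(cell.n):
                records.append(
                    CallRecord(
                        call_id=f"f{i:05d}",
                        date=lo + dt.timedelta(days=(7 * k) % (span + 1)),
                        village_id=f"fz_{zone}",
                        referred=True, complied=complied,
                        used_ipsi=k < cell.n_ipsi and complied,
                        zone=zone,
                    )
                )
                i += 1
        return records

    def full_call_log(self) -> list[CallRecord]:
        """The referred records padded to the call centre's full volume of
        4,830 calls: 2,090 non-referred calls (the published table does not
        break these down; they are synthetic padding spread over semesters
        in proportion to referred volume) and 9 referred calls whose
        village could not be ascertained."""
        records = self.call_records()
        referred_by_sem = {
            s: self.compliance_table.referred(s) for s in (1, 2, 3, 4)
        }
        total_ref = sum(referred_by_sem.values())
        n_pad = 4830 - total_ref - 9
        shares = {
            s: Fraction(n_pad * n, total_ref) for s, n in referred_by_sem.items()
        }
        alloc = {s: math.floor(f) for s, f in shares.items()}
        leftover = n_pad - sum(alloc.values())
        for s, _f in sorted(shares.items(), key=lambda kv: kv[1] - math.floor(kv[1]),
                            reverse=True)[:leftover]:
            alloc[s] += 1
        i = 0
        zones = ("green", "yellow", "red")
        for s in (1, 2, 3, 4):
            lo, hi = SEMESTER_WINDOWS[s]
            span = (hi - lo).days
            for k in range(alloc[s]):
                records.append(
                    CallRecord(
                        call_id=f"nr{i:05d}",
                        date=lo + dt.timedelta(days=(3 * k) % (span + 1)),
                        village_id=f"fz_{zones[k % 3]}",
                        referred=False, zone=zones[k % 3],
                    )
                )
                i += 1
        for k in range(9):
            records.append(
                CallRecord(
                    call_id=f"x{k:02d}", date=dt.date(2014, 1, 1 + k),
                    village_id=UNKNOWN_VILLAGE, referred=True,
                )
            )
        assert len(records) == 4830
        return records


def table_fixtures() -> TableFixtures:
    """Load the printed-table bundle packaged with the library."""
    routes = []
    for r in _data_rows("route_catalog.csv"):
        routes.append({
            "route_id": r["route_id"],
            "route_name": r["route_name"],
            "mode": r["mode"],
            "distance_km": float(r["distance_km"]),
            "time_min": float(r["time_min"]),
            "catchment_population": int(r["catchment_population"]),
            "active": bool(int(r["active"])),
            "effective_speed_kmh": (
                float(r["effective_speed_kmh"]) if r["effective_speed_kmh"] else None
            ),
            "single_mode_consistent": bool(int(r["single_mode_consistent"])),
        })
    zone_rows = [
        {
            "zone": r["zone"], "n_villages": int(r["n_villages"]),
            "area_km2": float(r["settlement_area_km2"]),
            "population": int(r["population"]),
        }
        for r in _data_rows("zone_summary.csv")
        if r["zone"] != "total"
    ]
    printed_total = next(
        int(r["population"]) for r in _data_rows("zone_summary.csv")
        if r["zone"] == "total"
    )
    counts = {
        (int(r["semester"]), bool(int(r["complied"])), r["zone"]):
        ZoneCount(int(r["n"]), int(r["n_ipsi"]))
        for r in _data_rows("call_counts.csv")
    }
    margins = {
        int(r["semester"]): (int(r["complied_n"]), int(r["ipsi_n"]))
        for r in _data_rows("call_margins.csv")
    }
    return TableFixtures(
        speed_table=SpeedTable.default(),
        routes=tuple(routes),
        zone_rows=tuple(zone_rows),
        compliance_table=ComplianceTable(counts, printed_semester_margins=margins),
        printed_total_population=printed_total,
    )
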
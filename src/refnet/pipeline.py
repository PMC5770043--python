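"""End-to-end pipeline: geodata -> network -> routes -> zones -> analytics.

A run is fully determined by its inputs and :class:`RunConfig`; identical
inputs and config produce byte-identical artifacts.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from ._util import round_half_up
from .errors import RefnetError
from .geodata import read_call_log, read_geodata
from .network_routing import (
    assign_catchments,
    build_network,
    build_route_catalog,
    write_route_catalog,
)
from .referral_analytics import analyze, drop_unresolved, tabulate
from .travel_time import SpeedTable
from .zoning import assign_zones, zone_summary

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Pipeline parameters.

    ``breaks`` are the zone cut minutes (green <= first < yellow <= second
    < red); ``coverage_threshold`` is the village-area share a band must
    cover to claim a straddling village; ``max_connector_km`` bounds the
    walking connector from a village centre to the network.
    """

    speed_table_path: str | None = None
    breaks: tuple[float, float] = (30.0, 50.0)
    coverage_threshold: float = 0.5
    max_connector_km: float = 5.0
    exclusion_list: tuple[str, ...] = ()
    manual_overrides: tuple[tuple[str, str], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        b1, b2 = self.breaks
        if not (0 < b1 < b2):
            raise ValueError("breaks must be ascending and positive")
        if not 0 < self.coverage_threshold <= 1:
            raise ValueError("coverage_threshold must lie in (0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Flat ``key = value`` config; lists comma-separated, overrides
        as ``village:route`` pairs."""
        kwargs: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "breaks":
                kwargs["breaks"] = tuple(float(x) for x in value.split(","))
            elif key in ("coverage_threshold", "max_connector_km"):
                kwargs[key] = float(value)
            elif key == "seed":
                kwargs[key] = int(value)
            elif key == "exclusion_list":
                kwargs[key] = tuple(x.strip() for x in value.split(",") if x.strip())
            elif key == "manual_overrides":
                kwargs[key] = tuple(
                    tuple(p.strip().split(":")) for p in value.split(",") if p.strip()
                )
            elif key == "speed_table_path":
                kwargs[key] = value or None
            else:
                raise ValueError(f"{path}: unknown config key {key!r}")
        return cls(**kwargs)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["manual_overrides"] = [list(p) for p in self.manual_overrides]
        d["exclusion_list"] = list(self.exclusion_list)
        return d


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except RefnetError as exc:
                raise type(exc)(f"[{name}] {exc}") from exc
        return wrapped
    return deco


def run_pipeline(
    config: RunConfig,
    geodata_dir: str | Path,
    calls_path: str | Path | None,
    out_dir: str | Path,
) -> Path:
    """Run every stage and write the artifact directory.

    Emits network_summary.json, routes.csv, catchments.csv, zones.csv,
    table3.csv, and — when a call log is given — table4.csv and stats.json,
    plus a manifest recording config and package version.
    """
    geodata_dir = Path(geodata_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    villages = read_geodata(geodata_dir / "villages.geojson", "villages")
    roads = read_geodata(geodata_dir / "roads.geojson", "roads")
    hubs = read_geodata(geodata_dir / "hubs.geojson", "hubs")
    facilities = read_geodata(geodata_dir / "facilities.geojson", "facilities")
    constraints_path = geodata_dir / "constraints.geojson"
    constraints = (
        read_geodata(constraints_path, "constraints")
        if constraints_path.exists() else []
    )

    speed_table = (
        SpeedTable.from_config(config.speed_table_path,
                               base=SpeedTable.with_nasiman())
        if config.speed_table_path else SpeedTable.with_nasiman()
    )

    network = _stage("build_network")(build_network)(
        villages, roads, constraints=constraints, speed_table=speed_table,
        max_connector_km=config.max_connector_km,
    )
    routes = _stage("route_catalog")(build_route_catalog)(
        network, hubs, facilities
    )
    catchments = _stage("assign_catchments")(assign_catchments)(
        routes, villages, network,
        exclusion_list=config.exclusion_list,
        manual_overrides=dict(config.manual_overrides),
    )
    zones = _stage("zoning")(assign_zones)(
        network, villages, facilities, breaks=config.breaks,
        exclusion_list=config.exclusion_list,
        coverage_threshold=config.coverage_threshold,
    )
    summary = zone_summary(villages, zones, config.exclusion_list)

    n_excluded = sum(1 for r in routes if not r.active)
    logger.info(
        "network: %d vertices, %d edges; %d routes (%d excluded as unsafe)",
        network.graph.number_of_nodes(), network.graph.number_of_edges(),
        len(routes), n_excluded,
    )

    with open(out / "network_summary.json", "w") as fh:
        json.dump({
            "n_vertices": network.graph.number_of_nodes(),
            "n_edges": network.graph.number_of_edges(),
            "n_villages": len(villages),
            "n_routes": len(routes),
            "n_routes_active": sum(r.active for r in routes),
            "total_population": sum(v.population for v in villages),
        }, fh, indent=1, sort_keys=True)
        fh.write("\n")

    write_route_catalog(routes, out / "routes.csv")

    with open(out / "catchments.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["village_id", "route_id", "pickup_id", "access_min"])
        for vid in sorted(catchments):
            a = catchments[vid]
            w.writerow([a.village_id, a.route_id, a.pickup_id,
                        f"{round_half_up(a.access_min, 2):.2f}"])

    with open(out / "zones.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["village_id", "zone"])
        for vid in sorted(zones):
            w.writerow([vid, zones[vid].value])

    with open(out / "table3.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["zone", "n_villages", "settlement_area_km2", "population",
                    "population_pct"])
        for row in summary:
            w.writerow([row.zone, row.n_villages,
                        f"{row.settlement_area_km2:.2f}", row.population,
                        row.population_pct])

    if calls_path is not None:
        records = _stage("read_calls")(read_call_log)(calls_path)
        kept, n_dropped = drop_unresolved(records)
        zoned = []
        for r in kept:
            zone = zones.get(r.village_id)
            zoned.append(r.with_zone(zone.value if zone else r.zone))
        referred = [r for r in zoned if r.referred and r.zone is not None]
        table = _stage("tabulate")(tabulate)(referred)
        stats = analyze(table)
        stats["n_calls_total"] = len(records)
        stats["n_dropped_unresolved"] = n_dropped
        with open(out / "stats.json", "w") as fh:
            json.dump(stats, fh, indent=1, sort_keys=True)
            fh.write("\n")
        with open(out / "table4.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["semester", "complied", "zone", "n", "n_ipsi"])
            for (sem, complied, zone), cell in sorted(table.counts.items()):
                w.writerow([sem, int(complied), zone, cell.n, cell.n_ipsi])

    with open(out / "manifest.json", "w") as fh:
        json.dump({
            "package": "refnet",
            "version": __version__,
            "config": config.as_dict(),
        }, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return out
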
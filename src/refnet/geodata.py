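"""Domain types and GeoJSON/CSV readers and writers.

All geometry lives on a planar projected plane with kilometre units. Files
must declare this in a top-level ``coordinate_system`` member of the
FeatureCollection; geographic (lon/lat) inputs are rejected rather than
silently projected, because every distance in the travel-time model is a
ground distance.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from shapely.geometry import LineString, Point, Polygon, mapping, shape

from .errors import (
    ConsistencyError,
    CoordinateSystemError,
    DateRangeError,
    SchemaError,
)

__all__ = [
    "TransportMode",
    "UNSAFE_MODES",
    "ROAD_TYPES",
    "Village",
    "RoadSegment",
    "Hub",
    "HealthFacility",
    "Constraint",
    "CallRecord",
    "read_geodata",
    "write_geodata",
    "read_call_log",
    "write_call_log",
    "semester_of",
    "SEMESTER_WINDOWS",
]


class TransportMode(str, Enum):
    """Locally available modes of patient transport.

    ``nasiman`` (an improvised motorised three-wheeler) is part of the road
    network but flagged unsafe for patient transport and never dispatched.
    """

    RICKSHAW = "rickshaw"
    TEMPO = "tempo"
    CNG = "cng"
    WALK = "walk"
    BOAT = "boat"
    NASIMAN = "nasiman"


#: Modes that may appear on the network but are never used to move patients.
UNSAFE_MODES = frozenset({TransportMode.NASIMAN})

#: Vehicle modes that run on fixed road corridors.
FIXED_ROUTE_MODES = frozenset(
    {TransportMode.TEMPO, TransportMode.CNG, TransportMode.NASIMAN}
)

ROAD_TYPES = ("paved", "herringbone", "unpaved", "waterway")

#: Minimum road width (feet) passable by any wheeled vehicle.
MIN_VEHICLE_WIDTH_FT = 5.0


@dataclass(frozen=True)
class Village:
    """A settlement polygon carrying census population; the routing origin
    and the unit of zone assignment."""

    village_id: str
    name: str
    boundary: Polygon
    population: int
    households: int = 0
    union_id: str = ""
    upazila_id: str = ""

    def __post_init__(self) -> None:
        if self.boundary.is_empty or not self.boundary.is_valid:
            raise SchemaError(f"village {self.village_id}: invalid boundary polygon")
        if self.boundary.area <= 0:
            raise SchemaError(f"village {self.village_id}: zero-area boundary")
        if self.population < 0 or self.households < 0:
            raise SchemaError(f"village {self.village_id}: negative population")

    @property
    def centroid(self) -> Point:
        """Geometric centroid of the boundary (the routing origin)."""
        c = self.boundary.centroid
        if not self.boundary.covers(c):
            # non-convex boundary: fall back to a representative interior point
            c = self.boundary.representative_point()
        return c

    @property
    def area_km2(self) -> float:
        return self.boundary.area


@dataclass(frozen=True)
class RoadSegment:
    """A road or waterway polyline, the source of network edges."""

    segment_id: str
    geometry: LineString
    road_type: str
    width_ft: float | None = None
    fixed_route_modes: frozenset = frozenset()
    length_km: float | None = None

    def __post_init__(self) -> None:
        if self.road_type not in ROAD_TYPES:
            raise SchemaError(
                f"segment {self.segment_id}: unknown road_type {self.road_type!r} "
                f"(expected one of {ROAD_TYPES})"
            )
        modes = frozenset(TransportMode(m) for m in self.fixed_route_modes)
        object.__setattr__(self, "fixed_route_modes", modes)
        if self.road_type == "waterway":
            if self.width_ft is not None:
                raise SchemaError(
                    f"segment {self.segment_id}: waterway must not carry width_ft"
                )
            if modes:
                raise SchemaError(
                    f"segment {self.segment_id}: waterway cannot host fixed routes"
                )
        else:
            if self.width_ft is None or self.width_ft <= 0:
                raise SchemaError(
                    f"segment {self.segment_id}: road requires positive width_ft"
                )
            if modes and self.road_type != "paved":
                raise SchemaError(
                    f"segment {self.segment_id}: fixed-route services run on "
                    f"paved roads only"
                )
        if not modes <= FIXED_ROUTE_MODES:
            raise SchemaError(
                f"segment {self.segment_id}: fixed_route_modes must be a subset "
                f"of {{tempo, cng, nasiman}}"
            )
        true_len = self.geometry.length
        if self.length_km is None:
            object.__setattr__(self, "length_km", true_len)
        elif abs(self.length_km - true_len) > 1e-6:
            raise SchemaError(
                f"segment {self.segment_id}: declared length {self.length_km} km "
                f"disagrees with geometry length {true_len:.6f} km"
            )


@dataclass(frozen=True)
class Hub:
    """A vehicle pick-up point. ``hub`` anchors a fixed transport route at
    its community end; ``sub_hub`` is an intermediate boarding stop."""

    hub_id: str
    location: Point
    kind: str = "hub"
    name: str = ""
    route_ids: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in ("hub", "sub_hub"):
            raise SchemaError(f"hub {self.hub_id}: kind must be hub or sub_hub")
        object.__setattr__(self, "route_ids", tuple(self.route_ids))


@dataclass(frozen=True)
class HealthFacility:
    """A routing destination; one subdistrict hospital (UHC) per subdistrict."""

    facility_id: str
    location: Point
    level: str = "UHC"
    name: str = ""

    def __post_init__(self) -> None:
        if self.level not in ("UHC", "district", "union_clinic"):
            raise SchemaError(
                f"facility {self.facility_id}: unknown level {self.level!r}"
            )


@dataclass(frozen=True)
class Constraint:
    """A point constraint on the network: a single-pole bamboo bridge forces
    walking; a natural barrier blocks vehicle passage altogether."""

    constraint_id: str
    location: Point
    kind: str
    effect: str

    def __post_init__(self) -> None:
        if self.kind not in ("bamboo_bridge", "natural_barrier"):
            raise SchemaError(f"constraint {self.constraint_id}: unknown kind")
        if self.effect not in ("forces_walk", "blocks_passage"):
            raise SchemaError(f"constraint {self.constraint_id}: unknown effect")
        if self.effect == "forces_walk" and self.kind != "bamboo_bridge":
            raise SchemaError(
                f"constraint {self.constraint_id}: forces_walk applies only to "
                f"bamboo bridges"
            )


# --------------------------------------------------------------------------
# Call records

#: Operational window of the call centre and its four six-month semesters.
SEMESTER_WINDOWS = {
    1: (dt.date(2013, 10, 1), dt.date(2014, 3, 31)),
    2: (dt.date(2014, 4, 1), dt.date(2014, 9, 30)),
    3: (dt.date(2014, 10, 1), dt.date(2015, 3, 31)),
    4: (dt.date(2015, 4, 1), dt.date(2015, 9, 30)),
}

#: Village id used for calls whose village/zone could not be ascertained.
UNKNOWN_VILLAGE = "unknown"


def semester_of(date: dt.date) -> int:
    """Six-month semester index (1-4) of a call date, by calendar month."""
    for sem, (lo, hi) in SEMESTER_WINDOWS.items():
        if lo <= date <= hi:
            return sem
    raise DateRangeError(
        f"date {date.isoformat()} outside the Oct 2013 - Sep 2015 window"
    )


@dataclass(frozen=True)
class CallRecord:
    """One call to the referral centre.

    The flags nest: a call may be referred; a referred caller may comply;
    a compliant caller may use the project's dispatched transport.
    """

    call_id: str
    date: dt.date
    village_id: str
    referred: bool
    complied: bool = False
    used_ipsi: bool = False
    zone: str | None = None
    semester: int | None = None

    def __post_init__(self) -> None:
        if self.used_ipsi and not self.complied:
            raise ConsistencyError(
                f"call {self.call_id}: used_ipsi=1 requires complied=1"
            )
        if self.complied and not self.referred:
            raise ConsistencyError(
                f"call {self.call_id}: complied=1 requires referred=1"
            )
        sem = semester_of(self.date)
        if self.semester is None:
            object.__setattr__(self, "semester", sem)
        elif self.semester != sem:
            raise ConsistencyError(
                f"call {self.call_id}: semester {self.semester} inconsistent "
                f"with date {self.date.isoformat()} (semester {sem})"
            )

    def with_zone(self, zone: str) -> "CallRecord":
        return replace(self, zone=zone)


# --------------------------------------------------------------------------
# GeoJSON I/O

_LAYER_TYPES = {
    "villages": Village,
    "roads": RoadSegment,
    "hubs": Hub,
    "facilities": HealthFacility,
    "constraints": Constraint,
}

_PLANAR_KM = {"kind": "planar", "units": "km"}


def _looks_geographic(coords: list) -> bool:
    xs, ys = zip(*coords)
    return all(-180 <= x <= 180 for x in xs) and all(-90 <= y <= 90 for y in ys)


def _feature_to_object(layer_kind: str, feat: dict):
    props = dict(feat.get("properties") or {})
    geom = shape(feat["geometry"])
    fid = feat.get("id") or props.get(
        {"villages": "village_id", "roads": "segment_id", "hubs": "hub_id",
         "facilities": "facility_id", "constraints": "constraint_id"}[layer_kind],
        "<missing id>",
    )

    def req(key):
        if key not in props or props[key] is None:
            raise SchemaError(
                f"{layer_kind} feature {fid}: missing required property {key!r}"
            )
        return props[key]

    if layer_kind == "villages":
        return Village(
            village_id=str(req("village_id")),
            name=str(props.get("name", "")),
            boundary=geom,
            population=int(req("population")),
            households=int(props.get("households", 0)),
            union_id=str(props.get("union_id", "")),
            upazila_id=str(props.get("upazila_id", "")),
        )
    if layer_kind == "roads":
        width = props.get("width_ft")
        return RoadSegment(
            segment_id=str(req("segment_id")),
            geometry=geom,
            road_type=str(req("road_type")),
            width_ft=float(width) if width is not None else None,
            fixed_route_modes=frozenset(props.get("fixed_route_modes") or ()),
        )
    if layer_kind == "hubs":
        return Hub(
            hub_id=str(req("hub_id")),
            location=geom,
            kind=str(req("kind")),
            name=str(props.get("name", "")),
            route_ids=tuple(props.get("route_ids") or ()),
        )
    if layer_kind == "facilities":
        return HealthFacility(
            facility_id=str(req("facility_id")),
            location=geom,
            level=str(req("level")),
            name=str(props.get("name", "")),
        )
    if layer_kind == "constraints":
        return Constraint(
            constraint_id=str(req("constraint_id")),
            location=geom,
            kind=str(req("kind")),
            effect=str(req("effect")),
        )
    raise ValueError(f"unknown layer kind {layer_kind!r}")


def read_geodata(path: str | Path, layer_kind: str) -> list:
    """Read a GeoJSON FeatureCollection into a list of domain objects.

    The file must carry ``"coordinate_system": {"kind": "planar",
    "units": "km"}`` at the top level; collections without it — including
    ordinary lon/lat GeoJSON — are rejected with a coordinate-system error.
    """
    if layer_kind not in _LAYER_TYPES:
        raise ValueError(f"unknown layer kind {layer_kind!r}")
    with open(path) as fh:
        doc = json.load(fh)
    cs = doc.get("coordinate_system")
    if cs != _PLANAR_KM:
        hint = ""
        features = doc.get("features", [])
        if features:
            try:
                geom = shape(features[0]["geometry"])
                minx, miny, maxx, maxy = geom.bounds
                if _looks_geographic([(minx, miny), (maxx, maxy)]):
                    hint = " (coordinates look like lon/lat; reproject to a planar km grid)"
            except Exception:
                pass
        raise CoordinateSystemError(
            f"{path}: missing or non-planar coordinate_system declaration{hint}"
        )
    return [_feature_to_object(layer_kind, f) for f in doc.get("features", [])]


def _object_to_feature(obj) -> dict:
    if isinstance(obj, Village):
        geom, props = obj.boundary, {
            "village_id": obj.village_id, "name": obj.name,
            "population": obj.population, "households": obj.households,
            "union_id": obj.union_id, "upazila_id": obj.upazila_id,
        }
    elif isinstance(obj, RoadSegment):
        geom, props = obj.geometry, {
            "segment_id": obj.segment_id, "road_type": obj.road_type,
            "width_ft": obj.width_ft,
            "fixed_route_modes": sorted(m.value for m in obj.fixed_route_modes),
        }
    elif isinstance(obj, Hub):
        geom, props = obj.location, {
            "hub_id": obj.hub_id, "kind": obj.kind, "name": obj.name,
            "route_ids": list(obj.route_ids),
        }
    elif isinstance(obj, HealthFacility):
        geom, props = obj.location, {
            "facility_id": obj.facility_id, "level": obj.level, "name": obj.name,
        }
    elif isinstance(obj, Constraint):
        geom, props = obj.location, {
            "constraint_id": obj.constraint_id, "kind": obj.kind,
            "effect": obj.effect,
        }
    else:
        raise TypeError(f"cannot serialise {type(obj).__name__}")
    return {"type": "Feature", "geometry": mapping(geom), "properties": props}


_KIND_OF_TYPE = {v: k for k, v in _LAYER_TYPES.items()}


def write_geodata(collection: Sequence, path: str | Path) -> None:
    """Write domain objects as a GeoJSON FeatureCollection (planar km)."""
    collection = list(collection)
    if not collection:
        raise SchemaError("refusing to write an empty collection")
    kinds = {type(o) for o in collection}
    if len(kinds) > 1 or next(iter(kinds)) not in _KIND_OF_TYPE:
        raise SchemaError("collection must be homogeneous domain objects")
    doc = {
        "type": "FeatureCollection",
        "coordinate_system": dict(_PLANAR_KM),
        "layer_kind": _KIND_OF_TYPE[next(iter(kinds))],
        "features": [_object_to_feature(o) for o in collection],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


# --------------------------------------------------------------------------
# Call-log CSV I/O

_CALL_COLUMNS = ["call_id", "date", "village_id", "referred", "complied", "used_ipsi"]


def _flag(value, *, call_id: str, column: str, allow_empty: bool) -> bool:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        if allow_empty:
            return False
        raise SchemaError(f"call {call_id}: column {column} must be 0 or 1")
    iv = int(value)
    if iv not in (0, 1):
        raise SchemaError(f"call {call_id}: column {column} must be 0 or 1")
    return bool(iv)


def read_call_log(path: str | Path) -> list[CallRecord]:
    """Read and validate the referral-call CSV.

    Columns: call_id, date (ISO-8601), village_id, referred (0/1),
    complied (0/1, empty allowed when referred=0), used_ipsi (0/1, empty
    allowed when complied!=1). Validation enforces the nesting
    used_ipsi => complied => referred and the operational date window.
    """
    df = pd.read_csv(path, dtype={"call_id": str, "village_id": str})
    missing = [c for c in _CALL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: call log missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        cid = str(row.call_id)
        date = dt.date.fromisoformat(str(row.date))
        referred = _flag(row.referred, call_id=cid, column="referred", allow_empty=False)
        complied = _flag(row.complied, call_id=cid, column="complied", allow_empty=True)
        used = _flag(row.used_ipsi, call_id=cid, column="used_ipsi", allow_empty=True)
        records.append(
            CallRecord(
                call_id=cid, date=date, village_id=str(row.village_id),
                referred=referred, complied=complied, used_ipsi=used,
            )
        )
    return records


def write_call_log(records: Iterable[CallRecord], path: str | Path) -> None:
    """Write call records in the schema accepted by :func:`read_call_log`."""
    rows = []
    for r in records:
        rows.append({
            "call_id": r.call_id,
            "date": r.date.isoformat(),
            "village_id": r.village_id,
            "referred": int(r.referred),
            "complied": int(r.complied) if r.referred else "",
            "used_ipsi": int(r.used_ipsi) if r.complied else "",
        })
    pd.DataFrame(rows, columns=_CALL_COLUMNS).to_csv(path, index=False)
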
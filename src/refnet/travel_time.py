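"""The travel-time cost model: field-measured speeds per (mode, road type),
the 5-ft road-width accessibility rule, and segment/path time computation.

Times follow t = 60 * L / v with L in km and v in km/h. Speeds were measured
by GPS on the actual vehicles; they are deterministic constants, not
distributions — congestion and boarding delays are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import UndefinedSpeedError
from .geodata import (
    MIN_VEHICLE_WIDTH_FT,
    ROAD_TYPES,
    RoadSegment,
    TransportMode,
)

__all__ = [
    "SpeedTable",
    "DEFAULT_SPEEDS",
    "NASIMAN_SPEED_KMH",
    "lookup_speed",
    "applicable_modes",
    "segment_time",
    "path_time",
]

M = TransportMode

#: Measured speeds (km/h) by mode and road type. Walking applies to every
#: non-waterway road type at a flat 4 km/h; pairs not listed are undefined
#: (a CNG cannot run on an unpaved road).
DEFAULT_SPEEDS: dict[tuple[TransportMode, str], float] = {
    (M.RICKSHAW, "paved"): 8.05,
    (M.RICKSHAW, "herringbone"): 8.55,
    (M.RICKSHAW, "unpaved"): 7.10,
    (M.TEMPO, "paved"): 12.64,
    (M.CNG, "paved"): 20.40,
    (M.WALK, "paved"): 4.00,
    (M.WALK, "herringbone"): 4.00,
    (M.WALK, "unpaved"): 4.00,
    (M.BOAT, "waterway"): 8.00,
}

#: Nasiman speed is absent from the measured table; it is back-derived from
#: the one catalogued nasiman corridor (8.34 km in 39.61 min) and kept only
#: so that nasiman corridors receive a travel time before being excluded
#: from dispatch as unsafe.
NASIMAN_SPEED_KMH = 12.63

#: Canonical mode ordering used for "ordered set" results and tie-breaks:
#: faster vehicles first, walking last.
MODE_ORDER = (M.CNG, M.TEMPO, M.NASIMAN, M.RICKSHAW, M.BOAT, M.WALK)


@dataclass(frozen=True)
class SpeedTable:
    """Mapping (mode, road type) -> km/h.

    The default entries are the measured constants above, bit-exact; a table
    may be overridden from a flat config file with ``mode.road_type = kmh``
    lines.
    """

    entries: Mapping[tuple[TransportMode, str], float] = field(
        default_factory=lambda: dict(DEFAULT_SPEEDS)
    )

    def __post_init__(self) -> None:
        for (mode, road_type), v in self.entries.items():
            if v <= 0:
                raise ValueError(f"non-positive speed for ({mode.value}, {road_type})")

    @classmethod
    def default(cls) -> "SpeedTable":
        return cls()

    @classmethod
    def with_nasiman(cls) -> "SpeedTable":
        """Default table extended with the back-derived nasiman speed."""
        entries = dict(DEFAULT_SPEEDS)
        entries[(M.NASIMAN, "paved")] = NASIMAN_SPEED_KMH
        return cls(entries)

    @classmethod
    def from_config(cls, path: str | Path, *, base: "SpeedTable | None" = None) -> "SpeedTable":
        """Load overrides from ``mode.road_type = km/h`` lines; '#' comments."""
        entries = dict((base or cls.default()).entries)
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            mode_name, _, road_type = key.strip().partition(".")
            mode = TransportMode(mode_name.strip())
            road_type = road_type.strip()
            if road_type not in ROAD_TYPES:
                raise ValueError(f"{path}: unknown road type {road_type!r}")
            entries[(mode, road_type)] = float(value.strip())
        return cls(entries)

    def speed(self, mode: TransportMode, road_type: str) -> float:
        try:
            return self.entries[(TransportMode(mode), road_type)]
        except KeyError:
            raise UndefinedSpeedError(
                f"no speed defined for ({TransportMode(mode).value}, {road_type})"
            ) from None

    def defines(self, mode: TransportMode, road_type: str) -> bool:
        return (TransportMode(mode), road_type) in self.entries


def lookup_speed(
    mode: TransportMode, road_type: str, table: SpeedTable | None = None
) -> float:
    """Tabulated speed in km/h; undefined pairs raise UndefinedSpeedError."""
    return (table or SpeedTable.default()).speed(mode, road_type)


def applicable_modes(
    segment: RoadSegment, constraint_effect: str | None = None
) -> tuple[TransportMode, ...]:
    """Modes that may traverse a segment, fastest first.

    Waterways carry boats only. Roads under 5 ft wide are impassable to
    vehicles, so only walking applies. Wider roads take rickshaws (available
    everywhere, no fixed stations) and walking, plus any fixed-route vehicle
    service (tempo/CNG/nasiman) running on that corridor. A bamboo-bridge
    constraint forces walking; a natural barrier blocks vehicles.
    """
    if segment.road_type == "waterway":
        modes = {M.BOAT}
    elif segment.width_ft is not None and segment.width_ft < MIN_VEHICLE_WIDTH_FT:
        modes = {M.WALK}
    else:
        modes = {M.RICKSHAW, M.WALK} | set(segment.fixed_route_modes)
    if constraint_effect == "forces_walk":
        modes = {M.WALK} if M.WALK in modes or segment.road_type != "waterway" else set()
    elif constraint_effect == "blocks_passage":
        modes &= {M.WALK}
    return tuple(m for m in MODE_ORDER if m in modes)


def segment_time(
    length_km: float,
    mode: TransportMode,
    road_type: str,
    table: SpeedTable | None = None,
) -> float:
    """Traversal time in minutes: 60 * length / speed."""
    if length_km < 0:
        raise ValueError("negative segment length")
    return 60.0 * length_km / lookup_speed(mode, road_type, table)


def path_time(
    legs: Iterable[Sequence], table: SpeedTable | None = None
) -> float:
    """Total minutes over ordered (length_km, mode, road_type) legs.

    Additive over concatenation; any leg with an undefined speed pair raises.
    """
    return sum(segment_time(l, m, r, table) for (l, m, r) in legs)
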
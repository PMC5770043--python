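"""Call-centre referral analytics: compliance and transport-uptake rates
stratified by semester and travel-time zone.

The atoms are referred calls; the statistics are descriptive rates:

* compliance rate  = complied / referred
* transport (IPSI) usage rate = used / complied
* zone share of compliance = zone's complied / semester's complied total
* red:yellow usage ratio = red used / yellow used (counts)
* utilisation trend = per-semester usage rates and their pairwise ratios

Rates are rounded half-up on the exact rational value: 1 decimal for
percents, 2 for ratios, 0 for the headline usage figure.

Published compliance tables occasionally print marginal totals that
disagree with their own zone breakdown by a record or two. A
:class:`ComplianceTable` can therefore carry explicit printed semester
margins; semester-level statistics then use the margins while zone-level
statistics use the zone counts, which is how the published derived figures
are internally computed. Tables built by :func:`tabulate` always derive
margins from the zone counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable

from ._util import percent, ratio, round_half_up
from .errors import ConsistencyError
from .geodata import UNKNOWN_VILLAGE, CallRecord

__all__ = [
    "ComplianceTable",
    "tabulate",
    "drop_unresolved",
    "compliance_rate",
    "refusal_rate",
    "ipsi_usage_rate",
    "zone_share_of_compliance",
    "usage_ratio_red_yellow",
    "utilisation_trend",
    "TrendResult",
    "analyze",
]

logger = logging.getLogger(__name__)

SEMESTERS = (1, 2, 3, 4)
ZONES = ("green", "yellow", "red", "excluded")


@dataclass(frozen=True)
class ZoneCount:
    n: int
    n_ipsi: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_ipsi <= self.n:
            raise ConsistencyError("n_ipsi must lie in [0, n]")


@dataclass
class ComplianceTable:
    """Counts of referred calls by (semester, complied, zone), with the
    dispatched-transport usage count nested under the complied cells."""

    counts: dict[tuple[int, bool, str], ZoneCount] = field(default_factory=dict)
    #: Optional printed margins: semester -> (complied_n, ipsi_used_n).
    printed_semester_margins: dict[int, tuple[int, int]] | None = None

    def _cells(self, semester=None, complied=None, zone=None):
        for (s, c, z), cell in self.counts.items():
            if semester is not None and s != semester:
                continue
            if complied is not None and c != complied:
                continue
            if zone is not None and z != zone:
                continue
            yield cell

    def referred(self, semester=None, zone=None) -> int:
        return sum(c.n for c in self._cells(semester, None, zone))

    def complied(self, semester=None, zone=None) -> int:
        if zone is None and semester is not None and self.printed_semester_margins:
            if semester in self.printed_semester_margins:
                return self.printed_semester_margins[semester][0]
        if zone is None and semester is None and self.printed_semester_margins:
            return sum(m[0] for m in self.printed_semester_margins.values())
        return sum(c.n for c in self._cells(semester, True, zone))

    def ipsi_used(self, semester=None, zone=None) -> int:
        if zone is None and semester is not None and self.printed_semester_margins:
            if semester in self.printed_semester_margins:
                return self.printed_semester_margins[semester][1]
        if zone is None and semester is None and self.printed_semester_margins:
            return sum(m[1] for m in self.printed_semester_margins.values())
        return sum(c.n_ipsi for c in self._cells(semester, True, zone))

    def cell(self, semester: int, complied: bool, zone: str) -> ZoneCount:
        return self.counts.get((semester, complied, zone), ZoneCount(0, 0))


def drop_unresolved(
    records: Iterable[CallRecord],
) -> tuple[list[CallRecord], int]:
    """Drop calls whose village (hence zone) could not be ascertained,
    logging how many were removed."""
    kept, dropped = [], 0
    for r in records:
        if r.village_id == UNKNOWN_VILLAGE or (r.zone is None and r.village_id == ""):
            dropped += 1
        else:
            kept.append(r)
    if dropped:
        logger.info("dropped %d call(s) with unresolvable village/zone", dropped)
    return kept, dropped


def tabulate(calls: Iterable[CallRecord]) -> ComplianceTable:
    """Tabulate referred calls into a compliance table.

    Order- and batch-invariant; the grand total equals the record count.
    Every record must be referred and carry a zone ('excluded' is a valid
    zone for calls from villages outside the intervention).
    """
    counts: dict[tuple[int, bool, str], list[int]] = {}
    n_records = 0
    for r in calls:
        if not r.referred:
            raise ConsistencyError(
                f"call {r.call_id}: tabulate expects referred records only"
            )
        zone = r.zone if isinstance(r.zone, str) else getattr(r.zone, "value", None)
        if zone not in ZONES:
            raise ConsistencyError(f"call {r.call_id}: unknown zone {r.zone!r}")
        key = (int(r.semester), bool(r.complied), zone)
        cell = counts.setdefault(key, [0, 0])
        cell[0] += 1
        cell[1] += int(r.used_ipsi)
        n_records += 1
    table = ComplianceTable(
        {k: ZoneCount(n, u) for k, (n, u) in sorted(counts.items())}
    )
    assert table.referred() == n_records
    return table


def compliance_rate(
    table: ComplianceTable, semester: int | None = None, zone: str | None = None
) -> float:
    """Percent of referred calls that complied, half-up at 1 decimal."""
    denom = table.referred(semester, zone)
    if denom == 0:
        raise ZeroDivisionError("no referred calls in scope")
    return percent(table.complied(semester, zone), denom)


def refusal_rate(
    table: ComplianceTable, semester: int | None = None, zone: str | None = None
) -> float:
    """100 minus the compliance rate, on the same denominator."""
    return round_half_up(
        Fraction(100) - Fraction(str(compliance_rate(table, semester, zone))), 1
    )


def ipsi_usage_rate(
    table: ComplianceTable,
    semester: int | None = None,
    zone: str | None = None,
    dp: int = 1,
) -> float:
    """Percent of compliant callers who used the dispatched transport."""
    denom = table.complied(semester, zone)
    if denom == 0:
        raise ZeroDivisionError("no compliant calls in scope")
    return percent(table.ipsi_used(semester, zone), denom, dp=dp)


def zone_share_of_compliance(
    table: ComplianceTable, semester: int, zone: str
) -> float:
    """A zone's complied calls as a percent of the semester's complied
    total (the total includes excluded-zone records)."""
    denom = table.complied(semester)
    if denom == 0:
        raise ZeroDivisionError(f"semester {semester}: no compliant calls")
    return percent(table.complied(semester, zone), denom)


def usage_ratio_red_yellow(table: ComplianceTable, semester: int) -> float:
    """Red-zone over yellow-zone transport-use counts, 2 decimals."""
    yellow = table.ipsi_used(semester, "yellow")
    if yellow == 0:
        raise ZeroDivisionError(f"semester {semester}: no yellow-zone usage")
    return ratio(table.ipsi_used(semester, "red"), yellow)


@dataclass(frozen=True)
class TrendResult:
    """Per-semester usage percents, pairwise ratios of the last semester to
    each earlier one, and successive first-differences (positive = rise)."""

    usage_pct: dict[int, float]
    last_vs: dict[int, float]
    successive_diff: dict[tuple[int, int], float]


def utilisation_trend(table: ComplianceTable) -> TrendResult:
    """Usage-rate trajectory across semesters, on exact fractions."""
    exact: dict[int, Fraction] = {}
    for s in SEMESTERS:
        denom = table.complied(s)
        if denom == 0:
            raise ZeroDivisionError(f"semester {s}: no compliant calls")
        exact[s] = Fraction(table.ipsi_used(s), denom)
    last = SEMESTERS[-1]
    return TrendResult(
        usage_pct={s: round_half_up(100 * f, 1) for s, f in exact.items()},
        last_vs={
            s: ratio(exact[last], exact[s]) for s in SEMESTERS if s != last
        },
        successive_diff={
            (a, b): round_half_up(100 * (exact[b] - exact[a]), 1)
            for a, b in zip(SEMESTERS, SEMESTERS[1:])
        },
    )


def analyze(table: ComplianceTable) -> dict:
    """The full descriptive statistic set as a JSON-serialisable dict."""
    trend = utilisation_trend(table)
    stats: dict = {
        "n_referred": table.referred(),
        "n_complied": table.complied(),
        "n_ipsi_used": table.ipsi_used(),
        "compliance_pct": compliance_rate(table),
        "refusal_pct": refusal_rate(table),
        "ipsi_usage_pct": ipsi_usage_rate(table, dp=0),
        "usage_pct_by_semester": trend.usage_pct,
        "usage_last_vs_semester": trend.last_vs,
        "usage_successive_diff": {
            f"S{a}_to_S{b}": v for (a, b), v in trend.successive_diff.items()
        },
    }
    for s in SEMESTERS:
        for z in ("green", "yellow", "red"):
            if table.referred(s, z):
                stats[f"compliance_pct_S{s}_{z}"] = compliance_rate(table, s, z)
            if table.complied(s, z):
                stats[f"zone_share_pct_S{s}_{z}"] = zone_share_of_compliance(
                    table, s, z
                )
        if table.ipsi_used(s, "yellow"):
            stats[f"usage_ratio_red_yellow_S{s}"] = usage_ratio_red_yellow(table, s)
    # zone compliance change, first to last semester (the published trend
    # quantities; computed under this package's conventions)
    for z in ("green", "yellow", "red"):
        first = compliance_rate(table, 1, z)
        last = compliance_rate(table, 4, z)
        stats[f"compliance_change_pts_{z}"] = round_half_up(
            Fraction(str(last)) - Fraction(str(first)), 1
        )
    return stats
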
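"""WISN difference, ratio, work-pressure classification and aggregation.

The WISN difference is available headcount minus computed requirement
(negative = shortage).  The WISN ratio, available / required, expresses work
pressure: below 1 the cadre is under pressure (understaffed), above 1 there
is surplus capacity.  Ratios use the rounded requirement as denominator and
are reported half-up at two decimals; the pressure class is taken on that
rounded ratio so that a printed 1.00 is "balanced".
"""

from __future__ import annotations

import enum
from collections import defaultdict
from typing import Iterable, Optional, Union

from pydantic import BaseModel, NonNegativeInt

from ._rounding import round_half_up
from .model import WisnError
from .requirement import RequirementResult


class Pressure(str, enum.Enum):
    SHORTAGE = "shortage"
    BALANCED = "balanced"
    SURPLUS = "surplus"
    #: requirement is zero, so the ratio (and pressure) is undefined
    UNDEFINED = "undefined"


class StaffingRecord(BaseModel):
    """Available headcount of one cadre at one facility."""

    model_config = {"frozen": True}

    facility: str
    cadre: str
    available: NonNegativeInt


class WisnResult(BaseModel):
    """Gap and work-pressure summary for one facility and cadre.

    ``ratio`` is ``None`` when the requirement is zero (the sentinel for an
    undefined ratio); such results are excluded from ratio-based counts.
    """

    model_config = {"frozen": True}

    facility: str
    cadre: str
    available: NonNegativeInt
    required: NonNegativeInt
    difference: int
    ratio: Optional[float]
    pressure: Pressure


class CadreAggregate(BaseModel):
    """Column sums and pressure counts for one cadre across facilities."""

    model_config = {"frozen": True}

    cadre: str
    n_facilities: int
    total_available: int
    total_required: int
    total_difference: int
    coverage_percent: Optional[int]
    n_shortage: int
    n_balanced: int
    n_surplus: int
    n_undefined: int
    total_surplus: int


class AggregateReport(BaseModel):
    """Per-cadre aggregates for one scope (an LGA or state)."""

    model_config = {"frozen": True}

    scope: str
    cadres: dict[str, CadreAggregate]


def compute_wisn_result(
    record: StaffingRecord, requirement: Union[RequirementResult, int]
) -> WisnResult:
    """WISN difference, ratio and pressure for one facility and cadre.

    ``requirement`` may be a full :class:`RequirementResult` or simply the
    rounded whole-staff requirement.  A zero requirement makes the ratio
    undefined; it is flagged (``ratio=None``, ``pressure=undefined``) rather
    than reported as infinite.
    """
    if isinstance(requirement, RequirementResult):
        if (requirement.facility, requirement.cadre) != (record.facility, record.cadre):
            raise WisnError(
                f"staffing record ({record.facility!r}, {record.cadre!r}) does not match "
                f"requirement ({requirement.facility!r}, {requirement.cadre!r})"
            )
        required = requirement.required
    else:
        required = int(requirement)
        if required < 0:
            raise WisnError(f"required staff cannot be negative: {required}")

    difference = record.available - required
    if required == 0:
        ratio: Optional[float] = None
        pressure = Pressure.UNDEFINED
    else:
        ratio = round_half_up(record.available / required, 2)
        if ratio > 1:
            pressure = Pressure.SURPLUS
        elif ratio < 1:
            pressure = Pressure.SHORTAGE
        else:
            pressure = Pressure.BALANCED
    return WisnResult(
        facility=record.facility,
        cadre=record.cadre,
        available=record.available,
        required=required,
        difference=difference,
        ratio=ratio,
        pressure=pressure,
    )


def aggregate(results: Iterable[WisnResult], scope: str) -> AggregateReport:
    """Sum results per cadre over facilities.

    ``coverage_percent`` is ``100 * total_available / total_required`` rounded
    to the nearest integer (half-up), or ``None`` when nothing is required.
    Duplicate (facility, cadre) pairs are rejected.
    """
    results = list(results)
    if not results:
        raise WisnError("cannot aggregate an empty result list")
    seen: set[tuple[str, str]] = set()
    by_cadre: dict[str, list[WisnResult]] = defaultdict(list)
    for r in results:
        key = (r.facility, r.cadre)
        if key in seen:
            raise WisnError(f"duplicate result for facility {r.facility!r}, cadre {r.cadre!r}")
        seen.add(key)
        by_cadre[r.cadre].append(r)

    cadres: dict[str, CadreAggregate] = {}
    for cadre, rs in by_cadre.items():
        total_available = sum(r.available for r in rs)
        total_required = sum(r.required for r in rs)
        coverage = (
            int(round_half_up(100.0 * total_available / total_required))
            if total_required > 0
            else None
        )
        cadres[cadre] = CadreAggregate(
            cadre=cadre,
            n_facilities=len(rs),
            total_available=total_available,
            total_required=total_required,
            total_difference=sum(r.difference for r in rs),
            coverage_percent=coverage,
            n_shortage=sum(r.pressure is Pressure.SHORTAGE for r in rs),
            n_balanced=sum(r.pressure is Pressure.BALANCED for r in rs),
            n_surplus=sum(r.pressure is Pressure.SURPLUS for r in rs),
            n_undefined=sum(r.pressure is Pressure.UNDEFINED for r in rs),
            total_surplus=sum(r.difference for r in rs if r.difference > 0),
        )
    return AggregateReport(scope=scope, cadres=cadres)


class Transfer(BaseModel):
    """A planned move of whole staff between two facilities."""

    model_config = {"frozen": True}

    from_facility: str
    to_facility: str
    cadre: str
    n_staff: int


def redistribute_surplus(results: Iterable[WisnResult]) -> list[Transfer]:
    """Greedy plan moving surplus staff to the facilities under most pressure.

    One staff member moves at a time, from the facility with the largest
    current surplus to the facility with the largest current absolute
    shortage; ties break alphabetically by facility name.  The plan is
    deterministic, never moves a facility below its requirement, and stops
    when either all surplus or all shortage is exhausted.  Consecutive moves
    along the same route are coalesced in the returned plan.
    """
    results = list(results)
    cadres = {r.cadre for r in results}
    if len(cadres) > 1:
        raise WisnError(f"redistribution plans one cadre at a time, got {sorted(cadres)}")

    surplus = {r.facility: r.difference for r in results if r.difference > 0}
    shortage = {r.facility: -r.difference for r in results if r.difference < 0}
    moves: dict[tuple[str, str], int] = defaultdict(int)
    cadre = next(iter(cadres)) if cadres else ""
    while surplus and shortage:
        donor = min(surplus, key=lambda f: (-surplus[f], f))
        recipient = min(shortage, key=lambda f: (-shortage[f], f))
        moves[(donor, recipient)] += 1
        surplus[donor] -= 1
        shortage[recipient] -= 1
        if surplus[donor] == 0:
            del surplus[donor]
        if shortage[recipient] == 0:
            del shortage[recipient]
    return [
        Transfer(from_facility=src, to_facility=dst, cadre=cadre, n_staff=n)
        for (src, dst), n in sorted(moves.items())
    ]
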
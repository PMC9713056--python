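"""Staff-requirement computation.

The required headcount of a cadre at a facility combines three terms:

* the **core requirement** ``sum_i AW_i / SW_i`` — annual service statistics
  divided by the standard workload, summed over core activities;
* the **category allowance factor** ``CAF = 100 / (100 - CAS)`` inflating the
  core requirement for support activities performed by all cadre members,
  where CAS is the percent of working time those activities absorb;
* the **individual allowance factor** ``IAF = IAS / AWT_hours`` adding the
  staff-equivalents of additional activities performed by some members,
  where IAS is their total annual hours.

Total requirement = ``CAF * core + IAF``, then rounded to whole staff.
"""

from __future__ import annotations

from typing import Iterable, Literal, Mapping

from pydantic import BaseModel, NonNegativeFloat, NonNegativeInt

from ._rounding import ceil_decimal, round_half_up
from .model import (
    ActivityStandard,
    AvailableWorkingTime,
    Category,
    ServiceStatistics,
    StandardWorkload,
    WisnError,
)

RoundingMode = Literal["half_up", "ceil"]


class AllowanceSummary(BaseModel):
    """Support (CAS/CAF) and individual (IAS/IAF) allowances for one cadre.

    ``total_cas`` is percent of working time in [0, 100); ``total_ias`` is
    hours/year.  ``caf >= 1`` always; ``iaf`` is in staff-equivalents.
    """

    model_config = {"frozen": True}

    cadre: str
    total_cas: float = 0.0
    caf: float = 1.0
    total_ias: NonNegativeFloat = 0.0
    iaf: NonNegativeFloat = 0.0


class RequirementResult(BaseModel):
    """Computed staffing requirement for one facility and cadre."""

    model_config = {"frozen": True}

    facility: str
    cadre: str
    core_requirement: NonNegativeFloat
    total_cas: float
    caf: float
    iaf: NonNegativeFloat
    required_raw: NonNegativeFloat
    required: NonNegativeInt


def compute_core_requirement(
    stats: ServiceStatistics, workloads: Mapping[str, StandardWorkload]
) -> float:
    """Core staff requirement: sum of AW_i / SW_i over core activities.

    ``workloads`` maps normalized activity names to standard workloads.  Any
    statistic with a positive count but no (or zero) standard workload is a
    hard error — silently dropping it would bias the requirement downward.
    """
    total = 0.0
    missing: list[str] = []
    for name, count in stats.normalized_counts().items():
        if count == 0:
            continue
        sw = workloads.get(name)
        if sw is None or sw.clients_per_year == 0:
            missing.append(name)
            continue
        total += count / sw.clients_per_year
    if missing:
        raise WisnError(
            f"facility {stats.facility!r}: service statistics reported for activities "
            f"without a usable standard workload: {sorted(missing)}"
        )
    return total


def _annual_hours(
    standards: Iterable[ActivityStandard],
    awt: AvailableWorkingTime,
    category: Category,
    **annualize_kwargs: float,
) -> float:
    from .model import annualize_standard

    return sum(
        annualize_standard(s, awt, **annualize_kwargs)
        for s in standards
        if s.category is category
    )


def compute_caf(
    support_standards: Iterable[ActivityStandard],
    awt: AvailableWorkingTime,
    **annualize_kwargs: float,
) -> tuple[float, float]:
    """Category allowance standard and factor: ``(total_cas, caf)``.

    CAS is the percent of available working time absorbed by support
    activities; CAF = 100 / (100 - CAS).  CAS >= 100 means support work
    alone exceeds the available time and is an error.
    """
    hours = _annual_hours(support_standards, awt, Category.SUPPORT, **annualize_kwargs)
    if awt.awt_hours <= 0:
        raise WisnError(f"cadre {awt.cadre!r}: available working time is zero")
    total_cas = 100.0 * hours / awt.awt_hours
    if total_cas >= 100.0:
        raise WisnError(
            f"cadre {awt.cadre!r}: support activities absorb {total_cas:.1f}% of "
            "working time; no time remains for core services"
        )
    return total_cas, 100.0 / (100.0 - total_cas)


def compute_iaf(
    individual_standards: Iterable[ActivityStandard],
    awt: AvailableWorkingTime,
    **annualize_kwargs: float,
) -> tuple[float, float]:
    """Individual allowance standard and factor: ``(total_ias, iaf)``.

    IAS is annual hours of additional activities (performed by some cadre
    members); IAF = IAS / AWT_hours, the extra staff-equivalents they imply.
    """
    if awt.awt_hours <= 0:
        raise WisnError(f"cadre {awt.cadre!r}: available working time is zero")
    hours = _annual_hours(individual_standards, awt, Category.INDIVIDUAL, **annualize_kwargs)
    return hours, hours / awt.awt_hours


def compute_allowances(
    standards: Iterable[ActivityStandard],
    awt: AvailableWorkingTime,
    **annualize_kwargs: float,
) -> AllowanceSummary:
    """Allowance summary for ``awt.cadre`` from its non-core standards."""
    own = [s for s in standards if s.cadre == awt.cadre]
    total_cas, caf = compute_caf(own, awt, **annualize_kwargs)
    total_ias, iaf = compute_iaf(own, awt, **annualize_kwargs)
    return AllowanceSummary(
        cadre=awt.cadre, total_cas=total_cas, caf=caf, total_ias=total_ias, iaf=iaf
    )


def round_requirement(required_raw: float, mode: RoundingMode = "half_up") -> int:
    """Whole-staff rounding of a fractional requirement.

    Default is round-half-up to the nearest whole number (5.5 -> 6,
    10.49 -> 10); ``mode="ceil"`` always rounds up.  Monotone non-decreasing
    in its argument either way.
    """
    if required_raw < 0:
        raise WisnError(f"requirement cannot be negative: {required_raw!r}")
    if mode == "half_up":
        return int(round_half_up(required_raw))
    if mode == "ceil":
        return int(ceil_decimal(required_raw))
    raise WisnError(f"unknown rounding mode {mode!r}")


def compute_total_requirement(
    facility: str,
    core_requirement: float,
    allowances: AllowanceSummary,
    rounding: RoundingMode = "half_up",
) -> RequirementResult:
    """Total requirement ``CAF * core + IAF``, raw and rounded."""
    if not (core_requirement >= 0):
        raise WisnError(f"core requirement must be finite and nonnegative: {core_requirement!r}")
    raw = allowances.caf * core_requirement + allowances.iaf
    return RequirementResult(
        facility=facility,
        cadre=allowances.cadre,
        core_requirement=core_requirement,
        total_cas=allowances.total_cas,
        caf=allowances.caf,
        iaf=allowances.iaf,
        required_raw=raw,
        required=round_requirement(raw, rounding),
    )


def compute_requirement(
    stats: ServiceStatistics,
    standards: Iterable[ActivityStandard],
    awt: AvailableWorkingTime,
    rounding: RoundingMode = "half_up",
    **annualize_kwargs: float,
) -> RequirementResult:
    """End-to-end requirement for one facility and one cadre.

    Convenience composition of standard workloads, core requirement,
    allowances and the total; intermediate values stay at full precision and
    only the final requirement is rounded.
    """
    from .model import standard_workloads_for_cadre

    standards = list(standards)
    workloads = standard_workloads_for_cadre(standards, awt)
    core = compute_core_requirement(stats, workloads)
    allowances = compute_allowances(standards, awt, **annualize_kwargs)
    return compute_total_requirement(stats.facility, core, allowances, rounding)
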
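"""Domain types and time accounting for workload-based staffing estimation.

The WISN (Workload Indicators of Staffing Need) method starts from three
primitives, all defined per health-worker cadre:

* **Available working time (AWT)** — the annual time one worker actually has
  for work, after public holidays, annual leave, sick leave and other
  absences are subtracted from the possible working days of the year.
* **Activity standards** — the expert-validated time it takes one worker of
  the cadre to perform each activity to acceptable standards.  Core
  (clinical) activities are timed per client; support and individual
  (non-clinical) activities are timed per day, week or month.
* **Standard workloads** — for each core activity, the number of clients one
  worker could serve in a year if they did nothing else:
  ``SW = AWT_hours * 60 / minutes_per_client``.

This module owns those primitives plus the unit conversions needed to bring
per-day/week/month standards onto an annual-hours scale.
"""

from __future__ import annotations

import enum
from typing import Mapping

from pydantic import BaseModel, Field, NonNegativeFloat, NonNegativeInt, model_validator


class WisnError(ValueError):
    """Raised for domain-rule violations (invalid inputs, broken invariants)."""


class Category(str, enum.Enum):
    """WISN activity category.

    ``core`` activities are clinical services with routine statistics,
    performed by every member of the cadre; ``support`` activities are
    non-clinical and performed by all members; ``individual`` (additional)
    activities are non-clinical and performed by only some members.
    """

    CORE = "core"
    SUPPORT = "support"
    INDIVIDUAL = "individual"


class TimeUnit(str, enum.Enum):
    MINUTES_PER_CLIENT = "minutes_per_client"
    HOURS_PER_CLIENT = "hours_per_client"
    MINUTES_PER_DAY = "minutes_per_day"
    MINUTES_PER_WEEK = "minutes_per_week"
    MINUTES_PER_MONTH = "minutes_per_month"
    HOURS_PER_DAY = "hours_per_day"
    HOURS_PER_WEEK = "hours_per_week"
    HOURS_PER_MONTH = "hours_per_month"


PER_CLIENT_UNITS = frozenset({TimeUnit.MINUTES_PER_CLIENT, TimeUnit.HOURS_PER_CLIENT})

#: Working days per week in the public service (5-day week).
WORKING_DAYS_PER_WEEK = 5.0
#: Months per year used to annualize monthly standards.
MONTHS_PER_YEAR = 12.0


def normalize_activity(name: str) -> str:
    """Canonical activity key: whitespace-trimmed, case-folded.

    Activity names are matched between standards and service statistics with
    this normalization; anything looser risks silently dropping workload.
    """
    return name.strip().casefold()


class AWTComponents(BaseModel):
    """Per-cadre absence accounting that yields annual available working time.

    Components follow the standard decomposition: possible working days in a
    year, minus days off for public holidays, official (annual) leave, sick
    leave, and other absences (casual, study/training and maternity leave).
    """

    model_config = {"frozen": True}

    cadre: str
    possible_working_days: NonNegativeFloat
    public_holidays: NonNegativeFloat = 0.0
    official_leave: NonNegativeFloat = 0.0
    sick_leave: NonNegativeFloat = 0.0
    other_absence: NonNegativeFloat = 0.0
    hours_per_working_day: float = Field(default=8.0, gt=0.0, le=24.0)

    @model_validator(mode="after")
    def _absences_fit_in_year(self) -> "AWTComponents":
        total_off = (
            self.public_holidays + self.official_leave + self.sick_leave + self.other_absence
        )
        if total_off > self.possible_working_days:
            raise WisnError(
                f"cadre {self.cadre!r}: absence days ({total_off:g}) exceed possible "
                f"working days ({self.possible_working_days:g})"
            )
        return self


class AvailableWorkingTime(BaseModel):
    """Annual time one worker of a cadre is available, in days and hours."""

    model_config = {"frozen": True}

    cadre: str
    awt_days: NonNegativeFloat
    awt_hours: NonNegativeFloat


class ActivityStandard(BaseModel):
    """One timed activity for one cadre.

    ``time_value == 0`` is legal and means the cadre does not perform the
    activity; such standards contribute nothing downstream.
    """

    model_config = {"frozen": True}

    cadre: str
    activity: str
    category: Category
    time_value: NonNegativeFloat
    time_unit: TimeUnit

    @model_validator(mode="after")
    def _unit_matches_category(self) -> "ActivityStandard":
        per_client = self.time_unit in PER_CLIENT_UNITS
        if self.category is Category.CORE and not per_client:
            raise WisnError(
                f"core activity {self.activity!r} ({self.cadre}) must be timed per "
                f"client, got unit {self.time_unit.value!r}"
            )
        if self.category is not Category.CORE and per_client:
            raise WisnError(
                f"{self.category.value} activity {self.activity!r} ({self.cadre}) must "
                f"use a per-day/week/month unit, got {self.time_unit.value!r}"
            )
        return self

    @property
    def key(self) -> str:
        return normalize_activity(self.activity)


class StandardWorkload(BaseModel):
    """Annual clients one worker can serve for one core activity (SW)."""

    model_config = {"frozen": True}

    cadre: str
    activity: str
    clients_per_year: NonNegativeFloat

    @property
    def key(self) -> str:
        return normalize_activity(self.activity)


class ServiceStatistics(BaseModel):
    """Annual client counts for one facility, keyed by core activity name."""

    model_config = {"frozen": True}

    facility: str
    year: int
    counts: Mapping[str, NonNegativeInt]

    def normalized_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for name, count in self.counts.items():
            key = normalize_activity(name)
            if key in out:
                raise WisnError(
                    f"facility {self.facility!r}: duplicate activity {name!r} after "
                    "name normalization"
                )
            out[key] = int(count)
        return out


def compute_awt(components: AWTComponents) -> AvailableWorkingTime:
    """Available working time: possible days minus all days off.

    ``awt_days = A - (B + C + D + E)`` where A is possible working days and
    B..E are public holidays, official leave, sick leave and other absences;
    ``awt_hours = awt_days * hours_per_working_day``.
    """
    awt_days = components.possible_working_days - (
        components.public_holidays
        + components.official_leave
        + components.sick_leave
        + components.other_absence
    )
    return AvailableWorkingTime(
        cadre=components.cadre,
        awt_days=awt_days,
        awt_hours=awt_days * components.hours_per_working_day,
    )


def annualize_standard(
    std: ActivityStandard,
    awt: AvailableWorkingTime,
    *,
    working_days_per_week: float = WORKING_DAYS_PER_WEEK,
    months_per_year: float = MONTHS_PER_YEAR,
) -> float:
    """Annual hours implied by a per-day/week/month standard.

    Daily standards recur on every available working day, weekly standards on
    every available working week (``awt_days / working_days_per_week``), and
    monthly standards twelve times a year regardless of absences.  Core
    (per-client) standards have no intrinsic annual volume and are rejected.
    """
    if std.category is Category.CORE:
        raise WisnError(
            f"cannot annualize core activity {std.activity!r}; per-client standards "
            "scale with service statistics, not with the calendar"
        )
    v = std.time_value
    unit = std.time_unit
    if unit is TimeUnit.MINUTES_PER_DAY:
        return v * awt.awt_days / 60.0
    if unit is TimeUnit.MINUTES_PER_WEEK:
        return v * (awt.awt_days / working_days_per_week) / 60.0
    if unit is TimeUnit.MINUTES_PER_MONTH:
        return v * months_per_year / 60.0
    if unit is TimeUnit.HOURS_PER_DAY:
        return v * awt.awt_days
    if unit is TimeUnit.HOURS_PER_WEEK:
        return v * (awt.awt_days / working_days_per_week)
    if unit is TimeUnit.HOURS_PER_MONTH:
        return v * months_per_year
    raise WisnError(f"unknown time unit {unit!r} for activity {std.activity!r}")


def compute_standard_workload(
    std: ActivityStandard, awt: AvailableWorkingTime
) -> StandardWorkload:
    """Standard workload of a core activity: AWT divided by the unit time.

    A zero time value is rejected rather than yielding an infinite workload:
    zero means "activity not performed by this cadre" and the caller should
    exclude the activity instead.
    """
    if std.category is not Category.CORE:
        raise WisnError(
            f"standard workload is defined for core activities only; "
            f"{std.activity!r} is {std.category.value}"
        )
    if std.time_value == 0:
        raise WisnError(
            f"core activity {std.activity!r} ({std.cadre}) has zero unit time; "
            "exclude it instead of computing a standard workload"
        )
    if std.time_unit is TimeUnit.MINUTES_PER_CLIENT:
        clients = awt.awt_hours * 60.0 / std.time_value
    else:  # hours per client
        clients = awt.awt_hours / std.time_value
    return StandardWorkload(cadre=std.cadre, activity=std.activity, clients_per_year=clients)


def standard_workloads_for_cadre(
    standards: list[ActivityStandard], awt: AvailableWorkingTime
) -> dict[str, StandardWorkload]:
    """Standard workloads for every non-zero core standard of ``awt.cadre``.

    Zero-time core standards are excluded (activity not performed), matching
    the convention that they produce no workload rather than an infinite one.
    """
    out: dict[str, StandardWorkload] = {}
    for std in standards:
        if std.cadre != awt.cadre or std.category is not Category.CORE:
            continue
        if std.time_value == 0:
            continue
        out[std.key] = compute_standard_workload(std, awt)
    return out
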
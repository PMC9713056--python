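"""Synthetic WISN scenarios: facility registers the study never published.

Annual service statistics live in facility paper registers and the national
DHIS2 instance, neither of which is publicly accessible, and the approved
absence calendar behind the study's available working time is likewise not
printed.  This module generates complete, schema-valid stand-ins: per-cadre
absence components, activity standards drawn within the observed ranges of
the published standards table, negative-binomially distributed annual client
counts, and facility rosters.

Facility registers are overdispersed relative to Poisson (catchment size,
outreach campaigns and stock-outs all vary between facilities), so counts
are drawn negative-binomially with mean ``utilization_scale`` and variance
``mean + overdispersion * mean**2``; ``overdispersion=0`` degenerates to
Poisson.  Each facility draws from its own substream keyed by a stable hash
of the facility name, so adding a facility never perturbs the others.

:func:`generate_with_target` inverts the pipeline: it constructs counts so
the computed (rounded) requirement equals a planted target exactly, which
is what makes end-to-end recovery testable without any real register data.
"""

from __future__ import annotations

import hashlib
from typing import Mapping, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .model import (
    ActivityStandard,
    AWTComponents,
    Category,
    ServiceStatistics,
    TimeUnit,
    WisnError,
    compute_awt,
    standard_workloads_for_cadre,
)
from .metrics import StaffingRecord
from .requirement import compute_allowances

#: Core clinical services prioritised at the primary-care level (reproductive,
#: maternal, newborn and child health plus common childhood illness).
CORE_ACTIVITIES: tuple[str, ...] = (
    "Antenatal care",
    "Delivery",
    "Postnatal care",
    "Family planning (counselling)",
    "Family planning (insertion of IUCD)",
    "Family planning (insertion of an implant)",
    "Family planning (injection)",
    "Family planning (oral pills)",
    "Immunization",
    "Diarrhoea in U5 years old",
    "Pneumonia in U5 years old",
    "Confirmed uncomplicated malaria",
)

SUPPORT_ACTIVITIES: tuple[str, ...] = (
    "Documentation on patients",
    "Staff meetings",
    "Hand over/report writing",
    "Group health education",
    "Community mobilisation and education",
)

INDIVIDUAL_ACTIVITIES: tuple[str, ...] = (
    "General administration",
    "Supervision of students",
    "Monthly report writing",
    "Mentoring of subordinates",
)

#: Observed per-client range of the published core standards (minutes).
CORE_MINUTES_RANGE = (7.0, 60.0)

#: Default absence calendar for the Nigerian public service: a 52-week,
#: 5-day working year (260 possible days), ~12 public holidays, 30 days
#: annual leave, and allowances for sick and other (casual/study/maternity)
#: leave, at 8 hours per working day.
DEFAULT_AWT = dict(
    possible_working_days=260.0,
    public_holidays=12.0,
    official_leave=30.0,
    sick_leave=7.0,
    other_absence=12.0,
    hours_per_working_day=8.0,
)


class ScenarioConfig(BaseModel):
    """Knobs of the synthetic study area.

    Defaults mirror the study setting: ten facilities, two cadres, annual
    per-service volumes in the low thousands with register-level
    overdispersion, support work absorbing 15-30% of working time, a modest
    individual-activity load, and rosters spanning the printed 0-14 range.
    """

    model_config = {"frozen": True}

    n_facilities: int = Field(default=10, ge=1)
    cadres: tuple[str, ...] = ("Nurse/Midwife", "CHW")
    utilization_scale: float = Field(default=2500.0, ge=0.0)
    overdispersion: float = Field(default=0.3, ge=0.0)
    support_fraction_range: tuple[float, float] = (0.15, 0.30)
    individual_hours_range: tuple[float, float] = (100.0, 400.0)
    roster_range: tuple[int, int] = (0, 14)
    year: int = 2019
    seed: int = 0

    @model_validator(mode="after")
    def _ranges_well_ordered(self) -> "ScenarioConfig":
        lo, hi = self.support_fraction_range
        if not (0.0 <= lo <= hi < 0.5):
            raise WisnError(f"support_fraction_range must lie within [0, 0.5): {lo, hi}")
        lo, hi = self.individual_hours_range
        if not (0.0 <= lo <= hi):
            raise WisnError(f"individual_hours_range is degenerate: {lo, hi}")
        lo, hi = self.roster_range
        if not (0 <= lo <= hi):
            raise WisnError(f"roster_range is degenerate: {lo, hi}")
        if not self.cadres:
            raise WisnError("at least one cadre is required")
        return self


class Scenario(BaseModel):
    """A complete generated input set for the staffing pipeline."""

    model_config = {"frozen": True}

    config: ScenarioConfig
    awt: dict[str, AWTComponents]
    standards: list[ActivityStandard]
    statistics: list[ServiceStatistics]
    staffing: list[StaffingRecord]


def _substream(seed: int, label: str) -> np.random.Generator:
    """Independent RNG keyed by a stable hash of ``label``."""
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return np.random.default_rng([seed & 0x7FFFFFFF, int.from_bytes(digest[:4], "big")])


def facility_names(n: int) -> list[str]:
    return [f"Facility {i + 1}" for i in range(n)]


def _draw_standards(config: ScenarioConfig, cadre: str, awt_days: float, awt_hours: float) -> list[ActivityStandard]:
    rng = _substream(config.seed, f"standards:{cadre}")
    out: list[ActivityStandard] = []
    lo, hi = CORE_MINUTES_RANGE
    for name in CORE_ACTIVITIES:
        out.append(
            ActivityStandard(
                cadre=cadre,
                activity=name,
                category=Category.CORE,
                time_value=float(np.round(rng.uniform(lo, hi), 1)),
                time_unit=TimeUnit.MINUTES_PER_CLIENT,
            )
        )
    # Support load: a target share of working time, split across activities
    # and expressed as minutes/day so it annualizes back to that share.
    frac = rng.uniform(*config.support_fraction_range)
    weights = rng.dirichlet(np.ones(len(SUPPORT_ACTIVITIES)))
    for name, w in zip(SUPPORT_ACTIVITIES, weights):
        minutes_per_day = frac * w * awt_hours * 60.0 / awt_days
        out.append(
            ActivityStandard(
                cadre=cadre,
                activity=name,
                category=Category.SUPPORT,
                time_value=float(minutes_per_day),
                time_unit=TimeUnit.MINUTES_PER_DAY,
            )
        )
    total_ind_hours = rng.uniform(*config.individual_hours_range)
    weights = rng.dirichlet(np.ones(len(INDIVIDUAL_ACTIVITIES)))
    for name, w in zip(INDIVIDUAL_ACTIVITIES, weights):
        minutes_per_day = total_ind_hours * w * 60.0 / awt_days
        out.append(
            ActivityStandard(
                cadre=cadre,
                activity=name,
                category=Category.INDIVIDUAL,
                time_value=float(minutes_per_day),
                time_unit=TimeUnit.MINUTES_PER_DAY,
            )
        )
    return out


def _draw_counts(rng: np.random.Generator, mean: float, overdispersion: float, k: int) -> np.ndarray:
    if mean == 0:
        return np.zeros(k, dtype=int)
    if overdispersion == 0:
        return rng.poisson(mean, size=k)
    n = 1.0 / overdispersion  # variance = mean + overdispersion * mean^2
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=k)


def default_awt_components(cadres: Sequence[str]) -> dict[str, AWTComponents]:
    return {c: AWTComponents(cadre=c, **DEFAULT_AWT) for c in cadres}


def generate_scenario(config: Optional[ScenarioConfig] = None) -> Scenario:
    """Draw a full synthetic study area from ``config`` (deterministic in seed)."""
    config = config or ScenarioConfig()
    awt_components = default_awt_components(config.cadres)
    standards: list[ActivityStandard] = []
    for cadre in config.cadres:
        awt = compute_awt(awt_components[cadre])
        standards.extend(_draw_standards(config, cadre, awt.awt_days, awt.awt_hours))

    statistics: list[ServiceStatistics] = []
    staffing: list[StaffingRecord] = []
    lo, hi = config.roster_range
    for facility in facility_names(config.n_facilities):
        rng = _substream(config.seed, f"facility:{facility}")
        counts = _draw_counts(
            rng, config.utilization_scale, config.overdispersion, len(CORE_ACTIVITIES)
        )
        statistics.append(
            ServiceStatistics(
                facility=facility,
                year=config.year,
                counts={name: int(c) for name, c in zip(CORE_ACTIVITIES, counts)},
            )
        )
        for cadre in config.cadres:
            staffing.append(
                StaffingRecord(
                    facility=facility, cadre=cadre, available=int(rng.integers(lo, hi + 1))
                )
            )
    return Scenario(
        config=config,
        awt=awt_components,
        standards=standards,
        statistics=statistics,
        staffing=staffing,
    )


def generate_with_target(
    targets: Mapping[str, int],
    config: Optional[ScenarioConfig] = None,
    cadre: Optional[str] = None,
) -> Scenario:
    """Construct a scenario whose computed requirements equal planted targets.

    ``targets`` maps facility name to the desired whole-staff requirement for
    ``cadre`` (default: the first configured cadre).  Standards and absence
    components are drawn exactly as in :func:`generate_scenario`; counts are
    then solved from the planted core requirement
    ``(target - IAF) / CAF`` and spread across core activities in equal
    requirement shares.  Because counts must be integers the reconstruction
    carries a rounding error of at most ``0.5 / SW_i`` per activity — orders
    of magnitude below the 0.5 staff that would move the rounded result.

    Statistics are shared per facility, so targets are planted for a single
    cadre at a time.  A target below the cadre's IAF is infeasible (even zero
    clients would require more staff) and raises :class:`WisnError`.
    """
    config = config or ScenarioConfig()
    cadre = cadre or config.cadres[0]
    if cadre not in config.cadres:
        raise WisnError(f"cadre {cadre!r} not in configured cadres {list(config.cadres)}")
    awt_components = default_awt_components(config.cadres)
    awt = compute_awt(awt_components[cadre])
    standards: list[ActivityStandard] = []
    for c in config.cadres:
        c_awt = compute_awt(awt_components[c])
        standards.extend(_draw_standards(config, c, c_awt.awt_days, c_awt.awt_hours))

    allowances = compute_allowances(standards, awt)
    workloads = standard_workloads_for_cadre(standards, awt)
    ordered = [s for s in standards if s.cadre == cadre and s.category is Category.CORE]

    statistics: list[ServiceStatistics] = []
    staffing: list[StaffingRecord] = []
    lo, hi = config.roster_range
    for facility in sorted(targets):
        target = int(targets[facility])
        if target < 0:
            raise WisnError(f"facility {facility!r}: target must be nonnegative, got {target}")
        if target < allowances.iaf:
            raise WisnError(
                f"facility {facility!r}: target {target} is below the individual "
                f"allowance factor {allowances.iaf:.3f}; infeasible"
            )
        core_target = (target - allowances.iaf) / allowances.caf
        share = core_target / len(ordered)
        counts = {
            s.activity: int(round(share * workloads[s.key].clients_per_year)) for s in ordered
        }
        statistics.append(
            ServiceStatistics(facility=facility, year=config.year, counts=counts)
        )
        rng = _substream(config.seed, f"facility:{facility}")
        for c in config.cadres:
            staffing.append(
                StaffingRecord(facility=facility, cadre=c, available=int(rng.integers(lo, hi + 1)))
            )
    return Scenario(
        config=config,
        awt=awt_components,
        standards=standards,
        statistics=statistics,
        staffing=staffing,
    )
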
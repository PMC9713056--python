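"""CSV/YAML readers and writers for all pipeline schemas, plus packaged
reference tables.

All CSV files are UTF-8, comma-delimited, with a mandatory header row and
"." as the decimal separator.  Facility names may contain parentheses and
slashes and are treated as opaque strings.  Readers validate eagerly and
report every offending row (with its line number) rather than stopping at
the first problem.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

import pandas as pd
import yaml

from .metrics import StaffingRecord, WisnResult
from .model import (
    ActivityStandard,
    AWTComponents,
    Category,
    ServiceStatistics,
    TimeUnit,
    WisnError,
    normalize_activity,
)
from .report import RESULT_COLUMNS, frame_to_results, results_to_frame
from .requirement import RequirementResult

PathLike = Union[str, Path]

REQUIREMENT_COLUMNS = [
    "facility", "cadre", "core_requirement", "total_cas", "caf", "iaf",
    "required_raw", "required",
]


class SchemaError(WisnError):
    """A file failed schema validation; ``errors`` lists every problem found."""

    def __init__(self, path: PathLike, errors: list[str]):
        self.errors = list(errors)
        super().__init__(f"{path}: " + "; ".join(self.errors))


def _read_csv(path: PathLike, required_columns: list[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in required_columns if c not in frame.columns]
    if missing:
        raise SchemaError(path, [f"missing required column(s): {missing}"])
    return frame


def read_activity_standards(path: PathLike) -> list[ActivityStandard]:
    """Load activity standards; zero-valued rows are retained (flagged as
    "not performed" downstream, never silently dropped)."""
    frame = _read_csv(path, ["cadre", "activity", "category", "time_value", "time_unit"])
    errors: list[str] = []
    out: list[ActivityStandard] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # 1-based + header
        try:
            std = ActivityStandard(
                cadre=row.cadre.strip(),
                activity=row.activity.strip(),
                category=Category(row.category.strip().lower()),
                time_value=float(row.time_value),
                time_unit=TimeUnit(row.time_unit.strip().lower()),
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"row {i}: {_terse(exc)}")
            continue
        key = (std.cadre, std.key)
        if key in seen:
            errors.append(f"row {i}: duplicate standard for {key}")
            continue
        seen.add(key)
        out.append(std)
    if errors:
        raise SchemaError(path, errors)
    return out


def read_staffing(path: PathLike) -> list[StaffingRecord]:
    frame = _read_csv(path, ["facility", "cadre", "available"])
    errors, out = [], []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            rec = StaffingRecord(
                facility=row.facility.strip(), cadre=row.cadre.strip(), available=int(row.available)
            )
        except ValueError as exc:
            errors.append(f"row {i}: {_terse(exc)}")
            continue
        key = (rec.facility, rec.cadre)
        if key in seen:
            errors.append(f"row {i}: duplicate staffing record for {key}")
            continue
        seen.add(key)
        out.append(rec)
    if errors:
        raise SchemaError(path, errors)
    return out


def read_statistics(path: PathLike) -> list[ServiceStatistics]:
    """Load long-format annual service statistics (one row per facility,
    activity) and fold them into per-facility records."""
    frame = _read_csv(path, ["facility", "year", "activity", "annual_count"])
    errors: list[str] = []
    grouped: dict[str, dict[str, int]] = {}
    years: dict[str, int] = {}
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        facility = row.facility.strip()
        activity = row.activity.strip()
        try:
            year = int(row.year)
            count = int(row.annual_count)
        except ValueError:
            errors.append(f"row {i}: year and annual_count must be integers")
            continue
        if count < 0:
            errors.append(f"row {i}: annual_count must be nonnegative, got {count}")
            continue
        counts = grouped.setdefault(facility, {})
        if normalize_activity(activity) in {normalize_activity(a) for a in counts}:
            errors.append(f"row {i}: duplicate activity {activity!r} for facility {facility!r}")
            continue
        if facility in years and years[facility] != year:
            errors.append(f"row {i}: facility {facility!r} spans multiple years")
            continue
        years[facility] = year
        counts[activity] = count
    if errors:
        raise SchemaError(path, errors)
    return [
        ServiceStatistics(facility=f, year=years[f], counts=c) for f, c in grouped.items()
    ]


def read_awt(path: PathLike) -> dict[str, AWTComponents]:
    """Load per-cadre absence components from YAML or JSON."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise SchemaError(path, ["expected a mapping of cadre -> components"])
    errors, out = [], {}
    for cadre, fields in data.items():
        try:
            out[cadre] = AWTComponents(cadre=cadre, **fields)
        except (TypeError, ValueError) as exc:
            errors.append(f"cadre {cadre!r}: {_terse(exc)}")
    if errors:
        raise SchemaError(path, errors)
    return out


def check_cross_references(
    standards: Iterable[ActivityStandard], statistics: Iterable[ServiceStatistics]
) -> None:
    """Every reported statistic must name an activity known to the standards.

    All offending names are listed at once; silently dropping any would bias
    requirements downward.
    """
    known = {s.key for s in standards}
    unknown = sorted(
        {
            f"{name!r} (facility {stat.facility!r})"
            for stat in statistics
            for name in stat.counts
            if normalize_activity(name) not in known
        }
    )
    if unknown:
        raise WisnError(
            "service statistics name activities absent from the standards: "
            + ", ".join(unknown)
        )


def _terse(exc: Exception) -> str:
    # pydantic ValidationErrors are verbose; first line carries the substance
    return str(exc).splitlines()[0]


# ---------------------------------------------------------------- writers

def write_activity_standards(standards: Iterable[ActivityStandard], path: PathLike) -> None:
    frame = pd.DataFrame(
        [
            {
                "cadre": s.cadre,
                "activity": s.activity,
                "category": s.category.value,
                "time_value": s.time_value,
                "time_unit": s.time_unit.value,
            }
            for s in standards
        ]
    )
    frame.to_csv(path, index=False, encoding="utf-8")


def write_staffing(records: Iterable[StaffingRecord], path: PathLike) -> None:
    frame = pd.DataFrame(
        [{"facility": r.facility, "cadre": r.cadre, "available": r.available} for r in records]
    )
    frame.to_csv(path, index=False, encoding="utf-8")


def write_statistics(statistics: Iterable[ServiceStatistics], path: PathLike) -> None:
    rows = [
        {"facility": s.facility, "year": s.year, "activity": a, "annual_count": c}
        for s in statistics
        for a, c in s.counts.items()
    ]
    pd.DataFrame(rows, columns=["facility", "year", "activity", "annual_count"]).to_csv(
        path, index=False, encoding="utf-8"
    )


def write_awt(components: dict[str, AWTComponents], path: PathLike) -> None:
    data = {
        cadre: {k: v for k, v in c.model_dump().items() if k != "cadre"}
        for cadre, c in components.items()
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")


def write_requirements(requirements: Iterable[RequirementResult], path: PathLike) -> None:
    frame = pd.DataFrame(
        [r.model_dump() for r in requirements], columns=REQUIREMENT_COLUMNS
    )
    frame.to_csv(path, index=False, encoding="utf-8")


def read_requirements(path: PathLike) -> list[RequirementResult]:
    frame = _read_csv(path, REQUIREMENT_COLUMNS)
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            RequirementResult(
                facility=row.facility,
                cadre=row.cadre,
                core_requirement=float(row.core_requirement),
                total_cas=float(row.total_cas),
                caf=float(row.caf),
                iaf=float(row.iaf),
                required_raw=float(row.required_raw),
                required=int(row.required),
            )
        )
    return out


def write_results(results: Iterable[WisnResult], path: PathLike) -> None:
    results_to_frame(results).to_csv(path, index=False, encoding="utf-8")


def read_results(path: PathLike) -> list[WisnResult]:
    frame = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in RESULT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(path, [f"missing required column(s): {missing}"])
    return frame_to_results(frame)


# --------------------------------------------------------------- fixtures

def _data_path(name: str):
    return resources.files("wisn.data").joinpath(name)


def load_kaduna_standards() -> list[ActivityStandard]:
    """The published activity-standards table (26 activities, two cadres)."""
    with resources.as_file(_data_path("activity_standards.csv")) as p:
        return read_activity_standards(p)


def load_kaduna_results() -> pd.DataFrame:
    """The published per-facility staffing table for Kaduna North LGA.

    Columns: facility, cadre, available, required, gap, ratio — where gap and
    ratio are the values as printed, kept for verification against the
    package's own computation.
    """
    with resources.as_file(_data_path("wisn_results_kaduna_north.csv")) as p:
        return pd.read_csv(p, encoding="utf-8")


def load_kaduna_staffing() -> list[StaffingRecord]:
    """Available headcounts from the published staffing table."""
    frame = load_kaduna_results()
    return [
        StaffingRecord(facility=row.facility, cadre=row.cadre, available=int(row.available))
        for row in frame.itertuples(index=False)
    ]
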
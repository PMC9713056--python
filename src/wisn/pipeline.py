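"""End-to-end staffing pipeline and run manifests.

``run_pipeline`` composes the stages the study performed in a spreadsheet:
available working time per cadre, standard workloads, per-facility
requirements, gap/ratio metrics, and the scope-level aggregate.  Nothing in
the pipeline consumes randomness; reruns on identical inputs produce
identical outputs, which the manifest hash makes checkable.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from typing import Iterable, Optional

from pydantic import BaseModel

from .io import check_cross_references
from .metrics import AggregateReport, StaffingRecord, WisnResult, aggregate, compute_wisn_result
from .model import (
    ActivityStandard,
    AWTComponents,
    ServiceStatistics,
    WisnError,
    compute_awt,
)
from .requirement import RequirementResult, RoundingMode, compute_requirement

logger = logging.getLogger("wisn")

try:
    __version__ = _pkg_version("wisn")
except PackageNotFoundError:  # pragma: no cover - source tree without install
    __version__ = "0+unknown"


class RunManifest(BaseModel):
    """Provenance record of one pipeline run.

    ``run_hash`` digests the inputs, configuration and outputs (but not the
    timestamp), so two runs on identical inputs yield equal hashes.
    """

    model_config = {"frozen": True}

    input_hashes: dict[str, str]
    config: dict
    package_version: str
    timestamp: str
    seed: Optional[int]
    run_hash: str


class PipelineResult(BaseModel):
    model_config = {"frozen": True}

    requirements: list[RequirementResult]
    results: list[WisnResult]
    aggregate: AggregateReport
    manifest: RunManifest


def _digest(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()


def run_pipeline(
    standards: Iterable[ActivityStandard],
    statistics: Iterable[ServiceStatistics],
    staffing: Iterable[StaffingRecord],
    awt_components: dict[str, AWTComponents],
    *,
    scope: str = "LGA",
    rounding: RoundingMode = "half_up",
    seed: Optional[int] = None,
) -> PipelineResult:
    """Compute requirements, gaps and the aggregate for every staffed
    (facility, cadre) pair.

    Every staffing record must have matching service statistics for its
    facility and absence components for its cadre; any gap aborts with a
    stage-tagged error.
    """
    standards = list(standards)
    statistics = list(statistics)
    staffing = list(staffing)
    logger.info(
        "inputs: %d standards, %d facility statistics, %d staffing records, %d cadre AWTs",
        len(standards), len(statistics), len(staffing), len(awt_components),
    )
    check_cross_references(standards, statistics)

    stats_by_facility = {s.facility: s for s in statistics}
    if len(stats_by_facility) != len(statistics):
        raise WisnError("statistics: duplicate facility entries")

    awt_by_cadre = {}
    for cadre, comp in awt_components.items():
        awt_by_cadre[cadre] = compute_awt(comp)
        logger.info(
            "AWT[%s]: %.1f days, %.1f hours", cadre,
            awt_by_cadre[cadre].awt_days, awt_by_cadre[cadre].awt_hours,
        )

    requirements: list[RequirementResult] = []
    results: list[WisnResult] = []
    for record in staffing:
        stats = stats_by_facility.get(record.facility)
        if stats is None:
            raise WisnError(
                f"requirements stage: no service statistics for facility {record.facility!r}"
            )
        awt = awt_by_cadre.get(record.cadre)
        if awt is None:
            raise WisnError(
                f"requirements stage: no AWT components for cadre {record.cadre!r}"
            )
        req = compute_requirement(stats, standards, awt, rounding)
        requirements.append(req)
        results.append(compute_wisn_result(record, req))
    logger.info("computed %d requirements", len(requirements))

    agg = aggregate(results, scope)
    for cadre, c in agg.cadres.items():
        logger.info(
            "%s/%s: required %d, available %d, difference %d",
            scope, cadre, c.total_required, c.total_available, c.total_difference,
        )

    config = {"scope": scope, "rounding": rounding}
    input_hashes = {
        "standards": _digest([s.model_dump() for s in standards]),
        "statistics": _digest([s.model_dump() for s in statistics]),
        "staffing": _digest([s.model_dump() for s in staffing]),
        "awt": _digest({k: v.model_dump() for k, v in awt_components.items()}),
    }
    run_hash = _digest(
        {
            "inputs": input_hashes,
            "config": config,
            "version": __version__,
            "seed": seed,
            "outputs": [r.model_dump() for r in results],
        }
    )
    manifest = RunManifest(
        input_hashes=input_hashes,
        config=config,
        package_version=__version__,
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        seed=seed,
        run_hash=run_hash,
    )
    return PipelineResult(
        requirements=requirements, results=results, aggregate=agg, manifest=manifest
    )
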
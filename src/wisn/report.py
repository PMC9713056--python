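"""Tabular views of WISN results: machine-readable frames and a text table."""

from __future__ import annotations

import math
from typing import Iterable, Optional

import pandas as pd

from .metrics import AggregateReport, Pressure, WisnResult

RESULT_COLUMNS = ["facility", "cadre", "available", "required", "difference", "ratio", "pressure"]


def format_difference(difference: int) -> str:
    """Signed gap/excess: surpluses print with an explicit '+', zero as '0'."""
    return f"+{difference}" if difference > 0 else str(difference)


def format_ratio(ratio: Optional[float]) -> str:
    return "n/a" if ratio is None else f"{ratio:.2f}"


def results_to_frame(results: Iterable[WisnResult]) -> pd.DataFrame:
    rows = [
        {
            "facility": r.facility,
            "cadre": r.cadre,
            "available": r.available,
            "required": r.required,
            "difference": r.difference,
            "ratio": r.ratio,
            "pressure": r.pressure.value,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def frame_to_results(frame: pd.DataFrame) -> list[WisnResult]:
    out = []
    for row in frame.itertuples(index=False):
        ratio = None if row.ratio is None or (isinstance(row.ratio, float) and math.isnan(row.ratio)) else float(row.ratio)
        out.append(
            WisnResult(
                facility=row.facility,
                cadre=row.cadre,
                available=int(row.available),
                required=int(row.required),
                difference=int(row.difference),
                ratio=ratio,
                pressure=Pressure(row.pressure),
            )
        )
    return out


def _render_rows(header: list[str], rows: list[list[str]]) -> str:
    widths = [max(len(h), *(len(r[i]) for r in rows)) if rows else len(h) for i, h in enumerate(header)]
    def line(cells: list[str]) -> str:
        return "  ".join(c.ljust(w) for c, w in zip(cells, widths)).rstrip()
    sep = "  ".join("-" * w for w in widths)
    return "\n".join([line(header), sep, *(line(r) for r in rows)])


def render_report(
    results: Iterable[WisnResult], aggregate: Optional[AggregateReport] = None
) -> str:
    """Human-readable staffing table, one row per facility and cadre.

    Mirrors the conventional WISN results layout: available, calculated
    (required), gap/excess with explicit sign, and the 2-decimal WISN ratio,
    followed by per-cadre totals when an aggregate is given.
    """
    results = list(results)
    header = ["facility", "cadre", "available", "calculated", "gap/excess", "WISN ratio"]
    rows = [
        [
            r.facility,
            r.cadre,
            str(r.available),
            str(r.required),
            format_difference(r.difference),
            format_ratio(r.ratio),
        ]
        for r in results
    ]
    text = _render_rows(header, rows)
    if aggregate is not None:
        agg_header = [
            "scope", "cadre", "available", "calculated", "gap/excess",
            "coverage %", "shortage", "balanced", "surplus",
        ]
        agg_rows = [
            [
                aggregate.scope,
                c.cadre,
                str(c.total_available),
                str(c.total_required),
                format_difference(c.total_difference),
                "n/a" if c.coverage_percent is None else str(c.coverage_percent),
                str(c.n_shortage),
                str(c.n_balanced),
                str(c.n_surplus),
            ]
            for c in aggregate.cadres.values()
        ]
        text += "\n\n" + _render_rows(agg_header, agg_rows)
    return text
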
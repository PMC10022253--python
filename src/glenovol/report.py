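"""Machine-readable analysis reports (JSON/CSV) with a shipped JSON schema.

Printed precision follows the clinical reporting convention used throughout
the package: volumes and descriptive statistics to 2 decimals, correlation
coefficients to 2 decimals, p-values to 4 decimals.  ICC values are kept at
3 decimals.  Field order is deterministic so reruns are byte-identical.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ValidationError

from .errors import FormatError

__all__ = ["SummaryRow", "CorrelationCell", "ICCReport", "AnalysisReport",
           "build_report", "write_report", "read_report", "validate_report",
           "report_json_schema"]


class SummaryRow(BaseModel):
    variable: str
    mean: float | None = None
    sd: float | None = None
    min: float | None = None
    max: float | None = None
    n: int


class CorrelationCell(BaseModel):
    r: float
    p: float
    n: int
    significant: bool


class ICCReport(BaseModel):
    value: float
    model: str
    category: str
    n_subjects: int
    n_raters: int


class AnalysisReport(BaseModel):
    """Top-level report: descriptives, correlation grid, optional reliability."""

    schema_version: str = "1"
    seed: int | None = None
    n_patients: int
    descriptives: list[SummaryRow]
    correlations: dict[str, dict[str, CorrelationCell]]  # motion -> volume -> cell
    iccs: dict[str, ICCReport] | None = None
    notes: list[str] = []


_DEFAULT_NOTES = [
    "volumes in mL; angles in degrees; IRb as ordinal vertebral-level score 1-18",
    "p-values two-sided, from the t transform with n-2 df, unadjusted for multiplicity",
]


def _round(x: float, nd: int) -> float:
    return float(np.round(float(x), nd))


def build_report(results, reliability=None, seed: int | None = None) -> AnalysisReport:
    """Assemble an :class:`AnalysisReport` from fitted results objects.

    ``results`` is a :class:`~glenovol.stats.VolumeROMResults`;
    ``reliability`` is an optional mapping of analysis name (for example
    ``"interobserver"``) to :class:`~glenovol.stats.ReliabilityResults`.
    """
    if len(results.model.cohort) == 0:
        raise ValueError("cannot report on an empty cohort")
    rows = []
    for var, row in results.descriptives.iterrows():
        if np.isnan(row["mean"]):
            rows.append(SummaryRow(variable=str(var), n=int(row["n"])))
        else:
            rows.append(SummaryRow(variable=str(var), mean=_round(row["mean"], 2),
                                   sd=_round(row["sd"], 2), min=_round(row["min"], 2),
                                   max=_round(row["max"], 2), n=int(row["n"])))
    correlations = {}
    for m in results.model.motion_cols:
        correlations[m] = {}
        for v in results.model.volume_cols:
            c = results.grid.cell(m, v)
            correlations[m][v] = CorrelationCell(r=_round(c.r, 2), p=_round(c.p, 4),
                                                 n=c.n, significant=c.significant)
    iccs = None
    if reliability:
        iccs = {name: ICCReport(value=_round(res.icc.value, 3), model=res.icc.model,
                                category=res.icc.category,
                                n_subjects=res.icc.n_subjects, n_raters=res.icc.n_raters)
                for name, res in reliability.items()}
    return AnalysisReport(seed=seed, n_patients=len(results.model.cohort),
                          descriptives=rows, correlations=correlations,
                          iccs=iccs, notes=list(_DEFAULT_NOTES))


def write_report(report: AnalysisReport, path: str | Path, format: str = "json") -> Path:
    """Write the report as JSON or flat CSV with deterministic field order."""
    path = Path(path)
    if format == "json":
        path.write_text(report.model_dump_json(indent=2) + "\n")
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(["section", "key", "field", "value"])
            w.writerow(["meta", "schema_version", "", report.schema_version])
            w.writerow(["meta", "seed", "", "" if report.seed is None else report.seed])
            w.writerow(["meta", "n_patients", "", report.n_patients])
            for row in report.descriptives:
                for fld in ("mean", "sd", "min", "max", "n"):
                    val = getattr(row, fld)
                    if val is not None:
                        w.writerow(["descriptives", row.variable, fld, val])
            for m, cells in report.correlations.items():
                for v, c in cells.items():
                    for fld in ("r", "p", "n", "significant"):
                        w.writerow(["correlations", f"{m}|{v}", fld, getattr(c, fld)])
            for name, icc in (report.iccs or {}).items():
                for fld in ("value", "model", "category", "n_subjects", "n_raters"):
                    w.writerow(["icc", name, fld, getattr(icc, fld)])
            for i, note in enumerate(report.notes):
                w.writerow(["notes", str(i), "", note])
    else:
        raise ValueError(f"unknown report format {format!r}; use 'json' or 'csv'")
    return path


def read_report(path: str | Path) -> AnalysisReport:
    """Read and validate a JSON report."""
    try:
        return AnalysisReport.model_validate_json(Path(path).read_text())
    except (ValidationError, OSError) as exc:
        raise FormatError(f"{path}: not a valid analysis report ({exc})") from exc


def validate_report(data: dict) -> AnalysisReport:
    """Validate a report dictionary against the schema; returns the model."""
    try:
        return AnalysisReport.model_validate(data)
    except ValidationError as exc:
        raise FormatError(f"report does not conform to the schema: {exc}") from exc


def report_json_schema() -> dict:
    """The JSON schema of the report format (also shipped under schemas/)."""
    return AnalysisReport.model_json_schema()


def dump_schema(path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report_json_schema(), indent=2, sort_keys=True) + "\n")
    return path
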
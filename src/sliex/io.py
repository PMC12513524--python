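"""Tabular readers and writers for panels, results and ratings.

Panels use a wide one-row-per-subject schema (``subject_id``, ``arm``,
``unit`` and ``<marker>_pre`` / ``<marker>_post`` columns); headers are
case-insensitive and the delimiter (comma or tab) is auto-detected.  Blank
cells are missing markers.  Row-level problems are collected as diagnostics
rather than aborting the read; only a file with zero valid rows is a hard
error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import RatingsMatrix
from .domain import LipidPanel, Marker, Unit
from .errors import DomainError, NoValidRowsError, SliexError
from .scoring import SliexResult, round_percent, score_panel

__all__ = [
    "PanelRecord",
    "read_panels",
    "write_results",
    "results_frame",
    "read_ratings",
    "write_ratings",
    "write_panel_records",
]

logger = logging.getLogger("sliex")

_MARKER_COLUMNS: dict[str, Marker] = {
    "tg": Marker.TG,
    "ldl": Marker.LDL_C,
    "hdl": Marker.HDL_C,
    "tc": Marker.TC,
}

_UNIT_ALIASES: dict[str, Unit] = {
    "mmol/l": Unit.MMOL_PER_L,
    "mmol per l": Unit.MMOL_PER_L,
    "mmoll": Unit.MMOL_PER_L,
    "mg/dl": Unit.MG_PER_DL,
    "mg.dl": Unit.MG_PER_DL,
    "mgdl": Unit.MG_PER_DL,
}


def parse_unit(text: str | Unit) -> Unit:
    """Parse a unit string, tolerating case and mg.dL-style punctuation."""
    if isinstance(text, Unit):
        return text
    key = str(text).strip().lower().replace(" ", "")
    key = key.replace(".", "/") if key in {"mg.dl", "mmol.l"} else key
    for alias, unit in _UNIT_ALIASES.items():
        if key == alias.replace(" ", ""):
            return unit
    raise DomainError(f"unknown unit string: {text!r}")


@dataclass(frozen=True)
class PanelRecord:
    """One subject's (or study arm's) wide-format pre/post lipid panel."""

    subject_id: str
    arm: str = ""
    unit: Unit = Unit.MMOL_PER_L
    tg_pre: float | None = None
    tg_post: float | None = None
    ldl_pre: float | None = None
    ldl_post: float | None = None
    hdl_pre: float | None = None
    hdl_post: float | None = None
    tc_pre: float | None = None
    tc_post: float | None = None

    def panels(self) -> tuple[LipidPanel, LipidPanel]:
        """Build the (pre, post) panels from the markers present at both
        timepoints."""
        pre_vals: dict[Marker, float] = {}
        post_vals: dict[Marker, float] = {}
        for col, marker in _MARKER_COLUMNS.items():
            pre = getattr(self, f"{col}_pre")
            post = getattr(self, f"{col}_post")
            if pre is not None and post is not None:
                pre_vals[marker] = pre
                post_vals[marker] = post
        return LipidPanel(pre_vals, self.unit), LipidPanel(post_vals, self.unit)

    def score(self, tolerance: float = 0.0) -> SliexResult:
        pre, post = self.panels()
        return score_panel(
            pre, post, tolerance=tolerance, subject_id=self.subject_id, arm=self.arm
        )


def _parse_cell(raw, row_label: str, column: str) -> float | None:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = str(raw).strip()
    if not text:
        return None
    try:
        value = float(text)
    except ValueError:
        raise ValueError(f"row {row_label}: malformed number {text!r} in {column}")
    if not np.isfinite(value) or value <= 0:
        raise ValueError(
            f"row {row_label}: {column} must be a finite positive value, got {value}"
        )
    return value


def read_panels(
    path: str | Path,
    unit_override: Unit | str | None = None,
    errors: list[str] | None = None,
) -> list[PanelRecord]:
    """Read wide-format panel records from a CSV/TSV file.

    Parameters
    ----------
    path
        Input file; must have a header row.  Delimiter is auto-detected.
    unit_override
        Use this unit for every row, ignoring any ``unit`` column.
    errors
        Optional list that receives one message per rejected row.

    Raises
    ------
    NoValidRowsError
        If the file yields no valid record at all.
    """
    path = Path(path)
    if unit_override is not None:
        unit_override = parse_unit(unit_override)
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except (pd.errors.EmptyDataError, csv.Error):
        # sep sniffing raises csv.Error on empty/one-column files
        raise NoValidRowsError(f"{path}: empty or undelimited file") from None
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "subject_id" not in df.columns:
        raise NoValidRowsError(f"{path}: missing required column 'subject_id'")

    value_cols = [f"{c}_{t}" for c in _MARKER_COLUMNS for t in ("pre", "post")]
    records: list[PanelRecord] = []
    diagnostics: list[str] = []
    for idx, row in df.iterrows():
        label = str(row.get("subject_id", idx)).strip() or f"#{idx}"
        try:
            if unit_override is not None:
                unit = unit_override
            elif "unit" in df.columns and isinstance(row["unit"], str) and row["unit"].strip():
                unit = parse_unit(row["unit"])
            else:
                unit = Unit.MMOL_PER_L
            values = {
                col: _parse_cell(row.get(col), label, col)
                for col in value_cols
                if col in df.columns
            }
            record = PanelRecord(
                subject_id=label,
                arm=str(row["arm"]).strip() if "arm" in df.columns and isinstance(row["arm"], str) else "",
                unit=unit,
                **values,
            )
            # A record must be scoreable: at least one marker at both timepoints.
            record.panels()
            records.append(record)
        except (ValueError, SliexError) as exc:
            diagnostics.append(f"row {label}: {exc}")
            logger.warning("skipping %s", diagnostics[-1])
    if errors is not None:
        errors.extend(diagnostics)
    if not records:
        raise NoValidRowsError(
            f"{path}: no valid rows ({len(diagnostics)} rejected)"
        )
    return records


_RESULT_COLUMNS = [
    "subject_id",
    "arm",
    "tg_change",
    "tg_weightage",
    "ldl_change",
    "ldl_weightage",
    "hdl_change",
    "hdl_weightage",
    "tc_change",
    "tc_weightage",
    "change_sum",
    "weightage_sum",
    "total",
    "attainable_max",
    "percent",
    "classification",
    "missing_markers",
    "worsened",
]

_MARKER_PREFIX = {Marker.TG: "tg", Marker.LDL_C: "ldl", Marker.HDL_C: "hdl", Marker.TC: "tc"}


def results_frame(results: list[SliexResult]) -> pd.DataFrame:
    """Results as a DataFrame in the canonical column order; percent is
    rounded half-up to one decimal for reporting."""
    rows = []
    for res in results:
        row: dict[str, object] = {c: None for c in _RESULT_COLUMNS}
        row["subject_id"] = res.subject_id or ""
        row["arm"] = res.arm or ""
        for s in res.per_marker:
            prefix = _MARKER_PREFIX[s.marker]
            row[f"{prefix}_change"] = s.change
            row[f"{prefix}_weightage"] = s.weightage
        row["change_sum"] = res.change_sum
        row["weightage_sum"] = res.weightage_sum
        row["total"] = res.total
        row["attainable_max"] = res.attainable_max
        row["percent"] = round_percent(res.percent)
        row["classification"] = res.classification.value
        row["missing_markers"] = ";".join(
            sorted(m.value for m in res.missing_markers)
        )
        row["worsened"] = res.worsened
        rows.append(row)
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


def write_results(
    results: list[SliexResult], path: str | Path, format: str = "csv"
) -> None:
    """Write scored results to ``path`` as CSV or JSON."""
    if not results:
        raise SliexError("no results to write")
    df = results_frame(results)
    path = Path(path)
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "json":
        payload = df.to_dict(orient="records")
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    else:
        raise DomainError(f"unknown output format {format!r}; use 'csv' or 'json'")


def read_ratings(path: str | Path) -> RatingsMatrix:
    """Read a raters-in-columns score matrix.

    The first column holds item identifiers; every remaining column is one
    rater's integer scores.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 3:
        raise NoValidRowsError(
            f"{path}: need an item column plus >= 2 rater columns"
        )
    items = tuple(str(v) for v in df.iloc[:, 0])
    scores = df.iloc[:, 1:].to_numpy()
    return RatingsMatrix(
        scores=scores,
        items=items,
        raters=tuple(str(c) for c in df.columns[1:]),
    )


def write_ratings(ratings: RatingsMatrix, path: str | Path) -> None:
    """Write a ratings matrix in the schema ``read_ratings`` expects."""
    df = ratings.to_frame()
    df.insert(0, "item", list(ratings.items))
    df.to_csv(path, index=False)


def write_panel_records(records: list[PanelRecord], path: str | Path) -> None:
    """Write panel records in the schema ``read_panels`` expects."""
    rows = []
    for rec in records:
        row = {
            f.name: getattr(rec, f.name)
            for f in fields(PanelRecord)
        }
        row["unit"] = rec.unit.value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
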
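"""CSV/TSV readers and writers for the curation tables.

Column names are lower-snake-case versions of the classic activity-table
columns (published_value, standard_units, data_validity_comment, ...).
Empty cells are absent values; malformed numeric cells (including
comma-decimal numerals, which are rejected rather than guessed) send the
whole row to a rejects report instead of being silently dropped.
"""

from __future__ import annotations

import csv
import json
import os
from typing import Optional

import pandas as pd

from .pipeline import CurationReport
from .records import ActivityRecord, AssayRecord, CompoundRecord
from .synthetic import SyntheticGroundTruth

ACTIVITY_REQUIRED = [
    "record_id",
    "document_id",
    "assay_id",
    "compound_id",
    "published_type",
    "published_relation",
    "published_value",
    "published_units",
]
ACTIVITY_OPTIONAL = [
    "document_year",
    "activity_comment",
    "standard_type",
    "standard_relation",
    "standard_value",
    "standard_units",
    "pchembl_value",
    "data_validity_comment",
    "potential_duplicate",
]
ACTIVITY_COLUMNS = ACTIVITY_REQUIRED[:4] + ["document_year"] + ACTIVITY_REQUIRED[4:] + ACTIVITY_OPTIONAL[1:]


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def _read_table(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def _opt(cell: Optional[str]) -> Optional[str]:
    return None if cell is None or cell == "" else cell


class RowReject:
    def __init__(self, row: int, column: str, value: str, reason: str):
        self.row, self.column, self.value, self.reason = row, column, value, reason

    def as_dict(self) -> dict:
        return {
            "row": self.row,
            "column": self.column,
            "value": self.value,
            "reason": self.reason,
        }


def _parse_float(cell: Optional[str]) -> Optional[float]:
    cell = _opt(cell)
    if cell is None:
        return None
    return float(cell)  # raises on comma decimals and other malformed cells


def _parse_int(cell: Optional[str]) -> Optional[int]:
    cell = _opt(cell)
    if cell is None:
        return None
    return int(cell)  # raises on malformed cells


def _parse_bool(cell: Optional[str]) -> bool:
    return _opt(cell) in ("True", "true", "1", "TRUE")


def read_activities(path) -> tuple[list[ActivityRecord], list[RowReject]]:
    """Read the activities table; returns (records, rejects)."""
    df = _read_table(path, ACTIVITY_REQUIRED)
    records: list[ActivityRecord] = []
    rejects: list[RowReject] = []
    for i, row in enumerate(df.to_dict(orient="records")):
        try:
            record = ActivityRecord(
                record_id=row["record_id"],
                document_id=row["document_id"],
                document_year=_parse_int(row.get("document_year")),
                assay_id=row["assay_id"],
                compound_id=row["compound_id"],
                published_type=_opt(row.get("published_type")),
                published_relation=_opt(row.get("published_relation")),
                published_value=_parse_float(row.get("published_value")),
                published_units=_opt(row.get("published_units")),
                activity_comment=_opt(row.get("activity_comment")),
                standard_type=_opt(row.get("standard_type")),
                standard_relation=_opt(row.get("standard_relation")),
                standard_value=_parse_float(row.get("standard_value")),
                standard_units=_opt(row.get("standard_units")),
                pchembl_value=_parse_float(row.get("pchembl_value")),
                data_validity_comment=_opt(row.get("data_validity_comment")),
                potential_duplicate=_parse_bool(row.get("potential_duplicate")),
            )
        except (ValueError, TypeError) as exc:
            rejects.append(RowReject(i, "numeric", str(row), str(exc)))
            continue
        records.append(record)
    return records, rejects


def read_compounds(path) -> list[CompoundRecord]:
    df = _read_table(path, ["compound_id"])
    return [
        CompoundRecord(
            compound_id=row["compound_id"],
            molecular_weight=_parse_float(row.get("molecular_weight")),
        )
        for row in df.to_dict(orient="records")
    ]


def read_assays(path) -> list[AssayRecord]:
    df = _read_table(path, ["assay_id", "document_id"])
    out = []
    for row in df.to_dict(orient="records"):
        out.append(
            AssayRecord(
                assay_id=row["assay_id"],
                document_id=row["document_id"],
                description=row.get("description", "") or "",
                assay_type=_opt(row.get("assay_type")),
                bao_format=_opt(row.get("bao_format")) or "unassigned",
                relationship_type=_opt(row.get("relationship_type")) or "D",
                target_id=_opt(row.get("target_id")),
                cell_line_token=_opt(row.get("cell_line_token")),
                therapeutic_context=_parse_bool(row.get("therapeutic_context")),
            )
        )
    return out


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "True" if value else "False"
    if isinstance(value, float):
        return repr(value)  # shortest round-tripping decimal
    return str(value)


def write_activities(records: list[ActivityRecord], path) -> None:
    """Write curated activities, preserving input row order and every
    published field verbatim (lossless float formatting)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=_sep(path))
        writer.writerow(ACTIVITY_COLUMNS)
        for r in records:
            writer.writerow([_fmt(getattr(r, c)) for c in ACTIVITY_COLUMNS])


def write_compounds(compounds: list[CompoundRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=_sep(path))
        writer.writerow(["compound_id", "molecular_weight"])
        for c in compounds:
            writer.writerow([c.compound_id, _fmt(c.molecular_weight)])


def write_assays(assays: list[AssayRecord], path) -> None:
    cols = [
        "assay_id",
        "document_id",
        "description",
        "assay_type",
        "bao_format",
        "relationship_type",
        "target_id",
        "cell_line_token",
        "therapeutic_context",
    ]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=_sep(path))
        writer.writerow(cols)
        for a in assays:
            writer.writerow([_fmt(getattr(a, c)) for c in cols])


def write_truth(truth: SyntheticGroundTruth, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=_sep(path))
        writer.writerow(["record_id", "labels"])
        for rid in sorted(truth.labels):
            writer.writerow([rid, "|".join(truth.labels[rid])])


def read_truth(path) -> SyntheticGroundTruth:
    df = _read_table(path, ["record_id", "labels"])
    labels = {
        row["record_id"]: row["labels"].split("|") if row["labels"] else ["clean"]
        for row in df.to_dict(orient="records")
    }
    return SyntheticGroundTruth(labels=labels)


def write_report(report: CurationReport, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report.model_dump(), fh, indent=2)
        fh.write("\n")


def write_rejects(rejects: list[RowReject], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([r.as_dict() for r in rejects], fh, indent=2)
        fh.write("\n")


def ensure_dir(path) -> None:
    os.makedirs(path, exist_ok=True)
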
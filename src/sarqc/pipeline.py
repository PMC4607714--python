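"""The seven-step activity curation workflow and its report.

Order of operations on a loaded corpus:

1. flag missing activities ('Potential missing data')
2. flag non-standard units for the activity type ('Non standard unit for type')
3. convert log activity values (part of standardization, counted here)
4. flag out-of-range values ('Outside typical range'), fragment-aware
5. flag potential duplicate values (POTENTIAL_DUPLICATE column)
6. flag potential transcription errors ('Potential transcription error')
7. calculate standard negative log values (pChEMBL)

The pipeline never deletes or reorders records and contains no
randomness: identical inputs and config give identical outputs, and
re-running it on its own output is a no-op.
"""

from __future__ import annotations

from typing import Iterable, Optional

from pydantic import BaseModel

from .config import CurationConfig
from .flags import flag_missing, flag_nonstandard_units, flag_out_of_range
from .pchembl import compute_pchembl
from .records import (
    MISSING_DATA,
    NONSTANDARD_UNIT,
    OUT_OF_RANGE,
    TRANSCRIPTION_ERROR,
    ActivityRecord,
    AssayRecord,
    CompoundRecord,
)
from .redundancy import apply_redundancy_flags
from .standardize import is_log_type, standardize_record


class ReportRow(BaseModel):
    order: int
    step: str
    data_validity_comment: Optional[str] = None
    count: int
    percentage: float


class CurationReport(BaseModel):
    """Per-step counts and percentages of affected records."""

    corpus_size: int
    rows: list[ReportRow]


def _pct(count: int, total: int) -> float:
    return round(100.0 * count / total, 2) if total else 0.0


def run_pipeline(
    records: Iterable[ActivityRecord],
    compounds: Iterable[CompoundRecord],
    assays: Iterable[AssayRecord],
    config: CurationConfig,
) -> tuple[list[ActivityRecord], CurationReport]:
    """Standardize, flag and annotate a corpus; return curated records and
    the per-step report. Input records are not mutated."""
    curated = [r.model_copy(deep=True) for r in records]
    compound_of = {c.compound_id: c for c in compounds}
    assays = list(assays)

    log_converted = 0
    for r in curated:
        if r.published_value is not None and is_log_type(r.published_type, config):
            log_converted += 1
        standardize_record(r, compound_of.get(r.compound_id), config)

    for r in curated:
        flag_missing(r)
    for r in curated:
        flag_nonstandard_units(r, config)
    for r in curated:
        flag_out_of_range(r, compound_of.get(r.compound_id), config)

    curated, redundancy_counts = apply_redundancy_flags(curated, assays)

    pchembl_count = 0
    for r in curated:
        r.pchembl_value = compute_pchembl(
            r.standard_type,
            r.standard_relation,
            r.standard_value,
            r.standard_units,
            r.data_validity_comment,
            config,
        )
        if r.pchembl_value is not None:
            pchembl_count += 1

    n = len(curated)

    def comment_count(comment: str) -> int:
        return sum(1 for r in curated if r.data_validity_comment == comment)

    rows = [
        ReportRow(
            order=1,
            step="Flag missing activities",
            data_validity_comment=MISSING_DATA,
            count=comment_count(MISSING_DATA),
            percentage=_pct(comment_count(MISSING_DATA), n),
        ),
        ReportRow(
            order=2,
            step="Flag non-standard units for activity type",
            data_validity_comment=NONSTANDARD_UNIT,
            count=comment_count(NONSTANDARD_UNIT),
            percentage=_pct(comment_count(NONSTANDARD_UNIT), n),
        ),
        ReportRow(
            order=3,
            step="Convert log activity values",
            data_validity_comment=None,
            count=log_converted,
            percentage=_pct(log_converted, n),
        ),
        ReportRow(
            order=4,
            step="Flag out of range values",
            data_validity_comment=OUT_OF_RANGE,
            count=comment_count(OUT_OF_RANGE),
            percentage=_pct(comment_count(OUT_OF_RANGE), n),
        ),
        ReportRow(
            order=5,
            step="Flag potential duplicate values",
            data_validity_comment=None,
            count=redundancy_counts["potential_duplicate"],
            percentage=_pct(redundancy_counts["potential_duplicate"], n),
        ),
        ReportRow(
            order=6,
            step="Flag potential transcription errors",
            data_validity_comment=TRANSCRIPTION_ERROR,
            count=comment_count(TRANSCRIPTION_ERROR),
            percentage=_pct(comment_count(TRANSCRIPTION_ERROR), n),
        ),
        ReportRow(
            order=7,
            step="Calculate standard negative log values",
            data_validity_comment=None,
            count=pchembl_count,
            percentage=_pct(pchembl_count, n),
        ),
    ]
    return curated, CurationReport(corpus_size=n, rows=rows)
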
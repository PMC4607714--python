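"""Validity flagging: missing data, non-standard units, out-of-range values.

Flagging never deletes or reorders records — a flag is a single
``data_validity_comment`` string per record, and a record that already
carries a comment from an earlier (more fundamental) step is left alone.
The out-of-range step honours the fragment exception: compounds below the
fragment molecular-weight threshold are genuinely weak binders, so their
upper range bound is relaxed by a configurable factor.
"""

from __future__ import annotations

from typing import Optional

from .config import CurationConfig
from .records import (
    MISSING_DATA,
    NONSTANDARD_UNIT,
    OUT_OF_RANGE,
    ActivityRecord,
    CompoundRecord,
)


def flag_missing(record: ActivityRecord) -> ActivityRecord:
    """Flag records with neither a published value nor an activity comment."""
    if record.data_validity_comment is not None:
        return record
    if record.published_value is None and record.activity_comment is None:
        record.data_validity_comment = MISSING_DATA
    return record


def flag_nonstandard_units(
    record: ActivityRecord, config: CurationConfig
) -> ActivityRecord:
    """Flag records whose standard units are irrelevant, unknown or null
    for their standard type.

    Only types with a declared allowed-unit set participate; absent units
    count as non-standard for those types. Records flagged by an earlier
    step are skipped.
    """
    if record.data_validity_comment is not None:
        return record
    stype = record.standard_type
    if stype is None or stype not in config.allowed_units:
        return record
    if record.published_value is None:
        return record
    allowed = config.allowed_units[stype]
    if record.standard_units is None or record.standard_units not in allowed:
        record.data_validity_comment = NONSTANDARD_UNIT
    return record


def value_out_of_range(
    standard_value: float,
    standard_type: str,
    standard_units: str,
    molecular_weight: Optional[float],
    config: CurationConfig,
) -> bool:
    """Whether a standardized value falls outside its typical range.

    Ranges are inclusive and opt-in: a (type, unit) pair without an entry
    is never out of range. For fragments (MW below the threshold) the
    upper bound is multiplied by the relaxation factor, so relaxation can
    only ever unflag.
    """
    bounds = config.typical_range(standard_type, standard_units)
    if bounds is None:
        return False
    low, high = bounds
    if (
        molecular_weight is not None
        and molecular_weight < config.fragment_mw_threshold
    ):
        high = high * config.fragment_range_relaxation
    return not (low <= standard_value <= high)


def flag_out_of_range(
    record: ActivityRecord,
    compound: Optional[CompoundRecord],
    config: CurationConfig,
) -> ActivityRecord:
    """Flag unusually low or high standardized values for their type/unit."""
    if record.data_validity_comment is not None:
        return record
    if (
        record.standard_value is None
        or record.standard_type is None
        or record.standard_units is None
    ):
        return record
    mw = compound.molecular_weight if compound is not None else None
    if value_out_of_range(
        record.standard_value, record.standard_type, record.standard_units, mw, config
    ):
        record.data_validity_comment = OUT_OF_RANGE
    return record
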
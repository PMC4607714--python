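"""Standardization of published activity types, relations, values and units.

Published measurements arrive in dozens of spellings of the same type
('Half life', 'T1/2', 't(1/2)') and unit ('uM', 'umol/L', 'micromolar').
This module normalizes types through a synonym table, unlogs logarithmic
types (pKi -> Ki with the censoring relation flipped), converts units
within their dimension class (molar concentrations to nM, mass
concentrations to ug.mL-1, exposure to ng.h.mL-1, time to hr) and applies
the two-tier rounding rule: values below 10 are rounded arithmetically
(half-up) to 3 significant figures, the rest to 2 decimal places.

Cross-class conversion (mass <-> molar via molecular weight) is
deliberately not performed: a published mass concentration stays on the
mass scale.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

from .config import CurationConfig
from .records import ActivityRecord, CompoundRecord

#: Unit classes that denote a physical concentration (must be positive).
CONCENTRATION_CLASSES = {"molar_concentration", "mass_concentration", "exposure"}

_RELATION_FLIP = {"<": ">", "<=": ">=", "=": "=", ">=": "<=", ">": "<", "~": "~"}

_WS_RE = re.compile(r"\s+")
_SEP_RE = re.compile(r"[\s×*·]+")
_DOT_RE = re.compile(r"\.+")


@dataclass(frozen=True)
class StandardQuantity:
    """A standardized (type, relation, value, unit) quadruple."""

    standard_type: str
    standard_relation: Optional[str]
    standard_value: float
    standard_units: str


def _norm_type_key(text: str) -> str:
    """Case/whitespace/parenthesis-insensitive key for the synonym table."""
    return re.sub(r"[\s()]", "", text.strip().lower())


def normalize_unit(text: str) -> str:
    """Normalize a published unit spelling for table lookup.

    Lower-cases, maps the Greek mu to 'u', unifies the multiplication
    separators ('.', 'x', '*', middle dot, whitespace) to a single '.' and
    the minus sign to '-'.
    """
    s = text.strip().lower()
    s = s.replace("µ", "u").replace("μ", "u")  # µ, μ
    s = s.replace("−", "-").replace("⋅", "·")
    s = _SEP_RE.sub(".", s)
    s = _DOT_RE.sub(".", s)
    return s.strip(".")


def normalize_type(published_type: str, config: CurationConfig) -> str:
    """Map a published activity type to its canonical standard type.

    Unknown types pass through with surrounding/duplicate whitespace
    collapsed, so that downstream lookups see a stable spelling.
    """
    cleaned = _WS_RE.sub(" ", published_type.strip())
    return config.type_synonyms.get(_norm_type_key(cleaned), cleaned)


def flip_relation(relation: Optional[str]) -> Optional[str]:
    """Mirror a censoring relation under sign inversion ('>' <-> '<')."""
    if relation is None:
        return None
    return _RELATION_FLIP.get(relation, relation)


def _decimal(value: float) -> Decimal:
    # repr() gives the shortest decimal string that round-trips the float,
    # so half-up rounding acts on the printed value, not binary noise.
    return Decimal(repr(float(value)))


def round_sig(value: float, n: int) -> float:
    """Round to *n* significant figures, ties away from zero (half-up)."""
    if value == 0:
        return 0.0
    d = _decimal(value)
    quantum = Decimal(1).scaleb(d.adjusted() - (n - 1))
    return float(d.quantize(quantum, rounding=ROUND_HALF_UP))


def round_standard_value(value: float) -> float:
    """Two-tier arithmetic rounding of a standard activity value.

    Magnitudes below 10 are rounded half-up to 3 significant figures;
    everything else to the second decimal digit.
    """
    d = _decimal(value)
    if abs(d) < 10:
        return round_sig(value, 3)
    return float(d.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def convert_units(
    value: float,
    relation: Optional[str],
    published_units: Optional[str],
    standard_type: str,
    config: CurationConfig,
) -> Optional[StandardQuantity]:
    """Convert a published value to the standard unit of its dimension class.

    Returns ``None`` (a failure marker, consumed by the non-standard-unit
    flagging step) when the unit spelling is unknown, the dialect is not
    applicable to the standard type, or a concentration is non-positive.
    The conversion never crosses dimension classes.
    """
    if published_units is None:
        return None
    entry = _conversion_index(config).get(normalize_unit(published_units))
    if entry is None:
        return None
    if (
        entry.applicable_standard_types is not None
        and standard_type not in entry.applicable_standard_types
    ):
        return None
    if entry.unit_class in CONCENTRATION_CLASSES and value <= 0:
        return None
    return StandardQuantity(
        standard_type=standard_type,
        standard_relation=relation,
        standard_value=value * entry.factor,
        standard_units=entry.standard_unit,
    )


_INDEX_CACHE: dict[int, dict] = {}


def _conversion_index(config: CurationConfig):
    key = id(config)
    index = _INDEX_CACHE.get(key)
    if index is None:
        index = {normalize_unit(e.pattern): e for e in config.unit_conversions}
        _INDEX_CACHE.clear()  # keep at most one config's index around
        _INDEX_CACHE[key] = index
    return index


def unlog_value(
    standard_type: str,
    value: float,
    relation: Optional[str],
    config: CurationConfig,
) -> Optional[StandardQuantity]:
    """Unlog a logarithmic activity type onto the nM scale.

    pKi = 9 becomes Ki = 1 nM; censoring relations are flipped for
    negative-log types (pKi > 6 means Ki < 1000 nM). Unknown log types
    return ``None`` and the record passes through untouched.
    """
    rule = config.log_types.get(standard_type)
    if rule is None:
        return None
    exponent = -value if rule.negative_log else value
    if rule.reference == "M":
        value_nm = 10.0 ** (exponent + 9.0)
    else:
        value_nm = 10.0 ** exponent
    out_relation = flip_relation(relation) if rule.negative_log else relation
    return StandardQuantity(
        standard_type=rule.standard_type,
        standard_relation=out_relation,
        standard_value=value_nm,
        standard_units="nM",
    )


def is_log_type(published_type: Optional[str], config: CurationConfig) -> bool:
    """Whether a published type unlogs to a linear standard type."""
    if published_type is None:
        return False
    return normalize_type(published_type, config) in config.log_types


def standardize_record(
    record: ActivityRecord,
    compound: Optional[CompoundRecord],
    config: CurationConfig,
) -> ActivityRecord:
    """Populate the standard_* fields of a record from its published fields.

    Composition: normalize_type -> unlog_value (log types) -> convert_units
    -> round_standard_value. Published fields are never touched. On
    conversion failure the published value/units pass through to the
    standard fields unchanged so the unit flagging step can inspect them;
    with no published value the standard fields stay absent.

    The function is deterministic in the published fields, hence idempotent
    under re-runs of the pipeline. ``compound`` is accepted for interface
    stability (mass <-> molar conversion via MW is out of scope).
    """
    del compound  # not used: no cross-class conversion
    record.standard_type = None
    record.standard_relation = None
    record.standard_value = None
    record.standard_units = None
    if record.published_value is None:
        return record

    stype = (
        normalize_type(record.published_type, config)
        if record.published_type is not None
        else None
    )
    relation = record.published_relation

    quantity: Optional[StandardQuantity] = None
    if stype is not None and stype in config.log_types:
        quantity = unlog_value(stype, record.published_value, relation, config)
    elif stype is not None:
        quantity = convert_units(
            record.published_value, relation, record.published_units, stype, config
        )

    if quantity is None:
        # failure marker: keep published value/units for the unit flagger
        record.standard_type = stype
        record.standard_relation = relation
        record.standard_value = record.published_value
        record.standard_units = record.published_units
        return record

    record.standard_type = quantity.standard_type
    record.standard_relation = quantity.standard_relation
    record.standard_value = round_standard_value(quantity.standard_value)
    record.standard_units = quantity.standard_units
    return record
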
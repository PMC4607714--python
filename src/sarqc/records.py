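"""Core record types shared by every curation stage.

The tables mirror the experimental-data section of a literature-extracted
bioactivity database: per-measurement activity records that keep the
published type/relation/value/units verbatim next to their standardized
counterparts, the compound and assay tables they reference, and the target
taxonomy used for target assignment.

Validation never raises: :func:`validate_record` and
:func:`validate_target` return lists of human-readable violation
descriptions so that dirty input can be inventoried instead of rejected.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, field_validator

#: Relation vocabulary for published/standard relations. '~' is treated as
#: '=' for flagging purposes but never yields a pChEMBL value.
RELATIONS = ("<", "<=", "=", ">=", ">", "~")

#: The complete data-validity comment vocabulary. One comment per record;
#: the duplicate flag is carried separately in ``potential_duplicate``.
MISSING_DATA = "Potential missing data"
NONSTANDARD_UNIT = "Non standard unit for type"
OUT_OF_RANGE = "Outside typical range"
TRANSCRIPTION_ERROR = "Potential transcription error"
VALIDITY_COMMENTS = (MISSING_DATA, NONSTANDARD_UNIT, OUT_OF_RANGE, TRANSCRIPTION_ERROR)

#: Assay type codes: binding, functional, ADME, toxicity, physicochemical.
ASSAY_TYPES = ("B", "F", "A", "T", "P")

BAO_FORMATS = ("biochemical", "cell-based", "tissue-based", "organism-based", "unassigned")

TARGET_TYPES = (
    "SINGLE PROTEIN",
    "PROTEIN FAMILY",
    "PROTEIN COMPLEX",
    "PROTEIN COMPLEX GROUP",
    "CELL-LINE",
    "ORGANISM",
    "NON-PROTEIN",
)

#: Target types that aggregate several protein components.
_MULTI_COMPONENT_TYPES = ("PROTEIN FAMILY", "PROTEIN COMPLEX", "PROTEIN COMPLEX GROUP")


class ActivityRecord(BaseModel):
    """One published measurement with its standardized view.

    Published fields are preserved verbatim so users can map a record back
    to the original publication; the ``standard_*`` fields hold the
    canonical type/relation/value/units produced by the standardization
    workflow. ``pchembl_value`` is -log10 of the standard value in molar
    units, computed only for clean dose-response records.
    """

    record_id: str
    document_id: str
    document_year: Optional[int] = None
    assay_id: str
    compound_id: str
    published_type: Optional[str] = None
    published_relation: Optional[str] = None
    published_value: Optional[float] = None
    published_units: Optional[str] = None
    activity_comment: Optional[str] = None
    standard_type: Optional[str] = None
    standard_relation: Optional[str] = None
    standard_value: Optional[float] = None
    standard_units: Optional[str] = None
    pchembl_value: Optional[float] = None
    data_validity_comment: Optional[str] = None
    potential_duplicate: bool = False


class CompoundRecord(BaseModel):
    """Compound identity plus molecular weight (Da), used for the fragment
    exception in range flagging."""

    compound_id: str
    molecular_weight: Optional[float] = None

    @field_validator("molecular_weight")
    @classmethod
    def _positive_mw(cls, v):
        if v is not None and v <= 0:
            raise ValueError("molecular_weight must be positive")
        return v


class AssayRecord(BaseModel):
    """Assay metadata: free-text description, assay type code, assay format
    and the (possibly homologous, ``relationship_type='H'``) target link."""

    assay_id: str
    document_id: str
    description: str = ""
    assay_type: Optional[str] = None
    bao_format: str = "unassigned"
    relationship_type: str = "D"
    target_id: Optional[str] = None
    cell_line_token: Optional[str] = None
    therapeutic_context: bool = False


class TargetRecord(BaseModel):
    """A target with its type taxonomy and protein components.

    The taxonomy distinguishes a SINGLE PROTEIN from targets whose
    molecular identity is broader: a PROTEIN FAMILY (subtype unresolved),
    a PROTEIN COMPLEX (defined multi-subunit assembly) and a PROTEIN
    COMPLEX GROUP (complex of unresolved subunit composition).
    """

    target_id: str
    target_type: str
    components: list[str] = []
    binding_component: Optional[str] = None


def validate_record(record: ActivityRecord) -> list[str]:
    """Check the cross-field invariants of an activity record.

    Returns an empty list when the record is internally consistent.
    """
    violations: list[str] = []
    for field in ("published_relation", "standard_relation"):
        rel = getattr(record, field)
        if rel is not None and rel not in RELATIONS:
            violations.append(f"{field}: unknown relation {rel!r}")
    comment = record.data_validity_comment
    if comment is not None and comment not in VALIDITY_COMMENTS:
        violations.append(f"data_validity_comment: unknown comment {comment!r}")
    if record.standard_value is not None and comment != NONSTANDARD_UNIT:
        if record.standard_units is None:
            violations.append("standard_units: absent although standard_value is present")
        if record.standard_type is None:
            violations.append("standard_type: absent although standard_value is present")
    if record.pchembl_value is not None and comment is not None:
        violations.append(
            "pchembl_value: present although a data validity comment is set"
        )
    return violations


def validate_target(target: TargetRecord) -> list[str]:
    """Check component-count and membership invariants of a target."""
    violations: list[str] = []
    if target.target_type not in TARGET_TYPES:
        violations.append(f"target_type: unknown type {target.target_type!r}")
    n = len(target.components)
    if target.target_type == "SINGLE PROTEIN" and n != 1:
        violations.append(f"components: SINGLE PROTEIN must have exactly 1 component, got {n}")
    if target.target_type in _MULTI_COMPONENT_TYPES and n < 2:
        violations.append(
            f"components: {target.target_type} must have >= 2 components, got {n}"
        )
    if target.binding_component is not None and target.binding_component not in target.components:
        violations.append("binding_component: not a member of components")
    return violations
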
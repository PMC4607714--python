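"""Curation configuration: the rule tables driving the pipeline.

All curation knowledge — type synonyms, unit-conversion dialects, allowed
units, typical value ranges, unlogging rules, assay keyword tiers and the
cell-line dictionary — is data, not code. A versioned default table ships
with the package; users extend or replace it with their own YAML file.
"""

from __future__ import annotations

from importlib import resources
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator


class UnitConversion(BaseModel):
    """One published-unit dialect: pattern (normalized spelling), dimension
    class, multiplicative factor to the standard unit, and the standard
    types the dialect is meaningful for (``None`` = any)."""

    pattern: str
    unit_class: str
    factor: float
    standard_unit: str
    applicable_standard_types: Optional[list[str]] = None

    @field_validator("factor")
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("conversion factor must be > 0")
        return v


class LogTypeRule(BaseModel):
    """How to unlog a logarithmic published type.

    negative_log types (pKi, pIC50, ...) are -log10 of the value expressed
    in ``reference`` units; plain log types (logIC50) are +log10.
    """

    standard_type: str
    negative_log: bool = True
    reference: str = "M"  # "M" or "nM"

    @field_validator("reference")
    @classmethod
    def _known_reference(cls, v):
        if v not in ("M", "nM"):
            raise ValueError("reference scale must be 'M' or 'nM'")
        return v


class CellLineIdentity(BaseModel):
    organism: str
    identity: str
    accession: str


class AssayKeywordRules(BaseModel):
    """Ordered keyword tiers for assay-type assignment and assay-format
    classification. Order *between* tiers is the precedence contract;
    order within a tier is immaterial."""

    adme: list[str] = []
    physicochemical: list[str] = []
    target_context: list[str] = []
    cytotoxicity: list[str] = []
    binding: list[str] = []
    organism_format: list[str] = []
    tissue_format: list[str] = []
    cell_format: list[str] = []
    biochemical_format: list[str] = []


class CurationConfig(BaseModel):
    model_config = ConfigDict(extra="ignore")

    schema_version: int = 1
    type_synonyms: dict[str, str] = {}
    unit_conversions: list[UnitConversion] = []
    allowed_units: dict[str, list[str]] = {}
    typical_ranges: dict[str, dict[str, tuple[float, float]]] = {}
    fragment_mw_threshold: float = 350.0
    fragment_range_relaxation: float = 100.0
    pchembl_types: list[str] = []
    log_types: dict[str, LogTypeRule] = {}
    assay_keyword_rules: AssayKeywordRules = AssayKeywordRules()
    cell_line_dictionary: dict[str, list[CellLineIdentity]] = {}

    @model_validator(mode="after")
    def _check_tables(self):
        for stype, by_unit in self.typical_ranges.items():
            for unit, (low, high) in by_unit.items():
                if not low < high:
                    raise ValueError(
                        f"typical range for ({stype}, {unit}) must have low < high"
                    )
        missing = [t for t in self.pchembl_types if t not in self.allowed_units]
        if missing:
            raise ValueError(
                f"pchembl_types not covered by allowed_units: {missing}"
            )
        if self.fragment_range_relaxation < 1:
            raise ValueError("fragment_range_relaxation must be >= 1")
        return self

    def typical_range(self, standard_type: str, standard_unit: str):
        """Inclusive (low, high) for a type/unit pair, or ``None``."""
        return self.typical_ranges.get(standard_type, {}).get(standard_unit)


def load_config(path) -> CurationConfig:
    """Load a curation configuration from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return CurationConfig.model_validate(raw)


def default_config() -> CurationConfig:
    """The packaged default rule tables."""
    text = (
        resources.files("sarqc").joinpath("data/default_config.yaml").read_text("utf-8")
    )
    return CurationConfig.model_validate(yaml.safe_load(text))
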
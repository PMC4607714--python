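"""Rule-based assay and cell-line annotation.

Assay-type assignment and assay-format classification in a production
database are expert manual curation; this module is an explicit rule-based
surrogate driven by configurable keyword tiers, suitable for synthetic
corpora and as a first-pass triage of real descriptions.

Assay types: B (binding), F (functional), A (ADME), T (toxicity),
P (physicochemical). Categories overlap, so precedence applies: ADME
beats binding (a cytochrome P450 assay is more usefully filed under
ADME), and a cytotoxicity readout is functional when the assay is run as
an efficacy model (e.g. anti-cancer) but toxicity otherwise.

Assay formats follow the BioAssay Ontology coarse classes with the
precedence organism-based > tissue-based > cell-based > biochemical:
more complex systems subsume the cues of simpler ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import CellLineIdentity, CurationConfig
from .records import AssayRecord


def _contains_any(text: str, keywords: list[str]) -> bool:
    return any(k.lower() in text for k in keywords)


def assign_assay_type(assay: AssayRecord, config: CurationConfig) -> str:
    """Assign one of the five assay type codes from the description.

    Deterministic keyword cascade; always returns a code (default F, the
    majority class for literature assays with a biological readout).
    """
    text = assay.description.lower()
    rules = config.assay_keyword_rules
    if _contains_any(text, rules.adme):
        return "A"
    if _contains_any(text, rules.physicochemical) and not _contains_any(
        text, rules.target_context
    ):
        return "P"
    if _contains_any(text, rules.cytotoxicity):
        return "F" if assay.therapeutic_context else "T"
    if _contains_any(text, rules.binding):
        return "B"
    return "F"


def classify_bao_format(assay: AssayRecord, config: CurationConfig) -> str:
    """Classify the assay format: biochemical, cell-based, tissue-based,
    organism-based or unassigned."""
    text = assay.description.lower()
    rules = config.assay_keyword_rules
    if _contains_any(text, rules.organism_format):
        return "organism-based"
    if _contains_any(text, rules.tissue_format):
        return "tissue-based"
    if assay.cell_line_token is not None or _contains_any(text, rules.cell_format):
        return "cell-based"
    if _contains_any(text, rules.biochemical_format):
        return "biochemical"
    return "unassigned"


@dataclass
class CellLineReport:
    """Candidate identities for a cell-line token.

    More than one candidate means the token is ambiguous (the classic
    'H4' case: a rat hepatoma or a human neuroglioma line) and organism
    context is needed to resolve it. An unknown token yields an empty,
    non-ambiguous report.
    """

    token: str
    candidates: list[CellLineIdentity] = field(default_factory=list)

    @property
    def ambiguous(self) -> bool:
        return len(self.candidates) > 1

    @property
    def known(self) -> bool:
        return len(self.candidates) > 0


def flag_ambiguous_cell_line(
    token: str, dictionary: dict[str, list[CellLineIdentity]]
) -> CellLineReport:
    """Look up a cell-line token and report its candidate identities."""
    return CellLineReport(token=token, candidates=list(dictionary.get(token, [])))


def annotate_assays(
    assays: list[AssayRecord], config: CurationConfig
) -> list[AssayRecord]:
    """Fill in assay_type and bao_format where unassigned (in place)."""
    for assay in assays:
        if assay.assay_type is None:
            assay.assay_type = assign_assay_type(assay, config)
        if assay.bao_format == "unassigned":
            assay.bao_format = classify_bao_format(assay, config)
    return assays
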
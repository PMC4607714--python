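"""Cross-publication redundancy: duplicate citations and unit slips.

Medicinal-chemistry papers routinely cite potency values for reference
compounds from earlier publications, often rounded, and sometimes with the
wrong units. Within groups of records sharing (compound, target, standard
type, standard units), this module detects

* *citation duplicates*: cross-document pairs whose standardized values
  are equal, or equal after rounding either member to 1-3 significant
  figures (published citations are typically truncations of the
  original); and
* *transcription errors*: cross-document pairs whose values agree on the
  mantissa but differ by exactly 3 or 6 orders of magnitude, the
  signature of a uM/nM (or mM/nM) unit slip.

In each matched cluster, records from every document except the earliest
one are flagged — the first publication is presumed to be the original
measurement. Repeats within a single document are never flagged (they are
legitimately independent, e.g. racemate plus isolated stereoisomers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .records import OUT_OF_RANGE, TRANSCRIPTION_ERROR, ActivityRecord, AssayRecord
from .standardize import round_sig

#: Decade offsets that signal a unit transcription error.
TRANSCRIPTION_DECADES = (3, 6)

#: Relative tolerance for comparing standardized values. Exact decade
#: ratios survive decimal -> binary conversion well within this bound.
REL_TOL = 1e-6


@dataclass
class GroupMember:
    record_id: str
    document_id: str
    document_year: Optional[int]
    standard_value: float


@dataclass
class MatchGroup:
    """Records sharing compound, target, standard type and standard units."""

    key: tuple[str, str, str, str]
    members: list[GroupMember] = field(default_factory=list)


def _doc_key(year: Optional[int], document_id: str) -> tuple[float, str]:
    # Unknown years sort last: an undated citation is flagged in
    # preference to the dated original.
    return (float(year) if year is not None else math.inf, document_id)


def _close(a: float, b: float, rel_tol: float = REL_TOL) -> bool:
    return math.isclose(a, b, rel_tol=rel_tol, abs_tol=0.0)


def values_match(a: float, b: float, rel_tol: float = REL_TOL) -> bool:
    """Duplicate-style match: equal, or equal after rounding either value
    to 1, 2 or 3 significant figures."""
    if _close(a, b, rel_tol):
        return True
    for n in (1, 2, 3):
        if _close(round_sig(a, n), b, rel_tol) or _close(a, round_sig(b, n), rel_tol):
            return True
    return False


def transcription_match(
    a: float,
    b: float,
    decades: Sequence[int] = TRANSCRIPTION_DECADES,
    rel_tol: float = REL_TOL,
) -> bool:
    """Whether two values differ by exactly 3 or 6 orders of magnitude,
    comparing mantissas with the same rounding-aware rule as duplicates."""
    if a <= 0 or b <= 0:
        return False
    small, large = sorted((a, b))
    return any(values_match(small * 10.0**k, large, rel_tol) for k in decades)


def build_groups(
    records: Iterable[ActivityRecord], assays: Iterable[AssayRecord]
) -> tuple[list[MatchGroup], int]:
    """Group standardized records by (compound, target, type, units).

    The target is resolved through the record's assay. Records lacking any
    key component or a standard value are skipped; their count is returned
    alongside the groups.
    """
    target_of = {a.assay_id: a.target_id for a in assays}
    groups: dict[tuple[str, str, str, str], MatchGroup] = {}
    skipped = 0
    for r in records:
        target_id = target_of.get(r.assay_id)
        if (
            target_id is None
            or r.compound_id is None
            or r.standard_type is None
            or r.standard_units is None
            or r.standard_value is None
        ):
            skipped += 1
            continue
        key = (r.compound_id, target_id, r.standard_type, r.standard_units)
        groups.setdefault(key, MatchGroup(key=key)).members.append(
            GroupMember(r.record_id, r.document_id, r.document_year, r.standard_value)
        )
    return list(groups.values()), skipped


def _clusters(members: list[GroupMember], pairs: list[tuple[int, int]]) -> list[list[int]]:
    parent = list(range(len(members)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    by_root: dict[int, list[int]] = {}
    for i in range(len(members)):
        by_root.setdefault(find(i), []).append(i)
    return [c for c in by_root.values() if len(c) > 1]


def _flag_later_documents(
    members: list[GroupMember], clusters: list[list[int]]
) -> set[str]:
    flagged: set[str] = set()
    for cluster in clusters:
        earliest = min(_doc_key(members[i].document_year, members[i].document_id) for i in cluster)
        for i in cluster:
            if _doc_key(members[i].document_year, members[i].document_id) != earliest:
                flagged.add(members[i].record_id)
    return flagged


def _sorted_members(group: MatchGroup) -> list[GroupMember]:
    # canonical order makes the outcome invariant under input permutation
    return sorted(
        group.members,
        key=lambda m: (_doc_key(m.document_year, m.document_id), m.record_id),
    )


def _duplicate_pairs(members: list[GroupMember]) -> list[tuple[int, int]]:
    pairs = []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            if members[i].document_id == members[j].document_id:
                continue
            if values_match(members[i].standard_value, members[j].standard_value):
                pairs.append((i, j))
    return pairs


def detect_duplicates(group: MatchGroup) -> set[str]:
    """Record ids to be flagged ``potential_duplicate`` within one group."""
    members = _sorted_members(group)
    clusters = _clusters(members, _duplicate_pairs(members))
    return _flag_later_documents(members, clusters)


def detect_transcription_errors(
    group: MatchGroup, decades: Sequence[int] = TRANSCRIPTION_DECADES
) -> set[str]:
    """Record ids to be flagged as potential transcription errors.

    A pair already matching as a duplicate (decade offset 0) is never also
    a transcription-error pair; the duplicate test runs first. Within a
    matched cluster, members from the earliest document hold the original
    value; later members that still match an original value are faithful
    citations (handled by the duplicate step), so only later members at a
    decade offset from every original value are flagged.
    """
    members = _sorted_members(group)
    pairs = []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            a, b = members[i], members[j]
            if a.document_id == b.document_id:
                continue
            if values_match(a.standard_value, b.standard_value):
                continue  # duplicate pair takes precedence
            if transcription_match(a.standard_value, b.standard_value, decades):
                pairs.append((i, j))
    flagged: set[str] = set()
    for cluster in _clusters(members, pairs):
        earliest = min(
            _doc_key(members[i].document_year, members[i].document_id) for i in cluster
        )
        original_values = [
            members[i].standard_value
            for i in cluster
            if _doc_key(members[i].document_year, members[i].document_id) == earliest
        ]
        for i in cluster:
            m = members[i]
            if _doc_key(m.document_year, m.document_id) == earliest:
                continue
            if any(values_match(m.standard_value, v) for v in original_values):
                continue
            flagged.add(m.record_id)
    return flagged


def apply_redundancy_flags(
    records: list[ActivityRecord], assays: Iterable[AssayRecord]
) -> tuple[list[ActivityRecord], dict[str, int]]:
    """Run duplicate and transcription-error detection and write back flags.

    Mutates only ``potential_duplicate`` and ``data_validity_comment``;
    record count and order are conserved. The transcription-error comment
    is the more specific diagnosis of an extreme value, so it may replace
    an 'Outside typical range' comment, but never the missing-data or
    non-standard-unit comments.
    """
    groups, skipped = build_groups(records, assays)
    duplicate_ids: set[str] = set()
    transcription_ids: set[str] = set()
    for group in groups:
        duplicate_ids |= detect_duplicates(group)
        transcription_ids |= detect_transcription_errors(group)
    for r in records:
        r.potential_duplicate = r.record_id in duplicate_ids
        if r.record_id in transcription_ids and r.data_validity_comment in (
            None,
            OUT_OF_RANGE,
            TRANSCRIPTION_ERROR,
        ):
            r.data_validity_comment = TRANSCRIPTION_ERROR
    counts = {
        "potential_duplicate": len(duplicate_ids),
        "transcription_error": sum(
            1 for r in records if r.data_validity_comment == TRANSCRIPTION_ERROR
        ),
        "skipped_ungrouped": skipped,
    }
    return records, counts
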
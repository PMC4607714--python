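import numpy as np
import pytest
from oracle_redundancy import oracle_duplicates, oracle_transcriptions

from sarqc.records import ActivityRecord, AssayRecord
from sarqc.redundancy import (
    GroupMember,
    MatchGroup,
    apply_redundancy_flags,
    build_groups,
    detect_duplicates,
    detect_transcription_errors,
    transcription_match,
    values_match,
)


def group_of(*members) -> MatchGroup:
    """members: (record_id, document_id, year, value)"""
    return MatchGroup(
        key=("C1", "T1", "IC50", "nM"),
        members=[GroupMember(*m) for m in members],
    )


def random_group(rng: np.random.Generator) -> list[tuple]:
    """A random group seeded with exact copies, rounded citations, decade
    slips and unrelated values across up to 6 documents."""
    n = int(rng.integers(2, 21))
    members = []
    for i in range(n):
        doc = int(rng.integers(0, 6))
        year = 2000 + doc if rng.random() < 0.9 else None
        if members and rng.random() < 0.5:
            base = members[int(rng.integers(len(members)))][3]
            kind = rng.random()
            if kind < 0.33:
                value = base
            elif kind < 0.66:
                digits = int(rng.integers(1, 4))
                from oracle_redundancy import sig_round

                value = sig_round(base, digits)
            else:
                value = base * 10.0 ** (int(rng.choice([3, 6])) * int(rng.choice([-1, 1])))
        else:
            value = 10.0 ** rng.uniform(-1, 5)
        members.append((f"R{i}", f"D{doc}", year, value))
    return members


class TestMatching:
    @pytest.mark.parametrize(
        "a,b,match",
        [
            (53.7, 54.0, True),  # citation rounded to 2 sig figs
            (53.7, 53.7, True),
            (53.7, 50.0, True),  # 1 sig fig
            (50.0, 70.0, False),
            (0.0123, 0.012, True),
            (123.46, 123.0, True),
            (111.0, 129.0, False),
        ],
    )
    def test_rounding_aware_value_match(self, a, b, match):
        assert values_match(a, b) is match
        assert values_match(b, a) is match  # symmetric

    @pytest.mark.parametrize(
        "a,b,match",
        [
            (50.0, 5.0e4, True),  # 3 decades
            (2.5, 2.5e6, True),  # 6 decades
            (50.0, 5.0e3, False),  # 2 decades is not a unit slip
            (53.7, 54000.0, True),  # rounded mantissa + 3 decades
            (50.0, 50.0, False),  # equal values are duplicates, not slips
            (50.0, 7.0e4, False),
        ],
    )
    def test_decade_slip_match(self, a, b, match):
        assert transcription_match(a, b) is match


class TestDetectDuplicates:
    def test_rounded_cross_document_citation_flags_later_paper(self):
        g = group_of(("R1", "A", 2001, 53.7), ("R2", "B", 2003, 54.0))
        assert detect_duplicates(g) == {"R2"}

    def test_same_document_repeats_never_flagged(self):
        # racemate plus stereoisomers reported in one paper
        g = group_of(("R1", "A", 2001, 50.0), ("R2", "A", 2001, 50.0))
        assert detect_duplicates(g) == set()

    def test_unrelated_values_not_flagged(self):
        g = group_of(("R1", "A", 2001, 50.0), ("R2", "B", 2003, 70.0))
        assert detect_duplicates(g) == set()

    def test_earliest_document_never_flagged(self):
        g = group_of(
            ("R1", "B", 2003, 50.0), ("R2", "A", 2001, 50.0), ("R3", "C", 2005, 50.0)
        )
        assert detect_duplicates(g) == {"R1", "R3"}

    def test_unknown_year_sorts_last(self):
        g = group_of(("R1", "A", None, 50.0), ("R2", "B", 2003, 50.0))
        assert detect_duplicates(g) == {"R1"}

    def test_year_tie_broken_by_document_id(self):
        g = group_of(("R1", "B", 2001, 50.0), ("R2", "A", 2001, 50.0))
        assert detect_duplicates(g) == {"R1"}


class TestDetectTranscriptionErrors:
    def test_three_decades_flags_later_document(self):
        g = group_of(("R1", "A", 2001, 50.0), ("R2", "B", 2003, 5.0e4))
        assert detect_transcription_errors(g) == {"R2"}

    def test_six_decades_flags_later_document(self):
        g = group_of(("R1", "A", 2001, 2.5), ("R2", "B", 2003, 2.5e6))
        assert detect_transcription_errors(g) == {"R2"}

    def test_two_decades_is_not_a_slip(self):
        g = group_of(("R1", "A", 2001, 50.0), ("R2", "B", 2003, 5.0e3))
        assert detect_transcription_errors(g) == set()

    def test_same_document_pair_not_flagged(self):
        g = group_of(("R1", "A", 2001, 50.0), ("R2", "A", 2001, 5.0e4))
        assert detect_transcription_errors(g) == set()

    def test_duplicate_pair_is_not_a_transcription_pair(self):
        g = group_of(("R1", "A", 2001, 50.0), ("R2", "B", 2003, 50.0))
        assert detect_transcription_errors(g) == set()
        assert detect_duplicates(g) == {"R2"}


class TestBuildGroups:
    def _assays(self):
        return [
            AssayRecord(assay_id="A1", document_id="A", target_id="T1"),
            AssayRecord(assay_id="A2", document_id="B", target_id="T1"),
            AssayRecord(assay_id="A3", document_id="B", target_id=None),
        ]

    def _rec(self, rid, assay, units="nM", value=50.0):
        return ActivityRecord(
            record_id=rid, document_id="A", assay_id=assay, compound_id="C1",
            standard_type="IC50", standard_units=units, standard_value=value,
        )

    def test_same_key_lands_in_one_group(self):
        records = [self._rec(f"R{i}", "A1") for i in range(3)]
        groups, skipped = build_groups(records, self._assays())
        assert len(groups) == 1 and len(groups[0].members) == 3 and skipped == 0

    def test_differing_units_split_groups(self):
        records = [self._rec("R1", "A1"), self._rec("R2", "A1", units="ug.mL-1")]
        groups, _ = build_groups(records, self._assays())
        assert len(groups) == 2

    def test_unresolvable_records_are_skipped_and_counted(self):
        records = [self._rec("R1", "A1"), self._rec("R2", "A3"), self._rec("R3", "A9")]
        groups, skipped = build_groups(records, self._assays())
        assert len(groups) == 1 and skipped == 2

    def test_empty_input(self):
        groups, skipped = build_groups([], [])
        assert groups == [] and skipped == 0


class TestProperties:
    def test_equivalence_with_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            members = random_group(rng)
            g = group_of(*members)
            assert detect_duplicates(g) == oracle_duplicates(members)
            assert detect_transcription_errors(g) == oracle_transcriptions(members)

    def test_output_invariant_under_input_permutation(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            members = random_group(rng)
            baseline_dup = detect_duplicates(group_of(*members))
            baseline_tr = detect_transcription_errors(group_of(*members))
            perm = list(members)
            rng.shuffle(perm)
            assert detect_duplicates(group_of(*perm)) == baseline_dup
            assert detect_transcription_errors(group_of(*perm)) == baseline_tr

    def test_adding_a_record_never_removes_a_matched_pair(self):
        """Pair-level monotonicity: growing a group preserves matched pairs
        (flag assignment may move if an earlier document is introduced)."""

        def matched_pairs(ms):
            pairs = set()
            for i in range(len(ms)):
                for j in range(i + 1, len(ms)):
                    if ms[i][1] != ms[j][1] and values_match(ms[i][3], ms[j][3]):
                        pairs.add(frozenset((ms[i][0], ms[j][0])))
            return pairs

        rng = np.random.default_rng(11)
        for _ in range(50):
            members = random_group(rng)
            assert matched_pairs(members[:-1]) <= matched_pairs(members)


class TestApplyFlags:
    def test_corpus_without_repeats_gets_zero_flags(self, make_record):
        assays = [AssayRecord(assay_id="A1", document_id="A", target_id="T1")]
        records = [
            make_record(record_id=f"R{i}", compound_id=f"C{i}",
                        standard_type="IC50", standard_units="nM",
                        standard_value=float(i + 1))
            for i in range(10)
        ]
        records, counts = apply_redundancy_flags(records, assays)
        assert counts["potential_duplicate"] == 0
        assert counts["transcription_error"] == 0
        assert all(not r.potential_duplicate for r in records)

    def test_only_flag_fields_are_mutated_and_count_conserved(self, make_record):
        assays = [
            AssayRecord(assay_id="A1", document_id="A", target_id="T1"),
            AssayRecord(assay_id="A2", document_id="B", target_id="T1"),
        ]
        records = [
            make_record(record_id="R1", document_id="A", document_year=2001,
                        assay_id="A1", standard_type="IC50",
                        standard_units="nM", standard_value=50.0),
            make_record(record_id="R2", document_id="B", document_year=2003,
                        assay_id="A2", standard_type="IC50",
                        standard_units="nM", standard_value=50.0),
        ]
        before = [r.model_dump(exclude={"potential_duplicate", "data_validity_comment"}) for r in records]
        records, counts = apply_redundancy_flags(records, assays)
        assert len(records) == 2
        assert counts["potential_duplicate"] == 1
        after = [r.model_dump(exclude={"potential_duplicate", "data_validity_comment"}) for r in records]
        assert before == after
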
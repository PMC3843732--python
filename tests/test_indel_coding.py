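"""Simple indel coding against an independently written rule oracle."""

import re
from itertools import combinations

import pytest

from plastscreen import (
    alignment_from_strings,
    combined_variability,
    count_indel_characters,
    find_gap_runs,
    simple_indel_coding,
)

from conftest import random_alignment


def oracle_gap_runs(rows):
    """Regex-based independent scan for maximal gap runs."""
    out = []
    for i, row in enumerate(rows):
        for m in re.finditer(r"-+", row):
            out.append((i, m.start(), m.end(), m.start() == 0 or m.end() == len(row)))
    return out


def oracle_simple_coding(rows):
    """Independent simple-indel-coding implementation.

    One character per distinct non-terminal (start, end) gap run; a row
    scores 1 with exactly that run, '?' when one of its gaps strictly
    contains the interval or a terminal gap covers it, 0 otherwise.
    """
    runs = oracle_gap_runs(rows)
    char_intervals = sorted({(s, e) for _, s, e, term in runs if not term})
    matrix = {}
    for interval in char_intervals:
        start, end = interval
        states = []
        for i, row in enumerate(rows):
            own = [(s, e, term) for r, s, e, term in runs if r == i]
            if any((s, e) == interval and not term for s, e, term in own):
                states.append("1")
            elif any(
                s <= start and e >= end and ((s, e) != interval or term)
                for s, e, term in own
            ):
                states.append("?")
            else:
                states.append("0")
        matrix[interval] = "".join(states)
    return matrix


class TestFindGapRuns:
    def test_gap_free_alignment_has_no_runs(self):
        assert find_gap_runs(alignment_from_strings(["ACGT", "ACGT"])) == []

    def test_single_internal_run(self):
        runs = find_gap_runs(alignment_from_strings(["AC--G", "ACGTG"]))
        assert len(runs) == 1
        assert runs[0].interval == (2, 4)
        assert not runs[0].terminal

    def test_terminal_flags(self):
        runs = find_gap_runs(alignment_from_strings(["--CGT", "ACG--"]))
        assert all(r.terminal for r in runs)

    def test_agreement_with_regex_oracle(self, rng):
        for _ in range(500):
            aln = random_alignment(rng, 3, 15, gap_prob=0.3)
            got = {
                (aln.ids.index(r.seq_id), *r.interval, r.terminal)
                for r in find_gap_runs(aln)
            }
            assert got == set(oracle_gap_runs(aln.rows))


class TestSimpleIndelCoding:
    def test_shared_gap_is_one_character(self):
        aln = alignment_from_strings(["ACG---TT", "ACG---TT", "ACGAAATT"])
        m = simple_indel_coding(aln)
        assert m.intervals == [(3, 6)]
        assert m.states == ["110"]

    def test_strictly_containing_gap_scores_missing(self):
        # seq1 gap [3,6); seq2 gap [2,8) strictly contains it; seq3 ungapped
        aln = alignment_from_strings(
            ["ACG---TTAA", "AC------AA", "ACGAAATTAA"]
        )
        m = simple_indel_coding(aln)
        assert m.intervals == [(2, 8), (3, 6)]
        by_interval = dict(zip(m.intervals, m.states))
        assert by_interval[(3, 6)] == "1?0"
        assert by_interval[(2, 8)] == "010"

    def test_terminal_gaps_found_no_character(self):
        aln = alignment_from_strings(["--GTACGT", "ACGTAC--", "ACGTACGT"])
        assert simple_indel_coding(aln).n_characters == 0

    def test_character_order_canonical_under_row_permutation(self, rng):
        for _ in range(50):
            aln = random_alignment(rng, 4, 12, gap_prob=0.25)
            m1 = simple_indel_coding(aln)
            perm = alignment_from_strings(list(reversed(aln.rows)))
            m2 = simple_indel_coding(perm)
            assert m1.intervals == m2.intervals
            assert [s[::-1] for s in m2.states] == m1.states

    def test_nonoverlapping_shared_gaps_one_character_each(self):
        aln = alignment_from_strings(
            ["A--GCT--A", "AGGGCTTTA", "A--GCTTTA"]
        )
        m = simple_indel_coding(aln)
        assert m.intervals == [(1, 3), (6, 8)]
        assert count_indel_characters(m) == 2

    def test_agreement_with_independent_oracle(self, rng):
        for _ in range(300):
            aln = random_alignment(rng, 4, 12, gap_prob=0.3)
            m = simple_indel_coding(aln)
            expected = oracle_simple_coding(aln.rows)
            assert dict(zip(m.intervals, m.states)) == expected

    def test_exhaustive_two_gap_layouts(self):
        """All placements of two gap runs on 8 columns across 3 rows agree
        with the rule oracle."""
        intervals = [
            (s, e) for s, e in combinations(range(9), 2) if e - s <= 5
        ]
        base = "ACGTACGT"
        for iv1 in intervals:
            for iv2 in intervals:
                rows = [base, base, base]
                rows[0] = base[: iv1[0]] + "-" * (iv1[1] - iv1[0]) + base[iv1[1] :]
                rows[1] = base[: iv2[0]] + "-" * (iv2[1] - iv2[0]) + base[iv2[1] :]
                aln = alignment_from_strings(rows)
                m = simple_indel_coding(aln)
                assert dict(zip(m.intervals, m.states)) == oracle_simple_coding(rows)


class TestCountAndCombine:
    def test_empty_matrix_counts_zero(self):
        m = simple_indel_coding(alignment_from_strings(["ACGT", "ACGT"]))
        assert count_indel_characters(m) == 0

    def test_invariant_character_not_counted(self):
        # all three sequences share the same internal gap
        aln = alignment_from_strings(["AC--GT", "AC--GT", "AC--GT"])
        m = simple_indel_coding(aln)
        assert m.n_characters == 1
        assert count_indel_characters(m) == 0

    def test_count_equals_recount(self, rng):
        for _ in range(100):
            aln = random_alignment(rng, 4, 15, gap_prob=0.25)
            m = simple_indel_coding(aln)
            recount = sum(
                1
                for s in m.states
                if "0" in s and "1" in s
            )
            assert count_indel_characters(m) == recount

    def test_identical_sequences_all_zero(self):
        stats = combined_variability(
            alignment_from_strings(["ACGTACGT"] * 4), marker="m"
        )
        assert (stats.variable, stats.indel_chars, stats.variable_plus_indels) == (
            0,
            0,
            0,
        )
        assert stats.pi_sites == 0

    def test_combined_sums_variable_and_indels(self):
        aln = alignment_from_strings(
            ["ACG---TTCA", "ACG---TTGA", "ACGAAATTGA"]
        )
        stats = combined_variability(aln, marker="m")
        assert stats.variable == 1
        assert stats.indel_chars == 1
        assert stats.variable_plus_indels == 2
        assert stats.total_chars == 10
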
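"""Sliding-window scan: slice-recount oracle, selection, merging, splitting."""

import warnings

import pytest

from plastscreen import (
    AnnotatedPlastome,
    CandidateRegion,
    Feature,
    alignment_from_strings,
    count_variable,
    merge_windows_to_regions,
    sliding_window_scan,
    split_region,
    top_windows,
)
from plastscreen.window_scan import WindowProfile

from conftest import random_alignment


class TestSlidingWindowScan:
    def test_invariant_alignment_gives_zero_profile(self):
        aln = alignment_from_strings(["ACGT" * 30] * 3)
        profile = sliding_window_scan(aln, window=40, step=10)
        assert all(v == 0 for v in profile.values)

    def test_values_equal_recount_on_window_slice(self, rng):
        for _ in range(200):
            aln = random_alignment(rng, 3, 60, gap_prob=0.05)
            profile = sliding_window_scan(aln, window=20, step=7)
            for start, value in zip(profile.window_starts, profile.values):
                assert value == count_variable(aln.slice_columns(start, start + 20))

    def test_window_wider_than_alignment_rejected(self):
        aln = alignment_from_strings(["ACGT" * 5] * 2)
        with pytest.raises(ValueError):
            sliding_window_scan(aln, window=100, step=10)
        with pytest.raises(ValueError):
            sliding_window_scan(aln, window=10, step=0)

    def test_larger_step_is_subsequence_of_denser_profile(self, rng):
        aln = random_alignment(rng, 3, 80)
        dense = sliding_window_scan(aln, window=20, step=5)
        sparse = sliding_window_scan(aln, window=20, step=10)
        dense_map = dict(zip(dense.window_starts, dense.values))
        for start, value in zip(sparse.window_starts, sparse.values):
            assert dense_map[start] == value

    def test_row_permutation_invariance(self, rng):
        aln = random_alignment(rng, 4, 60)
        perm = alignment_from_strings(list(reversed(aln.rows)))
        assert (
            sliding_window_scan(aln, window=20, step=5).values
            == sliding_window_scan(perm, window=20, step=5).values
        )

    def test_truncated_trailing_window_dropped_by_default(self):
        aln = alignment_from_strings(["ACGT" * 13] * 2)  # 52 columns
        profile = sliding_window_scan(aln, window=40, step=10)
        assert profile.window_starts == [0, 10]
        kept = sliding_window_scan(aln, window=40, step=10, keep_truncated=True)
        assert kept.truncated_last
        assert len(kept.window_starts) == 3

    def test_identity_track_range(self, rng):
        aln = random_alignment(rng, 3, 60)
        profile = sliding_window_scan(
            aln, window=20, step=10, reference=aln.ids[0]
        )
        assert profile.identity_pct is not None
        assert all(0.0 <= v <= 100.0 for v in profile.identity_pct)

    def test_ungapped_window_spans_reference_positions(self):
        rows = ["AAAA----CCCCGGGG", "AAAATTTTCCCCGGGG"]
        aln = alignment_from_strings(rows, ids=["ref", "other"])
        profile = sliding_window_scan(
            aln, window=8, step=4, reference="ref", ungapped_window=True
        )
        # first window covers 8 non-gap reference positions = columns [0,12)
        assert profile.window_starts[0] == 0


class TestTopWindows:
    def test_all_equal_profile_breaks_ties_by_offset(self):
        profile = WindowProfile([0, 10, 20, 30], 20, 10, [5, 5, 5, 5])
        assert top_windows(profile, 2) == [(0, 20), (10, 30)]

    def test_unique_maximum_selected(self):
        profile = WindowProfile([0, 10, 20], 20, 10, [1, 9, 3])
        assert top_windows(profile, 1) == [(10, 30)]

    def test_agreement_with_sort_oracle(self, rng):
        for _ in range(100):
            values = [int(v) for v in rng.integers(0, 10, size=15)]
            starts = [10 * i for i in range(15)]
            profile = WindowProfile(starts, 20, 10, values)
            k = int(rng.integers(1, 15))
            expected = {
                (starts[i], starts[i] + 20)
                for i in sorted(
                    range(15), key=lambda i: (-values[i], starts[i])
                )[:k]
            }
            assert set(top_windows(profile, k)) == expected

    def test_k_exceeding_windows_warns_and_returns_all(self):
        profile = WindowProfile([0, 10], 20, 10, [1, 2])
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            got = top_windows(profile, 10)
        assert len(got) == 2
        assert caught


class TestMergeWindows:
    def test_disjoint_windows_stay_separate(self):
        regions = merge_windows_to_regions([(0, 1000), (5000, 6000)])
        assert [r.interval for r in regions] == [(0, 1000), (5000, 6000)]

    def test_overlapping_windows_merge(self):
        regions = merge_windows_to_regions([(0, 1000), (100, 1100)])
        assert [r.interval for r in regions] == [(0, 1100)]

    def test_unannotated_regions_named_by_coordinates(self):
        (region,) = merge_windows_to_regions([(100, 300)])
        assert region.name == "region_101_300"

    def test_region_mostly_inside_gene_takes_gene_name(self):
        genome = AnnotatedPlastome(
            id="G",
            sequence="A" * 5000,
            features=[
                Feature("ycf1", "gene", (1000, 3500)),
                Feature("trnL", "gene", (4000, 4100)),
            ],
        )
        (region,) = merge_windows_to_regions([(1200, 2400)], genome=genome)
        assert region.name == "ycf1"

    def test_spacer_named_from_flanking_genes(self):
        genome = AnnotatedPlastome(
            id="G",
            sequence="A" * 5000,
            features=[
                Feature("rpl32", "gene", (500, 900)),
                Feature("trnL", "gene", (3100, 3300)),
            ],
        )
        (region,) = merge_windows_to_regions([(1000, 3000)], genome=genome)
        assert region.name == "rpl32-trnL"

    def test_counts_filled_from_alignment(self, rng):
        aln = random_alignment(rng, 3, 50)
        (region,) = merge_windows_to_regions([(10, 30)], aln=aln)
        assert region.variable == count_variable(aln.slice_columns(10, 30))


class TestSplitRegion:
    def test_short_region_unsplit(self):
        region = CandidateRegion((0, 900), "m")
        assert split_region(region, max_len=1300) == [region]

    def test_three_way_split_near_equal(self):
        region = CandidateRegion((0, 3585), "ycf1")
        parts = split_region(region, max_len=1300)
        assert [p.name for p in parts] == [
            "ycf1 part 1",
            "ycf1 part 2",
            "ycf1 part 3",
        ]
        sizes = [len(p) for p in parts]
        assert sizes == [1195, 1195, 1195]
        assert parts[0].start == 0 and parts[-1].end == 3585

    def test_parts_partition_interval(self):
        region = CandidateRegion((100, 3000), "big")
        parts = split_region(region, max_len=1300)
        assert parts[0].start == 100
        assert parts[-1].end == 3000
        for left, right in zip(parts, parts[1:]):
            assert left.end == right.start

    def test_max_len_floor(self):
        with pytest.raises(ValueError):
            split_region(CandidateRegion((0, 2000), "m"), max_len=400)
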
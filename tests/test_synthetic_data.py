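"""Generator determinism and planted-truth recovery."""

import pytest

from plastscreen import (
    RegionSpec,
    SimulationSpec,
    compare_ir_copies,
    count_indel_characters,
    count_variable,
    extract_region,
    merge_windows_to_regions,
    nei_gojobori,
    simple_indel_coding,
    simulate_clade_alignment,
    simulate_codon_pair,
    simulate_plastome_trio,
    sliding_window_scan,
    top_windows,
)
from plastscreen.synthetic_data import default_trio_spec, read_spec_config


class TestSimulateCladeAlignment:
    def test_zero_rate_gives_identical_sequences(self):
        spec = SimulationSpec(
            n_taxa=5, regions=[RegionSpec("r", 300)], seed=1
        )
        aln, truth = simulate_clade_alignment(spec)
        assert len(set(aln.rows)) == 1
        assert truth.n_variable == 0
        assert truth.n_indel_characters == 0

    def test_planted_counts_recovered_exactly(self, small_spec):
        aln, truth = simulate_clade_alignment(small_spec)
        assert truth.n_variable == 10  # 0.02 × 500
        assert truth.n_indel_characters == 3
        assert count_variable(aln) == 10
        assert count_indel_characters(simple_indel_coding(aln)) == 3

    def test_same_seed_byte_identical(self, small_spec):
        aln1, _ = simulate_clade_alignment(small_spec)
        aln2, _ = simulate_clade_alignment(small_spec)
        assert aln1.rows == aln2.rows
        assert aln1.ids == aln2.ids

    def test_different_seed_differs(self, small_spec):
        other = SimulationSpec(
            n_taxa=small_spec.n_taxa, regions=small_spec.regions, seed=99
        )
        aln1, _ = simulate_clade_alignment(small_spec)
        aln2, _ = simulate_clade_alignment(other)
        assert aln1.rows != aln2.rows

    def test_truth_columns_are_the_variable_columns(self, small_spec):
        from plastscreen import classify_sites

        aln, truth = simulate_clade_alignment(small_spec)
        expected = sorted(truth.variable_columns["marker"])
        got = [
            j for j, lab in enumerate(classify_sites(aln).labels) if lab == "variable"
        ]
        assert got == expected

    def test_nested_gaps_produce_missing_states(self):
        spec = SimulationSpec(
            n_taxa=6,
            regions=[RegionSpec("r", 400, nested_indels=1)],
            seed=5,
        )
        aln, truth = simulate_clade_alignment(spec)
        matrix = simple_indel_coding(aln)
        assert any("?" in s for s in matrix.states)
        (inner,) = truth.nested_intervals["r"]
        assert inner in matrix.intervals

    def test_too_many_variants_rejected(self):
        spec = SimulationSpec(
            n_taxa=3, regions=[RegionSpec("r", 10, rate=0.9, n_indels=3)], seed=0
        )
        with pytest.raises(ValueError):
            simulate_clade_alignment(spec)

    def test_ir_must_come_in_pairs(self):
        with pytest.raises(ValueError, match="IR"):
            SimulationSpec(n_taxa=3, regions=[RegionSpec("IRa", 100, "IR")])


class TestSimulatePlastomeTrio:
    def test_genomes_match_alignment_rows(self, trio):
        genomes, aln, _ = trio
        assert [g.sequence for g in genomes] == aln.rows
        assert [g.id for g in genomes] == aln.ids

    def test_ir_copies_identical_in_reverse_complement(self, trio):
        genomes, _, truth = trio
        for genome in genomes:
            ira = extract_region(genome, truth.region_intervals["IRa"])
            irb = extract_region(genome, truth.region_intervals["IRb"])
            assert compare_ir_copies(ira, irb).identical

    def test_hot_regions_recovered_by_scan(self, trio):
        genomes, aln, truth = trio
        profile = sliding_window_scan(aln)
        regions = merge_windows_to_regions(
            top_windows(profile, 20), genome=genomes[0], aln=aln
        )
        names = {r.name for r in regions}
        assert {"trnK-rps16", "clpP-psbB", "ndhF-rpl32", "rpl32-trnL"} <= names
        # recovered intervals lie within a window of the planted hot spacers
        for hot in ("trnK-rps16 spacer", "rpl32-trnL spacer"):
            start, end = truth.region_intervals[hot]
            assert any(
                r.start <= end + 1000 and r.end >= start - 1000 for r in regions
            )

    def test_flat_rates_fall_back_to_offset_tiebreak(self):
        spec = SimulationSpec(
            n_taxa=3,
            regions=[RegionSpec("flat", 3000, rate=0.0)],
            seed=2,
        )
        _, aln, _ = simulate_plastome_trio(spec)
        profile = sliding_window_scan(aln)
        assert top_windows(profile, 3) == [(0, 1000), (100, 1100), (200, 1200)]

    def test_cds_selection_regime_recoverable(self, trio):
        genomes, aln, truth = trio
        sd, nd = truth.cds_substitutions["ycf1"]
        assert sd + nd == 95
        from plastscreen import Feature, extract_codon_alignment, region_kaks

        start, end = truth.region_intervals["ycf1"]
        ca = extract_codon_alignment(aln, Feature("ycf1", "CDS", (start, end)))
        mean_ratio, results = region_kaks(ca)
        assert len(results) == 3  # three pairwise comparisons
        assert mean_ratio is not None and mean_ratio < 0.9  # planted purifying


class TestSimulateCodonPair:
    def test_event_counts_conserved(self):
        for seed in range(10):
            _, _, (sd, nd) = simulate_codon_pair(100, 0.5, 15, seed=seed)
            assert sd + nd == 15

    def test_omega_zero_gives_only_synonymous_events(self):
        anc, der, (sd, nd) = simulate_codon_pair(100, 0.0, 10, seed=3)
        assert (sd, nd) == (10, 0)
        r = nei_gojobori(anc, der)
        assert r.ka == 0.0

    def test_determinism(self):
        assert simulate_codon_pair(50, 0.7, 8, seed=9) == simulate_codon_pair(
            50, 0.7, 8, seed=9
        )

    def test_infeasible_requests_rejected(self):
        with pytest.raises(ValueError):
            simulate_codon_pair(5, 1.0, 100, seed=0)
        with pytest.raises(ValueError):
            simulate_codon_pair(10, -1.0, 2, seed=0)


def test_spec_config_round_trip(tmp_path):
    cfg = tmp_path / "sim.cfg"
    cfg.write_text(
        "n_taxa = 6\nseed = 13\n"
        "# name kind length rate n_indels [omega n_subs]\n"
        "region spacerA spacer 400 0.02 2\n"
        "region cds1 CDS 300 0 0 0.2 6\n"
    )
    spec = read_spec_config(cfg)
    assert spec.n_taxa == 6
    assert spec.seed == 13
    assert [r.name for r in spec.regions] == ["spacerA", "cds1"]
    assert spec.regions[1].omega == 0.2
    aln, truth = simulate_clade_alignment(spec)
    assert aln.n_rows == 6
    assert truth.n_indel_characters == 2


def test_default_trio_spec_is_valid():
    spec = default_trio_spec(seed=0)
    assert spec.n_taxa == 3
    assert sum(1 for r in spec.regions if r.kind == "IR") == 2
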
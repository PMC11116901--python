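"""Synthetic genome generator: contracts, junction edits, truth tiling, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from translokit import (
    Genome,
    GenomeError,
    apply_complex_translocation,
    apply_reciprocal_translocation,
    generate_wt_genome,
    read_genome_fasta,
    read_truth,
    reciprocal_junction_pair,
    simulate_mutant,
    write_genome_fasta,
    write_truth,
)
from translokit.genomes import JunctionSpec, apply_translocations


class TestGenerate:
    def test_lengths_and_names(self):
        g = generate_wt_genome(11, [200_000] * 11, 0.35, seed=7)
        assert [c for c, _ in g.karyotype] == [f"Chr{i}" for i in range(1, 12)]
        assert all(L == 200_000 for _, L in g.karyotype)

    def test_deterministic_fasta(self, tmp_path):
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_genome_fasta(generate_wt_genome(3, [20_000] * 3, 0.35, seed=7), p1)
        write_genome_fasta(generate_wt_genome(3, [20_000] * 3, 0.35, seed=7), p2)
        assert p1.read_bytes() == p2.read_bytes()
        p3 = tmp_path / "c.fasta"
        write_genome_fasta(generate_wt_genome(3, [20_000] * 3, 0.35, seed=8), p3)
        assert p1.read_bytes() != p3.read_bytes()

    def test_gc_by_direct_count(self):
        g = generate_wt_genome(1, [50_000], 0.35, seed=1)
        seq = g.chromosomes["Chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(g.gc_fraction(), abs=1e-12)
        # 50 kb draw stays near the target
        assert abs(gc - 0.35) < 0.02

    def test_gc_tolerance_at_scale(self, desk_wt):
        for chrom, _ in desk_wt.karyotype:
            assert abs(desk_wt.gc_fraction(chrom) - 0.35) < 0.02

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_chromosomes=0, lengths=[], gc_content=0.35, seed=1),
            dict(n_chromosomes=1, lengths=[5_000], gc_content=0.35, seed=1),
            dict(n_chromosomes=1, lengths=[20_000], gc_content=0.0, seed=1),
            dict(n_chromosomes=1, lengths=[20_000], gc_content=1.2, seed=1),
            dict(n_chromosomes=2, lengths=[20_000], gc_content=0.35, seed=1),
        ],
    )
    def test_parameter_errors(self, kwargs):
        with pytest.raises(GenomeError):
            generate_wt_genome(**kwargs)

    def test_alphabet_validation(self):
        with pytest.raises(GenomeError):
            Genome({"Chr1": "ACGTN"})
        with pytest.raises(GenomeError):
            Genome({"Chr1": ""})


class TestReciprocal:
    def test_blunt_exchange_conserves_length(self, small_wt):
        pair = reciprocal_junction_pair(("Chr1", 15_000), ("Chr2", 10_000))
        mt, truth = apply_reciprocal_translocation(small_wt, pair, "E")
        assert mt.total_length == small_wt.total_length
        assert set(mt.chromosomes) == {"Chr1^2", "Chr2^1", "Chr3"}

    def test_deletions_shorten_junctions(self, small_wt):
        pair = reciprocal_junction_pair(
            ("Chr1", 15_000), ("Chr2", 10_000), deletions=(3, 3))
        mt, truth = apply_reciprocal_translocation(small_wt, pair, "E")
        # each derived chromosome is 3 nt shorter than a blunt exchange
        assert len(mt.chromosomes["Chr1^2"]) == 15_000 + 20_000 - 3
        assert len(mt.chromosomes["Chr2^1"]) == 10_000 + 15_000 - 3
        assert mt.total_length == small_wt.total_length - 6

    def test_length_accounting_with_all_edits(self, small_wt):
        pair = reciprocal_junction_pair(
            ("Chr1", 15_000), ("Chr2", 10_000),
            deletions=(5, 2), insertions=("GGAATT", ""), motifs=("", ""))
        mt, truth = apply_reciprocal_translocation(small_wt, pair, "E")
        assert mt.total_length == small_wt.total_length - 7 + 6

    def test_motif_written_to_both_wt_flanks_once_in_mutant(self, small_wt):
        pair = reciprocal_junction_pair(
            ("Chr1", 15_000), ("Chr2", 10_000), motifs=("TTTAT", ""))
        mt, truth = apply_reciprocal_translocation(small_wt, pair, "E")
        wt = truth.wt_genome
        # both wild-type flanks carry the motif adjacent to the break
        assert wt.chromosomes["Chr1"][15_000 - 5 : 15_000] == "TTTAT"
        assert wt.chromosomes["Chr2"][10_000 : 10_000 + 5] == "TTTAT"
        # the mutant junction retains exactly one copy spanning the join
        junction = truth.junctions_on("Chr1^2")[0]
        window = mt.chromosomes["Chr1^2"][junction.position - 10 : junction.position + 10]
        assert window.count("TTTAT") == 1
        # one motif copy is gone from the total
        assert mt.total_length == small_wt.total_length - 5

    def test_truth_junction_coordinates(self, mta_small):
        wt, mt, truth = mta_small
        coords = truth.junction_coordinates
        # junction on the motif chromosome is left-shifted by the motif length
        j1 = truth.junctions_on("Chr1^2")[0]
        assert j1.position == j1.boundary - 5
        j2 = truth.junctions_on("Chr2^1")[0]
        assert j2.position == j2.boundary
        assert coords == {"Chr1^2": [j1.position], "Chr2^1": [j2.position]}

    def test_deletion_past_chromosome_end_rejected(self, small_wt):
        pair = reciprocal_junction_pair(
            ("Chr1", 100), ("Chr2", 10_000), deletions=(200, 0))
        with pytest.raises(GenomeError):
            apply_reciprocal_translocation(small_wt, pair, "E")

    def test_breakpoint_outside_chromosome_rejected(self, small_wt):
        pair = reciprocal_junction_pair(("Chr1", 30_000), ("Chr2", 10_000))
        with pytest.raises(GenomeError):
            apply_reciprocal_translocation(small_wt, pair, "E")

    def test_mismatched_pair_rejected(self, small_wt):
        j1 = JunctionSpec(("Chr1", 15_000), ("Chr2", 10_000))
        j2 = JunctionSpec(("Chr2", 9_999), ("Chr1", 15_000))
        with pytest.raises(GenomeError):
            apply_reciprocal_translocation(small_wt, (j1, j2), "E")


class TestComplexChain:
    def chain(self, wt):
        ex1 = reciprocal_junction_pair(("Chr1", 20_000), ("Chr2", 18_000),
                                       deletions=(25, 24))
        ex2 = reciprocal_junction_pair(("Chr2", 9_000), ("Chr3", 12_000),
                                       deletions=(1, 4))
        return apply_complex_translocation(wt, [ex1, ex2], "CX")

    def test_three_derived_chromosomes_four_junctions(self, small_wt):
        mt, truth = self.chain(small_wt)
        derived = {c for c in mt.chromosomes if "^" in c}
        assert derived == {"Chr1^2", "Chr2^3", "Chr3^2"}
        assert len(truth.junctions) == 4
        # the chromosome carrying the middle segment has two junctions
        assert len(truth.junctions_on("Chr3^2")) == 2

    def test_segment_enumeration_matches_hand_derivation(self, small_wt):
        mt, truth = self.chain(small_wt)
        segs = {c: [(s.source, s.start, s.end) for s in ss]
                for c, ss in truth.derived_chromosome_map.items() if "^" in c}
        assert segs["Chr1^2"] == [("Chr1", 1, 19_975), ("Chr2", 18_001, 30_000)]
        assert segs["Chr2^3"] == [("Chr2", 1, 8_999), ("Chr3", 12_001, 30_000)]
        assert segs["Chr3^2"] == [("Chr3", 1, 11_996), ("Chr2", 9_001, 17_976),
                                  ("Chr1", 20_001, 30_000)]

    def test_single_exchange_rejected(self, small_wt):
        ex = reciprocal_junction_pair(("Chr1", 15_000), ("Chr2", 10_000))
        with pytest.raises(GenomeError):
            apply_complex_translocation(small_wt, [ex], "CX")

    def test_disjoint_exchanges_equal_independent_reciprocals(self):
        wt = generate_wt_genome(4, [20_000] * 4, 0.35, seed=5, name="WT")
        ex1 = reciprocal_junction_pair(("Chr1", 13_000), ("Chr2", 7_000),
                                       deletions=(25, 24))
        ex2 = reciprocal_junction_pair(("Chr3", 9_500), ("Chr4", 11_500),
                                       deletions=(4, 4))
        mt_joint, _ = apply_complex_translocation(wt, [ex1, ex2], "B")
        mt_1, _ = apply_reciprocal_translocation(wt, ex1, "B1")
        mt_2, _ = apply_reciprocal_translocation(mt_1, ex2, "B2")
        # same mutant chromosomes from joint vs sequential application
        assert dict(mt_joint.chromosomes) == dict(mt_2.chromosomes)

    def test_event_splitting_disjoint_vs_chained(self, small_wt):
        ex1 = reciprocal_junction_pair(("Chr1", 20_000), ("Chr2", 18_000))
        ex2 = reciprocal_junction_pair(("Chr2", 9_000), ("Chr3", 12_000))
        _, _, truths = apply_translocations(small_wt, [ex1, ex2])
        assert len(truths) == 1 and truths[0].event.kind == "complex_chain"
        wt4 = generate_wt_genome(4, [20_000] * 4, 0.35, seed=5)
        ex3 = reciprocal_junction_pair(("Chr1", 13_000), ("Chr2", 7_000))
        ex4 = reciprocal_junction_pair(("Chr3", 9_500), ("Chr4", 11_500))
        _, _, truths = apply_translocations(wt4, [ex3, ex4])
        assert [t.event.kind for t in truths] == ["reciprocal", "reciprocal"]

    def test_conflicting_positions_rejected(self, small_wt):
        # second exchange claims a Chr1 region that moved to Chr1^2's partner
        ex1 = reciprocal_junction_pair(("Chr1", 10_000), ("Chr2", 18_000))
        ex2 = reciprocal_junction_pair(("Chr1", 10_000), ("Chr3", 12_000))
        with pytest.raises(GenomeError):
            apply_complex_translocation(small_wt, [ex1, ex2], "CX")


class TestTilingProperty:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        pa=st.integers(2_000, 18_000),
        pb=st.integers(2_000, 18_000),
        d1=st.integers(0, 25),
        d2=st.integers(0, 25),
        ins=st.text(alphabet="ACGT", max_size=8),
        use_motif=st.booleans(),
    )
    def test_tiling_and_length_conservation(self, pa, pb, d1, d2, ins, use_motif):
        """Concatenating truth segments (with edits) reproduces the mutant
        byte-exactly, and lengths balance for every generated event."""
        wt = generate_wt_genome(2, [20_000] * 2, 0.35, seed=3)
        motif = "TTTAT" if use_motif and not ins else ""
        pair = reciprocal_junction_pair(
            ("Chr1", pa), ("Chr2", pb), deletions=(d1, d2),
            insertions=(ins, ""), motifs=(motif, ""))
        mt, truth = apply_reciprocal_translocation(wt, pair, "E")
        assert truth.reconstruct() == mt
        assert mt.total_length == (
            wt.total_length - d1 - d2 - len(motif) + len(ins))

    def test_determinism(self, small_wt):
        pair = reciprocal_junction_pair(("Chr1", 15_000), ("Chr2", 10_000),
                                        deletions=(7, 2), motifs=("TTTAT", ""))
        a = apply_reciprocal_translocation(small_wt, pair, "E")
        b = apply_reciprocal_translocation(small_wt, pair, "E")
        assert a[0] == b[0]
        assert a[1].wt_genome == b[1].wt_genome


class TestIO:
    def test_fasta_round_trip(self, desk_wt, tmp_path):
        path = tmp_path / "g.fasta"
        write_genome_fasta(desk_wt, path)
        back = read_genome_fasta(path)
        assert back == desk_wt
        # 60-column wrapping
        lines = path.read_text().splitlines()
        assert max(len(ln) for ln in lines if not ln.startswith(">")) == 60

    def test_malformed_fasta_reports_line(self, tmp_path):
        bad = tmp_path / "bad.fasta"
        bad.write_text("ACGT\nACGT\n")
        with pytest.raises(GenomeError, match="malformed FASTA"):
            read_genome_fasta(bad)

    def test_truth_round_trip_and_bed(self, mta_small, tmp_path):
        _, _, truth = mta_small
        jp, bp = tmp_path / "t.json", tmp_path / "t.bed"
        write_truth(truth, jp, bp)
        back = read_truth(jp)
        assert back == truth  # wt_genome excluded from equality
        bed = [ln.split("\t") for ln in bp.read_text().splitlines()]
        assert len(bed) == 2  # one junction interval per derived chromosome
        by_chrom = {row[0]: row for row in bed}
        j1 = truth.junctions_on("Chr1^2")[0]
        assert by_chrom["Chr1^2"][1:3] == [str(j1.position - 1), str(j1.position)]
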
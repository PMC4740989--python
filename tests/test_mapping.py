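"""SNV clustering, probe construction, MSY placement, and classification."""

import numpy as np
import pytest

from msy_seg._seq import revcomp
from msy_seg.mapping import (
    MarkerProbe,
    assess_pseudogene,
    build_probe,
    classify_mechanism,
    cluster_snvs,
    locate_on_msy,
)

from _oracles import oracle_clusters, oracle_locate


def sites(*positions, chrom="chr1"):
    return [(chrom, p) for p in positions]


class TestClusterSnvs:
    def test_gap_rule_discards_far_singleton(self):
        assert cluster_snvs(sites(100, 110, 135)) == [sites(100, 110)]

    def test_transitive_chaining(self):
        """Three SNVs at 18-base spacings chain into one cluster even
        though the outer pair is 36 bases apart."""
        assert cluster_snvs(sites(100, 118, 136)) == [sites(100, 118, 136)]

    def test_single_site_is_not_a_cluster(self):
        assert cluster_snvs(sites(100)) == []
        assert cluster_snvs([]) == []

    def test_chromosomes_never_chain_together(self):
        mixed = sites(100, 110) + sites(105, 115, chrom="chr2")
        assert len(cluster_snvs(mixed)) == 2

    @pytest.mark.parametrize("seed", range(120))
    def test_matches_link_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        positions = [
            (rng.choice(["c1", "c2"]), int(p))
            for p in rng.integers(1, 300, size=rng.integers(0, 25))
        ]
        result = cluster_snvs(positions)
        assert sorted(sorted(c) for c in result) == oracle_clusters(positions, 20)

    def test_input_order_invariance(self, rng):
        positions = [("c1", int(p)) for p in rng.integers(1, 500, size=30)]
        shuffled = [positions[i] for i in rng.permutation(len(positions))]
        assert cluster_snvs(positions) == cluster_snvs(shuffled)
        clustered = sum(len(c) for c in cluster_snvs(positions))
        assert clustered <= len(set(positions))


CONTEXT = "ACGTTGCAGGTACCATGGACTTCAAGGTCCGATTGCAAGCTTGG"  # starts at pos 1000


class TestBuildProbe:
    def test_middle_placement_geometry(self):
        probe = build_probe(CONTEXT, 1000, [1015, 1020], ["A", "C"], flank=11)
        assert len(probe.sequence) == (1020 - 1015) + 2 * 11 + 1
        assert probe.snv_offsets == (11, 16)
        assert probe.sequence[11] == "A" and probe.sequence[16] == "C"

    def test_ends_placement_puts_first_snv_on_boundary(self):
        probe = build_probe(
            CONTEXT, 1000, [1010, 1014], ["A", "A"], flank=10, placement="ends"
        )
        assert probe.snv_offsets[0] == 0
        assert len(probe.sequence) == (1014 - 1010) + 2 * 10 + 1

    def test_probe_does_not_match_reference_context(self):
        probe = build_probe(CONTEXT, 1000, [1015, 1020], ["A", "C"], flank=11)
        assert probe.sequence not in CONTEXT
        read_with_alts = probe.sequence
        assert locate_on_msy(probe, {"c": "TT" + read_with_alts + "GG"}) == [
            ("c", 3, "+")
        ]

    def test_context_too_short_is_an_error(self):
        with pytest.raises(ValueError, match="too short"):
            build_probe(CONTEXT, 1000, [1002], ["A"], flank=15)

    def test_short_probes_rejected(self):
        with pytest.raises(ValueError, match=">= 24"):
            MarkerProbe("p", "ACGTACGTACGT", (0,))


class TestLocateOnMsy:
    PROBE = "ACCGTTAGGCATCAGGATTACCAGGCAT"

    def test_planted_probe_found_at_coordinate(self, rng):
        from msy_seg.simulate import _random_seq

        left = _random_seq(rng, 137)
        contig = left + self.PROBE + _random_seq(rng, 60)
        assert locate_on_msy(self.PROBE, {"bac1": contig}) == [("bac1", 138, "+")]

    def test_reverse_strand_hit(self, rng):
        from msy_seg.simulate import _random_seq

        contig = _random_seq(rng, 50) + revcomp(self.PROBE) + _random_seq(rng, 50)
        ((name, pos, strand),) = locate_on_msy(self.PROBE, {"bac1": contig})
        assert strand == "-" and pos == 51

    def test_absent_probe_returns_empty(self):
        assert locate_on_msy(self.PROBE, {"bac1": "ACGT" * 50}) == []

    def test_degenerate_bases_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            locate_on_msy("ACGTNACGTACGTACGTACGTACGTN", {"c": "ACGT"})

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_naive_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        from msy_seg.simulate import _random_seq

        probe = _random_seq(rng, int(rng.integers(24, 40)))
        contigs = {}
        for i in range(int(rng.integers(1, 4))):
            seq = _random_seq(rng, int(rng.integers(100, 400)))
            if rng.random() < 0.7:  # plant the probe (either strand) somewhere
                at = int(rng.integers(0, len(seq) - len(probe)))
                insert = probe if rng.random() < 0.5 else revcomp(probe)
                seq = seq[:at] + insert + seq[at + len(insert) :]
            contigs[f"bac{i}"] = seq
        assert sorted(locate_on_msy(probe, contigs)) == sorted(
            oracle_locate(probe, contigs)
        )


class TestClassifyMechanism:
    EXONS = ["ATGGCCGATTACCAGGCATTACGATGCAAT", "GGATTCCAGGCATGGACCTTGAACGGTAAT"]
    INTRON = "GTAAGCCTTGGACCATTGGACCTTGAAGCTTCCAG"

    def _contig(self, insert, rng):
        from msy_seg.simulate import _random_seq

        return {"bac": _random_seq(rng, 80) + insert + _random_seq(rng, 80)}

    def test_spliced_insert_is_retroposed(self, rng):
        contigs = self._contig("".join(self.EXONS), rng)
        assert classify_mechanism(self.EXONS, [self.INTRON], contigs) == "retroposed"

    def test_intron_bearing_insert_is_transposed(self, rng):
        genomic = self.EXONS[0] + self.INTRON + self.EXONS[1]
        contigs = self._contig(genomic, rng)
        assert classify_mechanism(self.EXONS, [self.INTRON], contigs) == "transposed"

    def test_exon_subset_is_partial_transposition(self, rng):
        contigs = self._contig(self.EXONS[0], rng)
        assert (
            classify_mechanism(self.EXONS, [self.INTRON], contigs)
            == "partial_transposed"
        )

    def test_msy_native_gene_short_circuits(self):
        assert (
            classify_mechanism(self.EXONS, [self.INTRON], {"c": "ACGT"}, source_on_msy=True)
            == "msy_duplication"
        )

    def test_intronless_gene_defaults_to_retroposed_with_warning(self, rng):
        contigs = self._contig(self.EXONS[0], rng)
        with pytest.warns(UserWarning, match="intronless"):
            assert classify_mechanism([self.EXONS[0]], [], contigs) == "retroposed"

    def test_unplaced_locus_is_an_error(self):
        with pytest.raises(ValueError, match="unplaced"):
            classify_mechanism(self.EXONS, [self.INTRON], {"c": "ACGT"}, placed=False)


class TestAssessPseudogene:
    INTACT = "ATG" + "GCT" * 40 + "TAA"
    BROKEN = "ATG" + "GCT" * 15 + "TGA" + "GCT" * 24 + "TAA"

    def test_stop_plus_silence_is_pseudogene(self):
        assert assess_pseudogene(self.BROKEN, 0.0) == "pseudogene"

    def test_intact_orf_with_expression_is_functional(self):
        assert assess_pseudogene(self.INTACT, 2.5) == "functional"

    def test_conflicting_evidence_is_indeterminate(self):
        assert assess_pseudogene(self.INTACT, 0.0) == "indeterminate"
        assert assess_pseudogene(self.BROKEN, 2.5) == "indeterminate"

    def test_frame_scan_handles_off_frame_lengths(self):
        # two leading bases shift the frame; the scan still finds the
        # open frame and calls the ORF intact
        assert assess_pseudogene("GG" + self.INTACT, 1.0) == "functional"


def test_duplication_mechanisms_recovered_on_demo_panel(demo_panel, demo_summary):
    """Every placed gene's classified mechanism matches the generator
    truth, including the multi-copy transposed gene (all copies hit)."""
    truth = demo_panel.truth["genes"]
    for gene, info in demo_summary["genes"].items():
        assert info["mechanism"] == truth[gene]["mechanism"], gene
        assert info["msy_contig"] == truth[gene]["msy_contig"], gene
    xpr1 = demo_summary["genes"]["Xpr1"]
    assert xpr1["n_hits"] >= 4 * demo_summary["genes"]["Xpr1"]["n_clusters"] > 0
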
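"""Tests for reference handling, SNV classification, filtering and fixtures."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from phagepop import hapio
from phagepop.model import ExperimentConfig, ModelParams
from phagepop.summaries import llr_statistic, lr_statistic, sr_statistic


class TestAnnotation:
    def test_toy_genome_is_valid_and_deterministic(self, toy_annotation):
        again = hapio.make_toy_annotation(seed=3, n_codons_gene1=60)
        assert again.sequence == toy_annotation.sequence
        assert len(toy_annotation.cds) == 2

    def test_overlapping_frames_differ(self, toy_annotation):
        g1, g2 = toy_annotation.cds
        assert g1.start < g2.start <= g1.end  # genes overlap
        assert (g2.start - g1.start) % 3 != 0  # in different frames

    def test_cds_length_must_be_codon_multiple(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            hapio.ReferenceAnnotation("ACGTACGTAC", [hapio.CDS("x", 1, 5)])

    def test_fasta_cds_round_trip(self, toy_annotation, tmp_path):
        fasta, cds = tmp_path / "ref.fa", tmp_path / "cds.tsv"
        toy_annotation.to_files(fasta, cds)
        back = hapio.ReferenceAnnotation.from_files(fasta, cds)
        assert back.sequence == toy_annotation.sequence
        assert back.cds == toy_annotation.cds


def _oracle_classify(pos, alt, annotation):
    """Independent oracle: translate each whole CDS before and after the
    substitution and compare the protein sequences."""
    seq = annotation.sequence
    mutated = seq[:pos - 1] + alt + seq[pos:]
    coding = False
    for c in annotation.cds:
        if not (c.start + c.frame <= pos <= c.end):
            continue
        n = (c.end - (c.start + c.frame) + 1) // 3 * 3
        ref_aa = Seq(seq[c.start + c.frame - 1: c.start + c.frame - 1 + n]).translate()
        alt_aa = Seq(mutated[c.start + c.frame - 1: c.start + c.frame - 1 + n]).translate()
        coding = True
        if ref_aa != alt_aa:
            return "non-synonymous"
    return "synonymous" if coding else "non-coding"


class TestClassifySNV:
    def test_third_position_degenerate_site(self):
        ann = hapio.ReferenceAnnotation("GGAGGGTAA", [hapio.CDS("g", 1, 9)])
        assert hapio.classify_snv(3, "A", "G", ann) == "synonymous"
        assert hapio.classify_snv(1, "G", "A", ann) == "non-synonymous"

    def test_utr_position_is_non_coding(self, toy_annotation):
        assert hapio.classify_snv(5, toy_annotation.sequence[4], "A"
                                  if toy_annotation.sequence[4] != "A" else "C",
                                  toy_annotation) == "non-coding"

    def test_position_outside_genome_rejected(self, toy_annotation):
        with pytest.raises(ValueError, match="outside"):
            hapio.classify_snv(10_000, "A", "C", toy_annotation)

    def test_wrong_reference_base_rejected(self, toy_annotation):
        pos = 100
        ref = toy_annotation.sequence[pos - 1]
        wrong = "A" if ref != "A" else "C"
        with pytest.raises(ValueError, match="reference base"):
            hapio.classify_snv(pos, wrong, "G", toy_annotation)

    def test_agrees_with_translation_oracle_on_every_site(self, toy_annotation):
        seq = toy_annotation.sequence
        for pos in range(1, toy_annotation.genome_length + 1):
            ref = seq[pos - 1]
            for alt in hapio.BASES:
                if alt == ref:
                    continue
                assert hapio.classify_snv(pos, ref, alt, toy_annotation) == \
                    _oracle_classify(pos, alt, toy_annotation), (pos, ref, alt)

    def test_silent_in_one_gene_missense_in_overlap_is_non_synonymous(
            self, toy_annotation):
        """Substitutions in the overlap that are silent for gene1 but change
        gene2's protein must classify as non-synonymous."""
        g1, g2 = toy_annotation.cds
        seq = toy_annotation.sequence
        found = 0
        for pos in range(g2.start, g1.end + 1):
            ref = seq[pos - 1]
            for alt in hapio.BASES:
                if alt == ref:
                    continue
                # silent w.r.t. gene1 alone?
                only_g1 = hapio.ReferenceAnnotation(seq, [g1])
                only_g2 = hapio.ReferenceAnnotation(seq, [g2])
                if (hapio.classify_snv(pos, ref, alt, only_g1) == "synonymous"
                        and hapio.classify_snv(pos, ref, alt, only_g2)
                        == "non-synonymous"):
                    found += 1
                    assert hapio.classify_snv(pos, ref, alt, toy_annotation) == \
                        "non-synonymous"
        assert found > 0  # the overlap genuinely exercises this rule


class TestComputePs:
    def test_fourfold_degenerate_toy_gene(self):
        """Poly-GGG CDS: the 3rd position is 4-fold degenerate, positions 1-2
        are not, so exactly 1/3 of substitutions are synonymous."""
        ann = hapio.ReferenceAnnotation("GGG" * 10, [hapio.CDS("g", 1, 30)])
        assert hapio.compute_ps(ann) == pytest.approx(1 / 3)

    def test_invariant_to_cds_order(self, toy_annotation):
        flipped = hapio.ReferenceAnnotation(
            toy_annotation.sequence, list(reversed(toy_annotation.cds)))
        assert hapio.compute_ps(flipped) == hapio.compute_ps(toy_annotation)

    def test_empty_cds_rejected(self):
        with pytest.raises(ValueError, match="no CDS"):
            hapio.compute_ps(hapio.ReferenceAnnotation("ACGT", []))


class TestPossibleStops:
    def test_known_single_codon_case(self):
        # TGG (Trp): TAG, TGA, TAA(x) -> G2A and G3A create stops
        ann = hapio.ReferenceAnnotation("TGGAAATAA", [hapio.CDS("g", 1, 9)])
        stops = hapio.possible_stop_snvs(ann)
        assert (2, "G", "A") in stops and (3, "G", "A") in stops
        # terminal codon excluded; AAA codon can make TAA? no: A1T gives TAA at 4-6
        assert (4, "A", "T") in stops


class TestFilterReads:
    POLICY = hapio.ReadFilterPolicy()

    @staticmethod
    def _records(rows):
        return pd.DataFrame(rows, columns=[
            "read_id", "line", "passage", "aligned_length", "strand",
            "n_alignments", "snvs"])

    def test_policy_gates(self, toy_annotation):
        min_len = int(np.ceil(0.98 * toy_annotation.genome_length))
        rows = [
            ("ok", "A", 3, toy_annotation.genome_length, "+", 1, ""),
            ("short", "A", 3, min_len - 10, "+", 1, ""),
            ("minus", "A", 3, toy_annotation.genome_length, "-", 1, ""),
            ("multi", "A", 3, toy_annotation.genome_length, "+", 2, ""),
        ]
        table, report = hapio.filter_reads(self._records(rows), self.POLICY,
                                           toy_annotation)
        assert list(table["read_id"]) == ["ok"]
        assert report == {"retained": 1, "too_short": 1, "multiple_alignments": 1,
                          "minus_strand": 1, "malformed": 0}

    def test_indel_tokens_dropped_and_malformed_reported(self, toy_annotation):
        L = toy_annotation.genome_length
        rows = [
            ("indel", "A", 3, L, "+", 1, "A100C;T200-"),
            ("bad", "A", 3, L, "+", 1, "xyz"),
        ]
        table, report = hapio.filter_reads(self._records(rows), self.POLICY,
                                           toy_annotation)
        assert list(table["snvs"]) == ["A100C"]
        assert report["malformed"] == 1


class TestClassAssignment:
    def test_read_class_tuples(self, toy_annotation):
        seq = toy_annotation.sequence
        syn, nonsyn = [], []
        for pos in toy_annotation.coding_positions():
            ref = seq[pos - 1]
            for alt in hapio.BASES:
                if alt == ref:
                    continue
                kind = hapio.classify_snv(int(pos), ref, alt, toy_annotation)
                (syn if kind == "synonymous" else nonsyn).append(
                    hapio.format_snv(int(pos), ref, alt))
        founder = {syn[0]}
        beneficial = {nonsyn[0]}
        table = pd.DataFrame([
            {"read_id": "r0", "line": "A", "passage": 3, "snvs": ""},
            {"read_id": "r1", "line": "A", "passage": 3,
             "snvs": f"{syn[0]};{nonsyn[0]}"},
        ])
        dists = hapio.table_to_class_distribution(table, toy_annotation,
                                                  beneficial, founder)
        d = dists[("A", 3)].as_dict()
        assert d[(0, 0, 0, 0, 0, 0)] == 0.5
        assert d[(1, 0, 0, 0, 0, 1)] == 0.5

    def test_non_coding_snv_rejected(self, toy_annotation):
        ref = toy_annotation.sequence[0]
        alt = "A" if ref != "A" else "C"
        table = pd.DataFrame([{"read_id": "r", "line": "A", "passage": 3,
                               "snvs": hapio.format_snv(1, ref, alt)}])
        with pytest.raises(ValueError, match="non-coding"):
            hapio.table_to_class_distribution(table, toy_annotation, set(), set())


class TestFixture:
    PARAMS = ModelParams(0.9, 0.7, 1.8, 0.005, 0.005, 0.5, 0.8, 1.0, -0.3, 0.2)
    CONFIG = ExperimentConfig(N=50_000, coverage={3: 250, 7: 250, 10: 250})

    def test_snv_free_when_everything_is_off(self):
        params = ModelParams(1, 1, 1, 0, 0, 0, 0, 0, 1, 0.0)
        cfg = ExperimentConfig(N=1000, coverage={3: 50, 7: 50, 10: 50}, err_seq=0.0)
        table, _ = hapio.generate_fixture(params, cfg, n_lines=1, seed=1)
        assert (table["snvs"] == "").all()

    def test_round_trip_reproduces_class_frequencies_exactly(self):
        table, truth = hapio.generate_fixture(self.PARAMS, self.CONFIG,
                                              n_lines=2, seed=5)
        dists = hapio.table_to_class_distribution(
            table, truth.annotation, truth.beneficial_snvs, truth.founder_snvs)
        assert set(dists) == set(truth.class_distributions)
        for key in dists:
            assert dists[key].as_dict() == truth.class_distributions[key].as_dict()

    def test_round_trip_preserves_summary_vectors_bit_exactly(self):
        table, truth = hapio.generate_fixture(self.PARAMS, self.CONFIG,
                                              n_lines=1, seed=6)
        dists = hapio.table_to_class_distribution(
            table, truth.annotation, truth.beneficial_snvs, truth.founder_snvs)
        observed = {p: d for (_, p), d in dists.items()}
        simulated = {p: d for (_, p), d in truth.class_distributions.items()}
        for stat in (sr_statistic, lr_statistic, llr_statistic):
            np.testing.assert_array_equal(stat(observed).values,
                                          stat(simulated).values)

    def test_fixed_seed_gives_byte_identical_table(self, tmp_path):
        paths = []
        for i, run in enumerate("ab"):
            table, _ = hapio.generate_fixture(self.PARAMS, self.CONFIG,
                                              n_lines=1, seed=9)
            path = tmp_path / f"{run}.tsv"
            hapio.write_haplotype_table(table, path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_table_tsv_round_trip(self, tmp_path):
        table, _ = hapio.generate_fixture(self.PARAMS, self.CONFIG,
                                          n_lines=1, seed=10)
        path = tmp_path / "tab.tsv"
        hapio.write_haplotype_table(table, path)
        back = hapio.read_haplotype_table(path)
        pd.testing.assert_frame_equal(back, table)


class TestTrajectoriesAndFounders:
    def test_snv_trajectories_frequencies(self):
        table = pd.DataFrame([
            {"read_id": "r0", "line": "A", "passage": 3, "snvs": "A10C"},
            {"read_id": "r1", "line": "A", "passage": 3, "snvs": "A10C;G20T"},
            {"read_id": "r2", "line": "A", "passage": 3, "snvs": ""},
            {"read_id": "r3", "line": "A", "passage": 10, "snvs": "A10C"},
        ])
        traj = hapio.snv_trajectories(table)
        f = traj.set_index(["snv", "passage"])["frequency"]
        assert f[("A10C", 3)] == pytest.approx(2 / 3)
        assert f[("G20T", 3)] == pytest.approx(1 / 3)
        assert f[("A10C", 10)] == 1.0

    def test_founder_identification_threshold(self):
        traj = pd.DataFrame([
            {"line": "A", "passage": 3, "snv": "A10C", "frequency": 0.08},
            {"line": "B", "passage": 3, "snv": "A10C", "frequency": 0.07},
            {"line": "A", "passage": 3, "snv": "G20T", "frequency": 0.01},
            {"line": "B", "passage": 3, "snv": "G20T", "frequency": 0.09},
        ])
        assert hapio.identify_founder_snvs(traj) == {"A10C"}
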
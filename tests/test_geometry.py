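"""Circular gene-organization accounting against the published annotation."""

import pytest

from mitokit.geometry import (gene_length, intergenic_nucleotides,
                              locate_control_region, organization_table,
                              spacer_overlap_summary, strand_census)
from mitokit.model import AnnotatedMitogenome, GeneFeature, ValidationError


def _by_name(features):
    return {f.name: f for f in features}


class TestGeneLength:
    def test_published_gene_lengths(self, published_annotation):
        features, n = published_annotation
        by = _by_name(features)
        assert gene_length(by["ND5"], n) == 1812
        assert gene_length(by["COX1"], n) == 1545
        assert gene_length(by["rrnS"], n) == 955
        assert gene_length(by["rrnL"], n) == 1575

    def test_single_base_and_wrap(self):
        assert gene_length(GeneFeature("x", "tRNA", 5, 5, "+"), 100) == 1
        assert gene_length(GeneFeature("x", "tRNA", 16490, 10, "+"), 16497) == 18

    def test_rejects_nonpositive_genome_length(self):
        with pytest.raises(ValidationError):
            gene_length(GeneFeature("x", "tRNA", 1, 5, "+"), 0)


class TestIntergenic:
    def test_published_overlaps_and_abutments(self, published_annotation):
        features, n = published_annotation
        gaps = {(r.upstream, r.downstream): r.intergenic_nt
                for r in intergenic_nucleotides(features, n)}
        assert gaps[("atp8", "atp6")] == -43
        assert gaps[("ND4L", "ND4")] == -7
        assert gaps[("trnV", "rrnL")] == 0
        assert gaps[("trnF", "rrnS")] == 2

    def test_largest_overlaps_are_atp8_and_nd4l(self, published_annotation):
        features, n = published_annotation
        overlaps = sorted((r for r in intergenic_nucleotides(features, n)
                           if r.intergenic_nt < 0),
                          key=lambda r: r.intergenic_nt)
        assert (overlaps[0].upstream, overlaps[0].intergenic_nt) == ("atp8", -43)
        pcg_overlaps = [r for r in overlaps
                        if r.upstream in ("atp8", "ND4L")]
        assert {r.intergenic_nt for r in pcg_overlaps} == {-43, -7}

    def test_unsorted_input_rejected(self):
        feats = [GeneFeature("b", "tRNA", 50, 60, "+"),
                 GeneFeature("a", "tRNA", 1, 10, "+")]
        with pytest.raises(ValidationError):
            intergenic_nucleotides(feats, 100)

    def test_conservation_law_published(self, published_annotation):
        """Gene lengths plus signed gaps tile the circle exactly."""
        features, n = published_annotation
        gaps = intergenic_nucleotides(features, n)
        total = sum(f.end - f.start + 1 for f in features) + \
            sum(r.intergenic_nt for r in gaps)
        assert total == n

    def test_conservation_law_synthetic(self, synthetic_genome):
        genome, _ = synthetic_genome
        n = len(genome.sequence)
        gaps = intergenic_nucleotides(genome.features, n)
        total = sum(f.length(n) for f in genome.features) + \
            sum(r.intergenic_nt for r in gaps)
        assert total == n

    def test_classification_partition(self, published_annotation):
        features, n = published_annotation
        for r in intergenic_nucleotides(features, n):
            kinds = [r.intergenic_nt > 0, r.intergenic_nt < 0,
                     r.intergenic_nt == 0]
            assert sum(kinds) == 1
            assert r.kind == ("spacer", "overlap", "abutting")[kinds.index(True)]


class TestStrandCensus:
    def test_published_census(self, skeleton_genome):
        census = strand_census(skeleton_genome)
        assert census[("H", "PCG")] == 12
        assert census[("H", "tRNA")] == 14
        assert census[("H", "rRNA")] == 2
        assert census[("L", "PCG")] == 1
        assert census[("L", "tRNA")] == 8
        assert sum(v for (s, _), v in census.items() if s == "H") == 28
        assert sum(v for (s, _), v in census.items() if s == "L") == 9

    def test_zero_feature_genome(self):
        assert strand_census(AnnotatedMitogenome("t", "ACGT")) == {}

    def test_synthetic_matches_ledger(self, synthetic_genome):
        genome, ledger = synthetic_genome
        census = strand_census(genome)
        for key, count in ledger["strand_census"].items():
            strand, cls = key.split(":")
            assert census[(strand, cls)] == count


class TestControlRegion:
    def test_published_location(self, skeleton_genome):
        cr = locate_control_region(skeleton_genome)
        assert (cr.start, cr.end) == (15434, 16497)
        assert cr.length(len(skeleton_genome.sequence)) == 1064

    def test_missing_trn_genes(self):
        g = AnnotatedMitogenome("t", "A" * 100)
        with pytest.raises(ValidationError, match="missing"):
            locate_control_region(g)

    def test_degenerate_zero_length_region(self):
        feats = [GeneFeature("trnF", "tRNA", 1, 30, "+"),
                 GeneFeature("trnP", "tRNA", 71, 100, "L")]
        g = AnnotatedMitogenome("t", "A" * 100, features=feats)
        with pytest.raises(ValidationError, match="degenerate"):
            locate_control_region(g)

    def test_generator_control_length_recovered(self, synthetic_genome):
        genome, ledger = synthetic_genome
        cr = locate_control_region(genome)
        start, end, length = ledger["control_region"]
        assert (cr.start, cr.end) == (start, end)
        assert cr.length(len(genome.sequence)) == length


class TestOrganizationTable:
    def test_row_count_and_lengths(self, skeleton_genome):
        rows = organization_table(skeleton_genome)
        assert len(rows) == 37
        by = {r.feature.name: r for r in rows}
        assert by["ND5"].length_bp == 1812
        assert by["atp8"].intergenic_nt == -43
        # undetermined sequence -> codons omitted
        assert by["ND5"].start_codon is None

    def test_codons_on_synthetic(self, synthetic_genome):
        genome, ledger = synthetic_genome
        rows = {r.feature.name: r for r in organization_table(genome)}
        for name, cds in ledger["cds"].items():
            assert rows[name].start_codon == cds[:3]

    def test_single_gene_circular_self_spacer(self):
        g = AnnotatedMitogenome(
            "t", "A" * 100,
            features=[GeneFeature("solo", "tRNA", 11, 40, "+")])
        rows = organization_table(g)
        assert len(rows) == 1
        assert rows[0].intergenic_nt == 100 - 40 + 11 - 1


class TestSpacerOverlapSummary:
    def test_counts_split_spacers_from_overlaps(self, published_annotation):
        features, n = published_annotation
        summary = spacer_overlap_summary(intergenic_nucleotides(features, n))
        records = intergenic_nucleotides(features, n)
        assert summary["n_spacers"] == sum(r.intergenic_nt > 0 for r in records)
        assert summary["n_overlaps"] == sum(r.intergenic_nt < 0 for r in records)
        assert summary["overlap_max_bp"] == 43
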
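"""Nei-Gojobori counting, Jukes-Cantor correction, and the selection screen."""

import math

import numpy as np
import pytest

from mitokit.codons import ALL_CODONS, VERTEBRATE_MITO
from mitokit.selection import (jukes_cantor, kaks_pair, ng_pair_differences,
                               ng_site_counts, per_gene_kaks,
                               prepare_gene_set)
from mitokit.model import ValidationError

from ng_oracle import oracle_differences, oracle_pair_counts, oracle_sites

SENSE = [c for c in ALL_CODONS if not VERTEBRATE_MITO.is_stop(c)]


class TestSiteCounts:
    def test_phe_third_position(self):
        # TTT: only TTT->TTC is synonymous (TTA/TTG are Leu)
        s, n = ng_site_counts("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_met_under_mito_code(self):
        # ATA is Met under the mitochondrial code, so ATG has one
        # synonymous neighbor (none under the standard code)
        s, _ = ng_site_counts("ATG")
        assert s == pytest.approx(1 / 3)
        from mitokit.codons import GeneticCode
        s_std, _ = ng_site_counts("ATG", GeneticCode.from_ncbi(1))
        assert s_std == 0.0

    def test_site_conservation_all_sense_codons(self):
        for codon in SENSE:
            s, n = ng_site_counts(codon)
            assert s + n == pytest.approx(3.0)
            assert (s, n) == pytest.approx(oracle_sites(codon))

    def test_stop_codon_rejected(self):
        with pytest.raises(ValidationError):
            ng_site_counts("TAA")


class TestPairDifferences:
    @pytest.mark.parametrize("a,b,expect", [
        ("TTA", "TTG", (1.0, 0.0)),   # Leu -> Leu, one synonymous step
        ("TTA", "CTA", (1.0, 0.0)),   # Leu -> Leu across the TTR/CTN boxes
        ("ATG", "ATG", (0.0, 0.0)),
    ])
    def test_known_single_steps(self, a, b, expect):
        assert ng_pair_differences(a, b) == pytest.approx(expect)

    def test_two_step_pathway_averaging(self):
        # ATG -> ACT via ACG or ATT; must equal the exhaustive enumeration
        assert ng_pair_differences("ATG", "ACT") == \
            pytest.approx(oracle_differences("ATG", "ACT"))

    def test_matches_oracle_on_random_codon_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(400):
            a, b = rng.choice(SENSE, 2)
            got = ng_pair_differences(a, b)
            want = oracle_differences(a, b)
            assert got == pytest.approx(want, abs=1e-12), (a, b)

    def test_difference_total_equals_hamming(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            a, b = rng.choice(SENSE, 2)
            sd, nd = ng_pair_differences(a, b)
            k = sum(x != y for x, y in zip(a, b))
            assert sd + nd == pytest.approx(k)


class TestJukesCantor:
    def test_formula(self):
        p = 0.2
        assert jukes_cantor(p) == pytest.approx(-0.75 * math.log(1 - 4 * p / 3))
        assert jukes_cantor(0.0) == 0.0

    def test_saturation(self):
        assert jukes_cantor(0.75) is None
        assert jukes_cantor(0.9) is None


class TestKaksPair:
    def test_identical_sequences_undefined(self):
        r = kaks_pair("ATGTTTAAA", "ATGTTTAAA")
        assert r.Ka == r.Ks == 0.0
        assert r.ratio is None
        assert r.label == "undefined"

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = "".join(rng.choice(SENSE, 5))
            b = "".join(rng.choice(SENSE, 5))
            r1, r2 = kaks_pair(a, b), kaks_pair(b, a)
            assert (r1.S, r1.N, r1.Sd, r1.Nd) == (r2.S, r2.N, r2.Sd, r2.Nd)

    def test_site_conservation(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            a = "".join(rng.choice(SENSE, 7))
            b = "".join(rng.choice(SENSE, 7))
            r = kaks_pair(a, b)
            assert r.S + r.N == pytest.approx(3 * r.codons_used)

    def test_matches_exhaustive_oracle_on_short_pairs(self):
        """S, N, Sd, Nd agree with the independent pathway-enumeration
        oracle to 1e-12 over 1000 random pairs of up to 3 codons."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            k = int(rng.integers(1, 4))
            a = "".join(rng.choice(SENSE, k))
            b = "".join(rng.choice(SENSE, k))
            r = kaks_pair(a, b)
            S, N, Sd, Nd = oracle_pair_counts(a, b)
            for got, want in [(r.S, S), (r.N, N), (r.Sd, Sd), (r.Nd, Nd)]:
                assert abs(got - want) < 1e-12, (a, b)

    def test_matches_independent_ng86_implementation(self):
        """Cross-check Ka and Ks against Biopython's NG86 on random codon
        alignments under the mitochondrial table."""
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        from Bio.Data import CodonTable
        t2 = CodonTable.unambiguous_dna_by_id[2]
        rng = np.random.default_rng(8)
        for _ in range(20):
            a = "".join(rng.choice(SENSE, 40))
            bl = []
            for i in range(0, len(a), 3):
                c = a[i:i + 3]
                if rng.random() < 0.15:
                    alts = [x for x in SENSE
                            if sum(p != q for p, q in zip(x, c)) == 1]
                    c = str(rng.choice(alts))
                bl.append(c)
            b = "".join(bl)
            r = kaks_pair(a, b)
            dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86",
                               codon_table=t2)
            assert r.Ka == pytest.approx(dn, abs=1e-9)
            assert r.Ks == pytest.approx(ds, abs=1e-9)

    def test_gap_and_ambiguous_codons_skipped_pairwise(self):
        r = kaks_pair("ATG---TTT", "ATGAAATTC")
        assert r.codons_used == 2

    def test_length_errors(self):
        with pytest.raises(ValidationError):
            kaks_pair("ATGTTT", "ATG")
        with pytest.raises(ValidationError):
            kaks_pair("ATGT", "ATGA")

    def test_saturated_pair_flagged(self):
        # codon columns all maximally different -> p beyond the JC domain
        a = "TGT" * 40
        b = "ACA" * 40
        r = kaks_pair(a, b)
        assert r.label == "undefined"
        assert r.Ka is None or r.Ks is None
        assert r.saturated


class TestPrepareGeneSet:
    def test_concatenation_duplicates_overlap_positions(self, synthetic_genome):
        """Positions shared by two PCGs belong to both prepared genes, so
        the concatenation length equals the plain sum of the per-gene
        trimmed lengths."""
        genome, _ = synthetic_genome
        genes, concat = prepare_gene_set(genome)
        assert len(genes) == 13
        assert len(concat) == sum(len(s) for s in genes.values())
        # the ATP8/ATP6 overlap appears in both genes
        atp8, atp6 = genome.get("atp8"), genome.get("atp6")
        shared = range(atp6.start, atp8.end + 1)
        assert len(shared) == 43

    def test_stop_removed_and_in_frame(self, synthetic_genome):
        genome, _ = synthetic_genome
        genes, _ = prepare_gene_set(genome)
        for name, cds in genes.items():
            assert len(cds) % 3 == 0
            assert not VERTEBRATE_MITO.is_stop(cds[-3:]), name

    def test_missing_gene_strict_vs_lenient(self, synthetic_genome):
        genome, _ = synthetic_genome
        from mitokit.model import AnnotatedMitogenome
        no_nd6 = AnnotatedMitogenome(
            "t", genome.sequence,
            features=[f for f in genome.features if f.name != "ND6"])
        with pytest.raises(ValidationError):
            prepare_gene_set(no_nd6, include=[p.name for p in genome.pcgs])
        with pytest.warns(UserWarning):
            genes, _ = prepare_gene_set(
                no_nd6, include=[p.name for p in genome.pcgs], strict=False)
        assert len(genes) == 12


class TestSelectionScreen:
    def test_planted_counts_recovered_exactly(self, species_pair):
        base, derived, ledger, plans = species_pair
        results = {r.gene: r for r in per_gene_kaks(base, derived)}
        for name, plan in plans.items():
            r = results[name]
            assert r.Sd == pytest.approx(plan.n_syn, abs=1e-9)
            assert r.Nd == pytest.approx(plan.n_nonsyn, abs=1e-9)

    def test_only_nd5_flagged_positive(self, species_pair):
        base, derived, _, _ = species_pair
        results = [r for r in per_gene_kaks(base, derived)
                   if r.gene != "concatenated_PCGs"]
        flagged = {r.gene for r in results if r.label == "positive"}
        assert flagged == {"ND5"}
        for r in results:
            if r.gene != "ND5":
                assert r.label == "purifying"

    def test_identical_genomes_all_undefined(self, synthetic_genome):
        genome, _ = synthetic_genome
        for r in per_gene_kaks(genome, genome):
            assert r.label == "undefined"
            assert r.ratio is None

    def test_ka_monotone_in_planted_nonsynonymous_changes(self):
        """Holding Sd fixed, adding nonsynonymous changes never lowers Ka."""
        from mitokit.synthetic import GenomeSpec, MutationPlan, \
            generate_species_pair
        kas = []
        for n_nonsyn in (2, 6, 12):
            base, derived, _, = generate_species_pair(
                GenomeSpec(seed=21), {"ND5": MutationPlan(3, n_nonsyn)})[:3]
            r = {x.gene: x for x in per_gene_kaks(base, derived)}["ND5"]
            kas.append(r.Ka)
        assert kas == sorted(kas)

    def test_concatenation_totals_sum_per_gene_counts(self, species_pair):
        base, derived, _, plans = species_pair
        results = {r.gene: r for r in per_gene_kaks(base, derived)}
        concat = results["concatenated_PCGs"]
        assert concat.Sd == pytest.approx(
            sum(p.n_syn for p in plans.values()), abs=1e-9)
        assert concat.Nd == pytest.approx(
            sum(p.n_nonsyn for p in plans.values()), abs=1e-9)
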
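"""Homology search and spliced-alignment tests.

The dynamic program is checked against an independent memoized-recursion
reimplementation of the same state machine on small inputs, and against
planted structures (introns, frameshifts, stops) on realistic ones.
"""

from functools import lru_cache

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from retroforge.homology import (
    GenomeIndex,
    Hsp,
    SearchParams,
    chain_hsps,
    search_protein_vs_genome,
    spliced_align,
)
from retroforge.io_formats import GenomeAssembly, reverse_complement, translate
from retroforge.simulate import _random_cds

BLOSUM = substitution_matrices.load("BLOSUM62")


# --------------------------------------------------------------------------
# independent oracle: plain recursion over the same state machine


def oracle_best_score(protein, dna, params):
    """Maximum local parse score by memoized recursion (small inputs only)."""
    P, D = len(protein), len(dna)
    gt = [dna[j : j + 2] == "GT" for j in range(D)]
    ag = [dna[j - 2 : j] == "AG" for j in range(D + 1)]

    def codon_score(i, j):
        codon = dna[j - 3 : j]
        if "N" in codon:
            return 0.0
        aa = str(Seq(codon).translate())
        return float(BLOSUM[protein[i - 1], aa])

    @lru_cache(maxsize=None)
    def best(i, j):
        options = [0.0]
        if i >= 1 and j >= 3:
            options.append(best(i - 1, j - 3) + codon_score(i, j))
        for nb in (1, 2, 4, 5):
            if i >= 1 and j >= nb:
                options.append(best(i - 1, j - nb) + params.frameshift_penalty)
        if i >= 1:
            options.append(best(i - 1, j) + params.gap_aa)
        if j >= 3:
            options.append(best(i, j - 3) + params.gap_codon)
        if ag[j]:
            for jp in range(0, j - params.min_intron + 1):
                if gt[jp]:
                    options.append(best(i, jp) + params.intron_penalty)
        return max(options)

    return max(best(i, j) for i in range(P + 1) for j in range(D + 1))


class TestSplicedAlignOracle:
    @pytest.mark.parametrize("case", ["exact", "intron", "frameshift", "random"])
    def test_dp_matches_recursion_oracle(self, case):
        rng = np.random.default_rng(hash(case) % 2**31)
        params = SearchParams(min_structure_score=1.0, min_intron=30)
        cds = _random_cds(rng, 10)
        protein = translate(cds)
        if case == "exact":
            dna = cds
        elif case == "intron":
            dna = cds[:15] + "GT" + "C" * 28 + "AG" + cds[15:]
        elif case == "frameshift":
            dna = cds[:13] + cds[14:]
        else:
            dna = "".join(rng.choice(list("ACGT"), size=45))
        st = spliced_align(protein, dna, params)
        expected = oracle_best_score(protein, dna, params)
        got = st.score if st.accepted else 0.0
        if expected > params.min_structure_score:
            assert got == pytest.approx(expected)
        else:
            assert not st.accepted


class TestSplicedAlignStructures:
    def setup_method(self):
        self.rng = np.random.default_rng(23)
        self.cds = _random_cds(self.rng, 120)
        self.protein = translate(self.cds)

    def test_self_parse_of_two_exon_gene_recovers_the_intron(self):
        locus = self.cds[:180] + "GT" + "C" * 80 + "AG" + self.cds[180:]
        st = spliced_align(self.protein, locus)
        assert st.accepted and st.intron_count == 1
        assert st.frameshift_positions == [] and st.stop_positions == []
        assert st.intron_positions_aa() == [60]

    def test_intronless_copy_parses_clean_with_full_coverage(self):
        st = spliced_align(self.protein, "TTT" * 30 + self.cds + "AAA" * 20)
        assert st.intron_count == 0 and st.coverage == 1.0 and st.identity == 1.0

    def test_single_base_deletion_is_reported_as_one_frameshift(self):
        mutated = self.cds[:90] + self.cds[91:]  # 1 bp deletion inside codon 30
        st = spliced_align(self.protein, mutated)
        assert len(st.frameshift_positions) == 1
        assert abs(st.frameshift_positions[0] - 30) <= 1

    def test_premature_stop_is_recorded_at_its_codon(self):
        mutated = self.cds[:150] + "TGA" + self.cds[153:]
        st = spliced_align(self.protein, mutated)
        assert st.stop_positions == [50]

    def test_rejects_unrelated_sequence(self):
        noise = "".join(np.random.default_rng(0).choice(list("ACGT"), size=400))
        st = spliced_align(self.protein[:60], noise)
        assert not st.accepted


def _genome_with_insert(insert, seed=0, length=30_000, at=11_000):
    rng = np.random.default_rng(seed)
    bg = "".join(rng.choice(list("ACGT"), size=length))
    return GenomeAssembly({"chr1": bg[:at] + insert + bg[at + len(insert) :]})


class TestSearch:
    def setup_method(self):
        rng = np.random.default_rng(31)
        self.cds = _random_cds(rng, 90)
        self.protein = translate(self.cds)

    def test_exact_copy_found_with_full_identity(self):
        genome = _genome_with_insert(self.cds)
        hsps = search_protein_vs_genome("q", self.protein, GenomeIndex(genome))
        assert len(hsps) == 1
        h = hsps[0]
        assert h.identity == 1.0 and h.strand == "+"
        assert h.g_start == 11_000 and h.g_end == 11_000 + len(self.cds)

    def test_reverse_complement_insertion_reported_on_minus_strand(self):
        fwd = _genome_with_insert(self.cds)
        rev = _genome_with_insert(reverse_complement(self.cds))
        h_fwd = search_protein_vs_genome("q", self.protein, GenomeIndex(fwd))
        h_rev = search_protein_vs_genome("q", self.protein, GenomeIndex(rev))
        assert len(h_fwd) == len(h_rev) == 1
        assert h_rev[0].strand == "-"
        assert h_rev[0].score == h_fwd[0].score

    def test_strand_symmetry_of_whole_chromosome(self):
        genome = _genome_with_insert(self.cds)
        flipped = GenomeAssembly({"chr1": reverse_complement(genome.sequences["chr1"])})
        a = search_protein_vs_genome("q", self.protein, GenomeIndex(genome))
        b = search_protein_vs_genome("q", self.protein, GenomeIndex(flipped))
        assert sorted(h.score for h in a) == sorted(h.score for h in b)
        assert {h.strand for h in a} == {"+"} and {h.strand for h in b} == {"-"}

    def test_partial_copy_well_below_50_aa_not_reported(self):
        rng = np.random.default_rng(33)
        cds = _random_cds(rng, 60)
        protein = translate(cds)
        genome = _genome_with_insert(cds[: 40 * 3], seed=5)  # 40 aa fragment
        hsps = search_protein_vs_genome("q", protein, GenomeIndex(genome))
        assert hsps == []

    def test_short_query_skipped(self):
        genome = _genome_with_insert(self.cds)
        assert search_protein_vs_genome("q", "MKL", GenomeIndex(genome)) == []


def _hsp(pid, chrom, strand, ps, pe, gs, ge, score=100.0):
    return Hsp(pid, chrom, strand, 0, ps, pe, gs, ge, score, 0.9)


class TestChaining:
    def test_collinear_hsps_within_max_intron_form_one_locus(self):
        hsps = [
            _hsp("p", "chr1", "+", 0, 60, 1000, 1180),
            _hsp("p", "chr1", "+", 60, 120, 3180, 3360),
        ]
        loci = chain_hsps(hsps, max_intron=50_000)
        assert len(loci) == 1
        assert (loci[0].g_start, loci[0].g_end) == (1000, 3360)

    def test_distant_hsps_split_into_two_loci(self):
        hsps = [
            _hsp("p", "chr1", "+", 0, 60, 1000, 1180),
            _hsp("p", "chr1", "+", 60, 120, 600_000, 600_180),
        ]
        assert len(chain_hsps(hsps, max_intron=50_000)) == 2

    def test_crossed_protein_order_is_not_chained(self):
        hsps = [
            _hsp("p", "chr1", "+", 60, 120, 1000, 1180),
            _hsp("p", "chr1", "+", 0, 60, 3180, 3360),
        ]
        assert len(chain_hsps(hsps, max_intron=50_000)) == 2

    def test_minus_strand_chains_with_reversed_protein_order(self):
        hsps = [
            _hsp("p", "chr1", "-", 60, 120, 1000, 1180),
            _hsp("p", "chr1", "-", 0, 60, 3180, 3360),
        ]
        assert len(chain_hsps(hsps, max_intron=50_000)) == 1

    def test_chains_are_pairwise_consistent_on_random_sets(self):
        """Soundness vs an independently coded pairwise predicate."""

        def compatible(a, b, max_intron):  # a before b in genomic order
            if a.chrom != b.chrom or a.strand != b.strand:
                return False
            if b.g_start - a.g_end > max_intron:
                return False
            if a.strand == "+":
                return b.prot_start >= a.prot_start and b.prot_end >= a.prot_end
            return b.prot_start <= a.prot_start and b.prot_end <= a.prot_end

        rng = np.random.default_rng(41)
        for _ in range(5):
            hsps = []
            for _ in range(8):
                gs = int(rng.integers(0, 100_000))
                ps = int(rng.integers(0, 150))
                hsps.append(
                    _hsp(
                        "p",
                        "chr1",
                        "+" if rng.random() < 0.5 else "-",
                        ps,
                        ps + 50,
                        gs,
                        gs + 150,
                    )
                )
            for locus in chain_hsps(hsps, max_intron=20_000):
                ordered = sorted(locus.hsps, key=lambda h: h.g_start)
                for a, b in zip(ordered, ordered[1:]):
                    assert compatible(a, b, 20_000)
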
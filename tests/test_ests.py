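"""EST cleaning, mapping, uniqueness filtering and support counting."""

import numpy as np
import pytest

from conftest import match_truth
from retroforge.ests import (
    EstAlignment,
    EstParams,
    NucleotideIndex,
    clean_ests,
    count_support,
    expression_support,
    filter_unique,
    map_est,
)
from retroforge.io_formats import GenomeAssembly, reverse_complement
from retroforge.simulate import _random_dna


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestCleanEsts:
    def test_polya_tail_is_trimmed_and_read_kept(self):
        body = _random_dna(_rng(1), 299, 0.5) + "G"  # body must not end in A
        kept, rejected = clean_ests([("e1", body + "A" * 25)])
        assert kept == [("e1", body)] and rejected == []

    def test_short_reads_dropped(self):
        kept, rejected = clean_ests([("e1", _random_dna(_rng(2), 60, 0.5))])
        assert kept == [] and rejected == [("e1", "short")]

    def test_low_complexity_reads_dropped(self):
        kept, rejected = clean_ests([("e1", "AT" * 150)])
        assert kept == [] and rejected[0][1] in {"low_complexity", "mononucleotide"}

    def test_mononucleotide_reads_dropped(self):
        kept, rejected = clean_ests([("e1", "A" * 200 + "C" * 10)])
        assert kept == []


class TestMapEst:
    def setup_method(self):
        rng = _rng(11)
        self.chrom = _random_dna(rng, 40_000, 0.45)
        self.genome = GenomeAssembly({"chr1": self.chrom})
        self.index = NucleotideIndex(self.genome)

    def test_error_free_read_maps_to_its_source(self):
        read = self.chrom[5000:5400]
        alns = map_est("e", read, self.index)
        assert alns
        best = alns[0]
        assert best.chrom == "chr1" and best.strand == "+"
        assert best.g_start == 5000 and best.g_end == 5400
        assert best.identity == 1.0

    def test_reverse_strand_read_found_on_minus(self):
        read = reverse_complement(self.chrom[5000:5400])
        alns = map_est("e", read, self.index)
        assert alns and alns[0].strand == "-"
        assert alns[0].g_start == 5000

    def test_read_with_8_percent_error_fails_identity_gate(self):
        rng = _rng(12)
        read = list(self.chrom[5000:5400])
        for i in rng.choice(400, size=32, replace=False):
            read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
        assert map_est("e", "".join(read), self.index) == []

    def test_read_with_1_percent_error_passes(self):
        rng = _rng(13)
        read = list(self.chrom[5000:5400])
        for i in rng.choice(400, size=4, replace=False):
            read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
        alns = map_est("e", "".join(read), self.index)
        assert alns and alns[0].identity > 0.95 and alns[0].g_start == 5000


def _aln(est_id, score, start=0, end=400):
    a = EstAlignment(
        est_id=est_id,
        chrom="chr1",
        strand="+",
        g_start=start,
        g_end=end,
        aligned_length=end - start,
        edit_distance=(end - start) - score,
        identity=score / (end - start),
        coverage=1.0,
        cigar=f"{end - start}=",
    )
    return a


class TestFilterUnique:
    def test_single_passing_alignment_is_unique(self):
        assert filter_unique([_aln("e", 400)]) is not None

    def test_equal_scores_are_ambiguous(self):
        assert filter_unique([_aln("e", 300), _aln("e", 300, 5000, 5400)]) is None

    def test_margin_of_ten_percent_is_unique(self):
        best = _aln("e", 200)
        second = _aln("e", 180, 5000, 5400)
        assert filter_unique([best, second]) is best


class TestCountSupport:
    def _record(self, start=1000, end=2000):
        from retroforge.discovery import RetrocopyRecord

        return RetrocopyRecord(
            retro_id="r1",
            chrom="chr1",
            strand="+",
            start=start,
            end=end,
            parent_gene="g",
            parent_protein="p",
            cls="intact",
            chimeric=False,
            overlaps_annotation=False,
            identity=0.95,
            coverage=1.0,
            n_frameshifts=0,
            n_stops=0,
            score=100.0,
        )

    def test_no_ests_means_zero_support(self):
        counts = count_support([], [self._record()])
        assert counts[0].n_supporting_ests == 0

    def test_80_bp_overlap_is_below_the_gate(self):
        aln = _aln("e", 400, start=940, end=1080)  # 80 bp inside [1000, 2000)
        counts = count_support([aln], [self._record()])
        assert counts[0].n_supporting_ests == 0

    def test_large_clean_overlap_counts(self):
        aln = _aln("e", 400, start=1100, end=1500)
        counts = count_support([aln], [self._record()])
        assert counts[0].n_supporting_ests == 1
        assert counts[0].supporting_est_ids == ["e"]


class TestEndToEndSupport:
    def test_supported_set_recovers_expressed_truth(self, small_ds, small_catalogue):
        counts, stats = expression_support(small_ds.ests, small_ds.genome, small_catalogue)
        truth = [t for t in small_ds.truth if t.kind == "retro"]
        supported = {c.retro_id for c in counts if c.n_supporting_ests > 0}
        rec_by_id = {r.retro_id: r for r in small_catalogue}
        sup_events = set()
        for rid in supported:
            t = match_truth(rec_by_id[rid], truth)
            if t is not None:
                sup_events.add(t.event_id)
        expressed = {t.event_id for t in truth if t.expressed}
        assert expressed
        tp = len(sup_events & expressed)
        precision = tp / max(1, len(sup_events))
        recall = tp / len(expressed)
        assert precision >= 0.9
        assert recall >= 0.8

    def test_loosening_thresholds_never_decreases_support(self, small_ds, small_catalogue):
        strict = EstParams()
        # loosen the support-counting thresholds (the mapping/uniqueness
        # gates interact non-monotonically by design: admitting more
        # alignments can make a read ambiguous)
        loose = EstParams(support_min_overlap_bp=50, support_min_identity=0.95)
        c_strict, _ = expression_support(small_ds.ests, small_ds.genome, small_catalogue, strict)
        c_loose, _ = expression_support(small_ds.ests, small_ds.genome, small_catalogue, loose)
        strict_by_id = {c.retro_id: c.n_supporting_ests for c in c_strict}
        for c in c_loose:
            assert c.n_supporting_ests >= strict_by_id[c.retro_id]

    def test_support_counts_are_deterministic(self, small_ds, small_catalogue):
        c1, s1 = expression_support(small_ds.ests, small_ds.genome, small_catalogue)
        c2, s2 = expression_support(small_ds.ests, small_ds.genome, small_catalogue)
        assert s1 == s2
        assert [(c.retro_id, c.n_supporting_ests, c.supporting_est_ids) for c in c1] == [
            (c.retro_id, c.n_supporting_ests, c.supporting_est_ids) for c in c2
        ]
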